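"""Self-validation experiments on synthetic cohorts with known ground truth.

Each function runs one calibration or recovery study end to end — generate
cohorts, run the relevant pipeline stages, compare against planted truth or
an independent oracle — and returns a small dict of summary numbers.  The
test suite asserts on these summaries; the reproduction script reports them.

Study sizes are desk scale (hundreds of samples, tens of replicates); the
methods note states the sizes and what they do and do not establish.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import synthdata as sd
from .association import partial_spearman, run_association_screen
from .covariates import build_model_matrix
from .enrichment import enrich_bidirectional, enrichment_score, rank_statistic
from .io import subclass_sets
from .metabolites import process_metabolites
from .profiling import filter_and_transform_species, profile_relative_abundance
from .variance import RidgeGrid, nested_cv_r2, ridge_fit


def _seed_stream(seed: int, n: int) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


# ---------------------------------------------------------------------------
# partial-correlation oracle equivalence

def residual_method_rho(x: np.ndarray, y: np.ndarray, Z: np.ndarray) -> float:
    """Independent oracle: rank everything, regress ranked x and y on ranked Z
    (with intercept), return the Pearson correlation of the residuals."""
    n = len(x)
    xr, yr = rankdata(x), rankdata(y)
    Zr = (
        np.column_stack([rankdata(Z[:, j]) for j in range(Z.shape[1])])
        if Z.shape[1]
        else np.empty((n, 0))
    )
    A = np.column_stack([np.ones(n), Zr])
    rx = xr - A @ np.linalg.lstsq(A, xr, rcond=None)[0]
    ry = yr - A @ np.linalg.lstsq(A, yr, rcond=None)[0]
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def partial_corr_oracle_fuzz(n_cases: int = 1000, seed: int = 0) -> dict:
    """Max |rho difference| between the precision-matrix estimator and the
    residual-regression oracle over random instances (n=30-200, k=0-5)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        n = int(rng.integers(30, 201))
        k = int(rng.integers(0, 6))
        Z = rng.normal(size=(n, k))
        x = rng.normal(size=n) + (Z @ rng.normal(size=k) if k else 0.0)
        y = rng.normal(size=n) + 0.5 * x
        rho = partial_spearman(x, y, Z).rho
        worst = max(worst, abs(rho - residual_method_rho(x, y, Z)))
    return {"max_abs_delta_rho": worst, "n_cases": n_cases}


# ---------------------------------------------------------------------------
# null calibration / FDR control

def fdr_null_study(
    n_cohorts: int = 50,
    n_samples: int = 300,
    n_species: int = 100,
    n_metabolites: int = 150,
    seed: int = 0,
) -> dict:
    """Screen fully null cohorts (no planted effects).

    Returns the mean false-discovery proportion of q < 0.05 calls (every call
    on a null cohort is false, so FDP is 1 when anything is called and 0
    otherwise), its Monte-Carlo SE over cohorts, and the raw p < 0.05
    fraction with the single-cohort binomial SD.
    """
    fdps, fracs = [], []
    n_pairs = None
    for s in _seed_stream(seed, n_cohorts):
        cfg = sd.SynthConfig(
            n_samples=n_samples, n_species=n_species, n_metabolites=n_metabolites,
            seed=s,
        )
        counts, raw, cov, _ = sd.generate_cohort(cfg)
        logm = filter_and_transform_species(
            profile_relative_abundance(counts), min_nonzero=100
        )
        mets = process_metabolites(raw, min_measured=100)
        Z = build_model_matrix(cov)
        tab = run_association_screen(logm.values, mets.values, Z.values, "null")
        n_pairs = len(tab)
        R = int((tab["q"] < 0.05).sum())
        fdps.append(1.0 if R > 0 else 0.0)
        fracs.append(float((tab["p"] < 0.05).mean()))
    fdps, fracs = np.asarray(fdps), np.asarray(fracs)
    return {
        "mean_fdp": float(fdps.mean()),
        "fdp_mc_se": float(fdps.std(ddof=1) / np.sqrt(n_cohorts)),
        "mean_p05_fraction": float(fracs.mean()),
        "binomial_sd": float(np.sqrt(0.05 * 0.95 / n_pairs)),
        "n_cohorts": n_cohorts,
        "n_pairs": int(n_pairs),
    }


# ---------------------------------------------------------------------------
# power / recovery and batch-confound nulling

def _prevalent_species(cfg: sd.SynthConfig, k: int) -> list[str]:
    """The k most prevalent species of the cohort a config will generate."""
    cov = sd.generate_covariates(cfg, sd._derive(cfg.seed, "covariates"))
    batch = cov["site"].astype(str) + "|" + cov["delivery_batch"].astype(str)
    comp = sd.generate_composition(cfg, sd._derive(cfg.seed, "composition"), batch)
    return (comp > 0).mean().sort_values(ascending=False).index[:k].tolist()


def power_study(
    n_replicates: int = 20,
    n_samples: int = 800,
    planted_r2: float = 0.2,
    seed: int = 0,
) -> dict:
    """Recovery of planted species-metabolite effects at q < 0.05.

    Effects are planted on the three most prevalent species of each cohort
    with a microbial signal fraction whose population Spearman rho exceeds
    0.3 (verified by Monte-Carlo during development); a replicate succeeds
    when every planted pair is significant in the adjusted screen.
    """
    hits = []
    for s in _seed_stream(seed, n_replicates):
        base = sd.SynthConfig(
            n_samples=n_samples, n_species=100, n_metabolites=50, seed=s
        )
        species = _prevalent_species(base, 3)
        cfg = dataclasses.replace(
            base,
            planted_effects=[
                sd.PlantedEffect(species[0], "met_0001", 0.6),
                sd.PlantedEffect(species[1], "met_0002", -0.6),
                sd.PlantedEffect(species[2], "met_0003", 0.6),
            ],
            planted_r2={m: planted_r2 for m in ("met_0001", "met_0002", "met_0003")},
        )
        counts, raw, cov, truth = sd.generate_cohort(cfg)
        logm = filter_and_transform_species(
            profile_relative_abundance(counts), min_nonzero=100
        )
        mets = process_metabolites(raw, min_measured=100)
        Z = build_model_matrix(cov)
        tab = run_association_screen(logm.values, mets.values, Z.values, "main")
        t = tab.set_index(["feature_id", "outcome_id"])
        ok = True
        for eff in truth.effects:
            key = (eff.species, eff.metabolite)
            ok = ok and key in t.index and t.loc[key, "q"] < 0.05
        hits.append(bool(ok))
    return {
        "recovery_rate": float(np.mean(hits)),
        "n_replicates": n_replicates,
    }


def batch_confounding_study(
    n_replicates: int = 20, n_samples: int = 800, seed: int = 0
) -> dict:
    """Planted pure-batch associations: significant unadjusted, nulled by
    covariate adjustment.

    Each cohort plants technical batch shifts into both the composition and
    the metabolites (no biological coupling).  A replicate succeeds when the
    unadjusted screen calls at least 1% of pairs significant while the
    batch-adjusted screen calls at most 0.5%.
    """
    ok = []
    unadj_frac, adj_frac = [], []
    for s in _seed_stream(seed, n_replicates):
        cfg = sd.SynthConfig(
            n_samples=n_samples, n_species=50, n_metabolites=50, seed=s,
            composition_batch_sd=1.0, batch_effect_sd=1.0,
        )
        counts, raw, cov, _ = sd.generate_cohort(cfg)
        logm = filter_and_transform_species(
            profile_relative_abundance(counts), min_nonzero=100
        )
        mets = process_metabolites(raw, min_measured=100)
        Z = build_model_matrix(cov)
        un = run_association_screen(logm.values, mets.values, None, "unadjusted")
        ad = run_association_screen(logm.values, mets.values, Z.values, "adjusted")
        fu = float((un["q"] < 0.05).mean())
        fa = float((ad["q"] < 0.05).mean())
        unadj_frac.append(fu)
        adj_frac.append(fa)
        ok.append(fu >= 0.01 and fa <= 0.005)
    return {
        "nulled_rate": float(np.mean(ok)),
        "mean_unadjusted_sig_fraction": float(np.mean(unadj_frac)),
        "mean_adjusted_sig_fraction": float(np.mean(adj_frac)),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# variance-explained recovery

def variance_recovery_study(
    fractions: tuple[float, ...] = (0.0, 0.1, 0.25, 0.4),
    n_replicates: int = 10,
    n_samples: int = 1000,
    n_species: int = 100,
    seed: int = 0,
) -> dict:
    """Nested-CV ridge r2 against planted microbial signal fractions.

    The signal is spread over 20 species (drawn strengths), reflecting the
    many-producer structure of microbial metabolites; the response is the
    latent log-scale metabolite, and the predictor matrix is the profiled
    ln(1+percent) species matrix.
    """
    grid = RidgeGrid()
    results = {}
    seeds = _seed_stream(seed, n_replicates * len(fractions))
    i = 0
    for f in fractions:
        vals = []
        for _ in range(n_replicates):
            s = seeds[i]
            i += 1
            rng = np.random.default_rng(s)
            strengths = rng.normal(0.0, 0.5, 20)
            cfg = sd.SynthConfig(
                n_samples=n_samples, n_species=n_species, n_metabolites=5, seed=s,
                planted_effects=[
                    sd.PlantedEffect(f"MGS{k + 1:04d}", "met_0001", float(b))
                    for k, b in enumerate(strengths)
                ] if f > 0 else [],
                planted_r2={"met_0001": f} if f > 0 else {},
                covariate_effect_sd=0.0, batch_effect_sd=0.0,
                detection_limit_quantile=0.0,
            )
            counts, raw, cov, truth = sd.generate_cohort(cfg)
            logm = filter_and_transform_species(
                profile_relative_abundance(counts), min_nonzero=100
            )
            y = truth.latent_metabolites["met_0001"].to_numpy()
            res = nested_cv_r2(logm.values.to_numpy(), y, grid=grid, seed=s)
            vals.append(res.r2)
        results[f] = float(np.mean(vals))
    errors = {f: results[f] - f for f in fractions}
    return {
        "mean_r2_by_fraction": results,
        "max_abs_error": float(max(abs(e) for e in errors.values())),
        "n_replicates": n_replicates,
    }


def ridge_closed_form_check(n_cases: int = 50, seed: int = 0) -> dict:
    """Ridge solver against the textbook closed form on random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        n, p = int(rng.integers(20, 80)), int(rng.integers(2, 15))
        lam = float(10 ** rng.uniform(-2, 3))
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        model = ridge_fit(X, y, lam)
        Xs = (X - X.mean(0)) / X.std(0)
        beta = np.linalg.solve(Xs.T @ Xs + lam * np.eye(p), Xs.T @ (y - y.mean()))
        worst = max(worst, float(np.max(np.abs(model.coef - beta))))
    return {"max_abs_delta_coef": worst, "n_cases": n_cases}


# ---------------------------------------------------------------------------
# enrichment

def exhaustive_enrichment_check(m: int = 8, set_size: int = 3, seed: int = 0) -> dict:
    """Permutation p against an independent exhaustive enumeration.

    Builds a random ranking of m items, tests every one of the C(m, s)
    subsets through the package's exhaustive mode, and recomputes each p by
    directly enumerating ES over all subsets in the test harness.
    """
    from .enrichment import preranked_test

    rng = np.random.default_rng(seed)
    assoc = pd.DataFrame(
        {
            "outcome_id": [f"m{i}" for i in range(m)],
            "p": rng.uniform(size=m),
            "t": rng.normal(size=m),
            "rho": rng.normal(size=m),
        }
    )
    stats = rank_statistic(assoc, "positive")
    items = list(stats.items)
    all_subsets = [frozenset(c) for c in combinations(items, set_size)]
    es_all = np.array([enrichment_score(stats, s) for s in all_subsets])
    worst = 0.0
    for target in all_subsets:
        obs = enrichment_score(stats, target)
        p_oracle = float(np.mean(es_all >= obs - 1e-12))
        res = preranked_test(
            stats, {"t": set(target)}, n_perm=10, seed=0, min_size=set_size
        )
        worst = max(worst, abs(float(res["p"].iloc[0]) - p_oracle))
    return {"max_abs_delta_p": worst, "n_subsets": len(all_subsets)}


def enrichment_recovery_study(
    n_replicates: int = 20, n_samples: int = 800, seed: int = 0
) -> dict:
    """Detection of a planted metabolite subclass.

    One prevalent species receives planted positive effects on every member
    of one subclass; the subclass must reach combined q < 0.05 in the
    positive direction of that species' enrichment profile.
    """
    hits = []
    for s in _seed_stream(seed, n_replicates):
        base = sd.SynthConfig(n_samples=n_samples, seed=s)
        sp = _prevalent_species(base, 1)[0]
        members = [m for i, m in enumerate(base.metabolite_ids)
                   if i % base.n_subclasses == 0]  # subclass_01
        cfg = dataclasses.replace(
            base,
            planted_effects=[sd.PlantedEffect(sp, m, 0.5) for m in members],
            planted_r2={m: 0.04 for m in members},
        )
        counts, raw, cov, _ = sd.generate_cohort(cfg)
        logm = filter_and_transform_species(
            profile_relative_abundance(counts), min_nonzero=100
        )
        mets = process_metabolites(raw, min_measured=100)
        Z = build_model_matrix(cov)
        tab = run_association_screen(logm.values, mets.values, Z.values, "main")
        prof = tab.loc[tab["feature_id"] == sp]
        res = enrich_bidirectional(
            prof, subclass_sets(mets.annotations), n_perm=2000, seed=s
        )
        row = res.loc[
            (res["set_id"] == "subclass_01") & (res["direction"] == "positive")
        ]
        hits.append(bool(len(row) and row["q"].iloc[0] < 0.05))
    return {"detection_rate": float(np.mean(hits)), "n_replicates": n_replicates}


# ---------------------------------------------------------------------------
# cross-stratum self-concordance

def concordance_study(
    n_per_stratum: int = 3000,
    n_species: int = 100,
    n_metabolites: int = 150,
    seed: int = 0,
) -> dict:
    """Stratified vs full-sample concordance of Spearman rho on homogeneous data.

    One cohort (three BMI tertiles of ``n_per_stratum`` samples each) with a
    broad spectrum of planted effects, so true associations span weak to
    strong; the same screen is run on the full sample and within each
    tertile, and the Pearson correlation of rho over shared pairs measures
    how well stratified estimates track the full-sample ones.
    """
    rng = np.random.default_rng(seed)
    base = sd.SynthConfig(
        n_samples=3 * n_per_stratum, n_species=n_species,
        n_metabolites=n_metabolites, seed=int(rng.integers(2**31)),
    )
    effects, r2s = [], {}
    for i, m in enumerate(base.metabolite_ids):
        species = f"MGS{(i * 7) % n_species + 1:04d}"
        strength = float(rng.choice([-0.6, 0.6]))
        effects.append(sd.PlantedEffect(species, m, strength))
        r2s[m] = float(rng.uniform(0.02, 0.3))
    cfg = dataclasses.replace(base, planted_effects=effects, planted_r2=r2s)
    counts, raw, cov, _ = sd.generate_cohort(cfg)
    logm = filter_and_transform_species(
        profile_relative_abundance(counts), min_nonzero=100
    )
    mets = process_metabolites(raw, min_measured=100)
    Z_full = build_model_matrix(cov)
    full = run_association_screen(logm.values, mets.values, Z_full.values, "main")

    from .association import cross_stratum_concordance
    from .covariates import StratificationScheme, stratify

    rs = {}
    for label, idx in stratify(cov, StratificationScheme("bmi", "tertile")).items():
        Z_s = build_model_matrix(cov.loc[idx])
        tab = run_association_screen(
            logm.values.loc[idx], mets.values.loc[idx], Z_s.values, label
        )
        rs[label] = cross_stratum_concordance(full, tab)
    return {
        "pearson_r_by_stratum": rs,
        "min_pearson_r": float(min(rs.values())),
        "n_per_stratum": n_per_stratum,
    }
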