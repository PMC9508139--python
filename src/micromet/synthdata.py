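"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the atlas analysis assumes,
so every downstream stage can be verified against planted parameters:

* species composition is logistic-normal (Gaussian per-species log abundances
  pushed through a softmax, hence closed to the simplex and compositional),
  with a per-species occupancy mask producing realistic sparsity;
* signature-gene read counts are multinomial over genes with probability
  proportional to species proportion x gene effective length, at a stated
  read depth, so length-normalised profiling inverts the generator in
  expectation;
* continuous metabolites are linear combinations of planted species
  log-abundances plus additive covariate and technical batch effects plus
  Gaussian noise, with the noise variance set so the microbial signal
  fraction matches a planted r-squared; raw peak areas are exponentiated and
  scaled per instrument plate, with detection-limit censoring at a stated
  quantile;
* drug metabolites are Bernoulli detected/undetected flags coupled to
  prescription records at stated conditional probabilities.

Defaults mirror a desk-scale version of a two-site, middle-aged Scandinavian
screening cohort (covariate distributions follow its published descriptive
table); the seed fully determines every output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metabolites import RawMetabolitePlates
from .profiling import SignatureGeneCounts

PLATE_SIZE = 144  # samples per metabolomics instrument plate


@dataclass(frozen=True)
class PlantedEffect:
    """A species -> metabolite effect: signed linear coefficient applied to
    the species ln(1+percent) abundance."""

    species: str
    metabolite: str
    strength: float


@dataclass(frozen=True)
class DrugSpec:
    """Detection prevalence and prescription coupling for one drug."""

    prevalence: float
    p_prescribed_given_detected: float
    p_prescribed_given_undetected: float

    def __post_init__(self) -> None:
        for v in (
            self.prevalence,
            self.p_prescribed_given_detected,
            self.p_prescribed_given_undetected,
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError("drug probabilities must lie in [0, 1]")


@dataclass
class SynthConfig:
    """Everything that determines a synthetic cohort."""

    n_samples: int = 300
    n_species: int = 100
    genes_per_species: int = 100
    read_depth: int = 100_000
    n_metabolites: int = 150
    n_subclasses: int = 10
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    planted_r2: dict[str, float] = field(default_factory=dict)
    planted_sets: dict[str, list[str]] = field(default_factory=dict)
    # detection prevalence and prescription coupling for drug metabolites;
    # defaults mirror published proton-pump-inhibitor / metformin concordance
    # (about 4% detected; 67% vs 8% and 78% vs 0.2% prescribed)
    drug_spec: dict[str, DrugSpec] = field(
        default_factory=lambda: {
            "drug_ppi": DrugSpec(0.04, 0.67, 0.08),
            "drug_metformin": DrugSpec(0.04, 0.78, 0.002),
        }
    )
    detection_limit_quantile: float = 0.02
    noise_sd: float = 1.0
    covariate_effect_sd: float = 0.1
    batch_effect_sd: float = 0.2
    # composition shape: spread of species baseline means; community-gradient
    # factor structure of the log-scale covariance (low rank + diagonal,
    # emulating co-abundance gradients); idiosyncratic log-sd; and the
    # occupancy (presence) range controlling sparsity
    composition_mu_sd: float = 1.5
    n_community_factors: int = 5
    factor_loading_sd: float = 2.2
    composition_sigma: float = 0.5
    occupancy_range: tuple[float, float] = (0.5, 1.0)
    # technical confounding: per-(species, batch) log-abundance shifts; 0 keeps
    # composition independent of the processing batches
    composition_batch_sd: float = 0.0
    frac_batch_limited: float = 0.05
    n_plates_per_site: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_species", "genes_per_species", "read_depth",
                     "n_metabolites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for m, r2 in self.planted_r2.items():
            if not 0.0 <= r2 < 1.0:
                raise ValueError(f"planted_r2[{m!r}] must lie in [0, 1)")
        if not 0.0 <= self.detection_limit_quantile < 1.0:
            raise ValueError("detection_limit_quantile must lie in [0, 1)")

    @property
    def species_ids(self) -> list[str]:
        return [f"MGS{i + 1:04d}" for i in range(self.n_species)]

    @property
    def metabolite_ids(self) -> list[str]:
        """Continuous metabolite ids; drug metabolites are appended by name."""
        return [f"met_{i + 1:04d}" for i in range(self.n_metabolites)]

    @property
    def all_metabolite_ids(self) -> list[str]:
        extra = [d for d in self.drug_spec if d not in set(self.metabolite_ids)]
        return self.metabolite_ids + extra

    def validate_references(self) -> None:
        species = set(self.species_ids)
        mets = set(self.metabolite_ids)
        for eff in self.planted_effects:
            if eff.species not in species:
                raise ValueError(f"planted effect references unknown species {eff.species!r}")
            if eff.metabolite not in mets:
                raise ValueError(
                    f"planted effect references unknown metabolite {eff.metabolite!r}"
                )
        for m in self.planted_r2:
            if m not in mets:
                raise ValueError(f"planted_r2 references unknown metabolite {m!r}")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort."""

    effects: list[PlantedEffect]
    realized_signal_fraction: dict[str, float]
    enriched_sets: dict[str, list[str]]
    drug_tables: dict[str, np.ndarray]
    #: latent log-scale continuous metabolite values (signal + covariate/batch
    #: effects + noise), before the peak-area emulation and censoring
    latent_metabolites: pd.DataFrame | None
    composition: pd.DataFrame  # true per-sample species proportions
    log_abundance: pd.DataFrame  # ln(1 + percent) of the true composition


def _derive(seed: int, stage: str) -> np.random.Generator:
    # stable per-stage stream: crc32 is deterministic across processes,
    # unlike Python's randomized str hash
    tag = zlib.crc32(stage.encode()) % 2**31
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def generate_composition(
    config: SynthConfig,
    rng: np.random.Generator,
    batch_label: pd.Series | None = None,
) -> pd.DataFrame:
    """Logistic-normal species composition with an occupancy sparsity mask.

    Per-sample log abundances are Gaussian with a low-rank-plus-diagonal
    covariance: a few community-gradient factors load on every species
    (emulating the dominant co-abundance gradients of real gut communities)
    on top of idiosyncratic per-species variation; the softmax then closes
    the vector to the simplex.  With ``composition_batch_sd`` > 0 and a
    ``batch_label`` series, each (species, batch) gets an additional log-scale
    shift, planting purely technical species-metabolite confounding.
    """
    S, n = config.n_species, config.n_samples
    mu = rng.normal(0.0, config.composition_mu_sd, size=S)
    occupancy = rng.uniform(*config.occupancy_range, size=S)
    K = config.n_community_factors
    # per-species factor-component sd ~= factor_loading_sd overall
    loadings = rng.normal(0.0, config.factor_loading_sd / np.sqrt(K), size=(K, S))
    factors = rng.normal(size=(n, K))
    z = (
        mu[None, :]
        + factors @ loadings
        + rng.normal(0.0, config.composition_sigma, size=(n, S))
    )
    if config.composition_batch_sd > 0 and batch_label is not None:
        levels = sorted(batch_label.unique())
        shifts = rng.normal(0.0, config.composition_batch_sd, size=(len(levels), S))
        idx = batch_label.map({b: i for i, b in enumerate(levels)}).to_numpy()
        z = z + shifts[idx]
    present = rng.uniform(size=(n, S)) < occupancy[None, :]
    # ensure no empty sample: force the most abundant baseline species present
    present[~present.any(axis=1), int(np.argmax(mu))] = True
    w = np.where(present, np.exp(z), 0.0)
    comp = w / w.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        comp,
        index=[f"S{i + 1:05d}" for i in range(n)],
        columns=config.species_ids,
    )


def generate_signature_counts(
    composition: pd.DataFrame, config: SynthConfig, rng: np.random.Generator
) -> SignatureGeneCounts:
    """Multinomial signature-gene counts at the configured read depth.

    Gene probabilities are proportional to species proportion x gene
    effective length, so per-sample totals equal the read depth exactly and
    length normalization in profiling undoes the length weighting in
    expectation.
    """
    comp = composition.to_numpy()
    if np.any(comp < 0):
        raise ValueError("species proportions must be non-negative")
    if not np.allclose(comp.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("species proportions must sum to 1 per sample")
    S, G = config.n_species, config.genes_per_species
    eff_len = np.round(rng.lognormal(mean=np.log(900.0), sigma=0.35, size=S * G)).clip(100)
    gene_ids = [
        f"{sp}_g{g + 1:03d}" for sp in config.species_ids for g in range(G)
    ]
    gene_meta = pd.DataFrame(
        {
            "species_id": np.repeat(config.species_ids, G),
            "effective_length": eff_len,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    weights = np.repeat(comp, G, axis=1) * eff_len[None, :]
    probs = weights / weights.sum(axis=1, keepdims=True)
    counts = rng.multinomial(config.read_depth, probs)  # batched over samples
    counts_df = pd.DataFrame(counts, index=composition.index, columns=gene_ids)
    return SignatureGeneCounts(counts=counts_df, gene_meta=gene_meta)


def generate_covariates(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Cohort covariate table: model covariates plus stratification variables."""
    n = config.n_samples
    idx = [f"S{i + 1:05d}" for i in range(n)]
    site = rng.choice(["Malmo", "Uppsala"], size=n, p=[0.45, 0.55])
    plates = np.array(
        [f"P{rng.integers(1, config.n_plates_per_site + 1)}" for _ in range(n)]
    )
    plate = np.char.add(np.char.add(site.astype(str), "_"), plates)
    # delivery batches nested in site: two for Uppsala, one for Malmo
    batch = np.where(
        site == "Uppsala",
        np.where(rng.uniform(size=n) < 0.5, "B1", "B2"),
        "B3",
    )
    fiber_g = np.clip(rng.normal(24.0, 8.0, size=n), 5.0, None)
    energy_kcal = np.clip(rng.normal(2000.0, 450.0, size=n), 800.0, None)
    cov = pd.DataFrame(
        {
            "age": np.clip(rng.normal(57.5, 4.4, size=n), 50, 65).round(1),
            "sex": rng.choice(["female", "male"], size=n, p=[0.52, 0.48]),
            "place_of_birth": rng.choice(
                ["Scandinavia", "non-Scandinavian Europe", "Asia", "other"],
                size=n,
                p=[0.845, 0.09, 0.045, 0.02],
            ),
            "site": site,
            "extraction_plate": plate,
            "delivery_batch": batch,
            "bmi": np.clip(rng.normal(27.1, 4.45, size=n), 16, 55).round(1),
            "systolic_bp": np.clip(rng.normal(123.5, 16.2, size=n), 85, 220).round(0),
            "egfr": np.clip(rng.normal(85.9, 11.8, size=n), 20, 130).round(1),
            "fiber_g": fiber_g.round(1),
            "energy_kcal": energy_kcal.round(0),
            "smoking": rng.choice(
                ["current", "former", "never"], size=n, p=[0.125, 0.34, 0.535]
            ),
            "antibiotics_12m": rng.uniform(size=n) < 0.2,
            "med_hypertension": rng.uniform(size=n) < 0.19,
            "med_cholesterol": rng.uniform(size=n) < 0.08,
            "med_diabetes": rng.uniform(size=n) < 0.04,
            "coffee": rng.choice(
                ["<1/d", "1-2/d", "3-4/d", ">4/d"], size=n, p=[0.13, 0.31, 0.415, 0.145]
            ),
        },
        index=pd.Index(idx, name="sample_id"),
    )
    cov["fiber_per_kcal"] = (cov["fiber_g"] / cov["energy_kcal"]).round(5)
    return cov


def _covariate_design(cov: pd.DataFrame) -> np.ndarray:
    """Standardised covariate design for additive log-metabolite effects."""
    return np.column_stack(
        [
            (cov["age"] - cov["age"].mean()) / cov["age"].std(),
            (cov["sex"] == "male").astype(float) - 0.5,
        ]
    )


def generate_metabolites(
    log_abundance: pd.DataFrame,
    cov: pd.DataFrame,
    config: SynthConfig,
    rng: np.random.Generator,
) -> tuple[
    RawMetabolitePlates, dict[str, float], dict[str, np.ndarray], pd.DataFrame, pd.DataFrame
]:
    """Raw metabolite plates with planted structure.

    Returns the raw plates, the realized per-metabolite microbial signal
    fraction, the drug 2x2 tables, the prescription flags, and the latent
    log-scale continuous metabolite matrix (before peak-area emulation).
    """
    config.validate_references()
    n = config.n_samples
    mets = config.all_metabolite_ids
    drug_ids = list(config.drug_spec)
    continuous = [m for m in mets if m not in drug_ids]

    effects_by_met: dict[str, list[PlantedEffect]] = {}
    for eff in config.planted_effects:
        effects_by_met.setdefault(eff.metabolite, []).append(eff)

    batch_label = cov["site"].astype(str) + "|" + cov["delivery_batch"].astype(str)
    batch_levels = sorted(batch_label.unique())
    batch_idx = batch_label.map({b: i for i, b in enumerate(batch_levels)}).to_numpy()
    design = _covariate_design(cov)

    log_values = np.empty((n, len(continuous)))
    realized: dict[str, float] = {}
    for j, m in enumerate(continuous):
        signal = np.zeros(n)
        for eff in effects_by_met.get(m, []):
            signal += eff.strength * log_abundance[eff.species].to_numpy()
        var_sig = float(np.var(signal))
        if m in config.planted_r2 and var_sig > 0:
            r2 = config.planted_r2[m]
            if r2 == 0:
                signal = np.zeros(n)
                var_sig = 0.0
                noise_sd = config.noise_sd
            else:
                noise_sd = float(np.sqrt(var_sig * (1.0 - r2) / r2))
        else:
            noise_sd = config.noise_sd
        noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
        coveff = (
            design @ rng.normal(0.0, config.covariate_effect_sd, size=design.shape[1])
            if config.covariate_effect_sd > 0
            else np.zeros(n)
        )
        beff = rng.normal(0.0, config.batch_effect_sd, len(batch_levels))[batch_idx]
        y = signal + coveff + beff + noise
        log_values[:, j] = y
        tot = float(np.var(y - coveff - beff))
        realized[m] = var_sig / tot if tot > 0 else 0.0

    # raw peak areas: exponentiate, apply a per-plate instrument scale
    plate_of = pd.Series(
        [f"MP{1 + i // PLATE_SIZE:03d}" for i in range(n)], index=cov.index, name="plate"
    )
    plate_codes, plate_uniques = pd.factorize(plate_of, sort=True)
    plate_scale = rng.lognormal(0.0, 0.3, size=len(plate_uniques))[plate_codes]
    base_scale = rng.lognormal(np.log(1e6), 1.0, size=len(continuous))
    raw_areas = np.exp(log_values) * base_scale[None, :] * plate_scale[:, None]
    det_cont = np.ones_like(raw_areas, dtype=bool)
    # detection-limit censoring at the configured quantile
    q = config.detection_limit_quantile
    if q > 0:
        lim = np.quantile(raw_areas, q, axis=0)
        below = raw_areas < lim[None, :]
        det_cont[below] = False
        raw_areas = np.where(below, np.nan, raw_areas)
    areas = pd.DataFrame(index=cov.index, columns=mets, dtype=float)
    detected = pd.DataFrame(False, index=cov.index, columns=mets)
    areas[continuous] = raw_areas
    detected[continuous] = det_cont

    # drug metabolites: Bernoulli detection coupled to prescriptions
    prescriptions = pd.DataFrame(index=cov.index, dtype=bool)
    drug_tables: dict[str, np.ndarray] = {}
    for d in drug_ids:
        spec = config.drug_spec[d]
        det = rng.uniform(size=n) < spec.prevalence
        p_presc = np.where(
            det, spec.p_prescribed_given_detected, spec.p_prescribed_given_undetected
        )
        presc = rng.uniform(size=n) < p_presc
        detected[d] = det
        areas[d] = np.where(det, 1.0, np.nan)
        prescriptions[f"presc_{d}"] = presc
        nd = int(det.sum())
        drug_tables[d] = np.array(
            [
                [nd * spec.p_prescribed_given_detected, nd * (1 - spec.p_prescribed_given_detected)],
                [
                    (n - nd) * spec.p_prescribed_given_undetected,
                    (n - nd) * (1 - spec.p_prescribed_given_undetected),
                ],
            ]
        )
        realized[d] = float("nan")

    # subclass / class annotations: metabolites cycle through subclasses
    subclass = [
        f"subclass_{(i % config.n_subclasses) + 1:02d}" if m not in drug_ids else "drug"
        for i, m in enumerate(mets)
    ]
    annotations = pd.DataFrame(
        {
            "name": mets,
            "class": ["xenobiotics" if m in drug_ids else "endogenous" for m in mets],
            "subclass": subclass,
            "is_drug": [m in drug_ids for m in mets],
            "batches_measured": "all",
        },
        index=pd.Index(mets, name="metabolite_id"),
    )

    # a fraction of continuous metabolites is unmeasured in one delivery batch
    measured = pd.DataFrame(True, index=cov.index, columns=mets)
    n_limited = int(round(config.frac_batch_limited * len(continuous)))
    if n_limited and len(batch_levels) > 1:
        limited = list(rng.choice(continuous, size=n_limited, replace=False))
        missing_batch = batch_levels[-1]
        mask = (batch_label == missing_batch).to_numpy()
        for m in limited:
            measured.loc[mask, m] = False
            detected.loc[mask, m] = False
            areas.loc[mask, m] = np.nan
            annotations.loc[m, "batches_measured"] = ",".join(
                b for b in batch_levels if b != missing_batch
            )

    raw = RawMetabolitePlates(
        areas=areas, detected=detected, plate=plate_of,
        annotations=annotations, measured=measured,
    )
    presc = prescriptions if drug_ids else pd.DataFrame(index=cov.index)
    latent = pd.DataFrame(log_values, index=cov.index, columns=continuous)
    return raw, realized, drug_tables, presc, latent


def generate_cohort(
    config: SynthConfig,
) -> tuple[SignatureGeneCounts, RawMetabolitePlates, pd.DataFrame, SyntheticTruth]:
    """Generate one fully structured synthetic cohort.

    Returns signature-gene counts, raw metabolite plates, the covariate table
    (with prescription flags appended) and the ground truth.  The same config
    (and seed) always produces bit-identical output.
    """
    config.validate_references()
    cov = generate_covariates(config, _derive(config.seed, "covariates"))
    batch_label = cov["site"].astype(str) + "|" + cov["delivery_batch"].astype(str)
    comp = generate_composition(
        config, _derive(config.seed, "composition"), batch_label=batch_label
    )
    counts = generate_signature_counts(comp, config, _derive(config.seed, "counts"))
    log_abund = np.log1p(100.0 * comp)
    raw, realized, drug_tables, presc, latent = generate_metabolites(
        log_abund, cov, config, _derive(config.seed, "metabolites")
    )
    cov = pd.concat([cov, presc], axis=1)
    enriched = {
        name: members for name, members in config.planted_sets.items()
    }
    truth = SyntheticTruth(
        effects=list(config.planted_effects),
        realized_signal_fraction=realized,
        enriched_sets=enriched,
        drug_tables=drug_tables,
        latent_metabolites=latent,
        composition=comp,
        log_abundance=log_abund,
    )
    return counts, raw, cov, truth
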