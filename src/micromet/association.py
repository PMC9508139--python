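"""Covariate-adjusted partial Spearman association screening.

The screening engine computes, for every (feature, outcome) pair, the partial
Spearman rank correlation given an adjustment matrix Z: all variables are
replaced by mid-ranks and the partial correlation is read off the precision
matrix of the ranked data,

    rho = -P_xy / sqrt(P_xx * P_yy),    P = C^{-1},

with a Student-t test on df = n - 2 - k (k = number of adjustment columns).
Multiple testing is controlled per analysis family with Benjamini-Hochberg
q-values.  The module also carries the downstream set operations used to mine
a finished association table: top-k sign-specific intersections, derived
ratio outcomes, cross-stratum concordance of rho, and detected-vs-prescribed
Fisher concordance for drug metabolites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: smallest p-value ever reported; two-sided tail probabilities below this
#: are floored so downstream -log10 transforms stay finite.
P_FLOOR = float(np.nextafter(0.0, 1.0))

ASSOCIATION_COLUMNS = [
    "feature_id",
    "feature_type",
    "outcome_id",
    "family",
    "n",
    "rho",
    "t",
    "df",
    "p",
    "q",
]


@dataclass(frozen=True)
class PartialCorrelation:
    """Result of a single partial Spearman correlation."""

    rho: float
    t: float
    df: int
    p: float
    n: int


def _rank_matrix(M: np.ndarray) -> np.ndarray:
    """Column-wise mid-ranks (average ranks for ties)."""
    return np.apply_along_axis(rankdata, 0, M)


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None = None,
) -> PartialCorrelation:
    """Partial Spearman correlation of ``x`` and ``y`` given covariates ``Z``.

    Rows with a non-finite value in any of ``x``, ``y`` or ``Z`` are dropped
    (complete-case analysis).  All remaining columns, covariates included, are
    converted to mid-ranks before the precision-matrix computation, so with an
    empty ``Z`` this reduces to the classical Spearman coefficient.

    Raises
    ------
    ValueError
        If fewer than ``k + 3`` complete cases remain, or if ``x`` or ``y``
        has zero variance on the complete cases (an undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z is None:
        Z = np.empty((x.shape[0], 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]

    mask = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(Z), axis=1)
    x, y, Z = x[mask], y[mask], Z[mask]
    n, k = x.shape[0], Z.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least k + 3 = {k + 3} complete cases, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance variable: partial correlation undefined")

    R = _rank_matrix(np.column_stack([x, y, Z]))
    # constant covariate columns rank to a constant; drop them so the
    # correlation matrix is well defined
    keep = np.ptp(R, axis=0) > 0
    R = R[:, keep]
    k = R.shape[1] - 2

    C = np.corrcoef(R, rowvar=False)
    # blockwise precision-matrix formula: with P = C^{-1} partitioned over
    # (x, y | Z), -P_xy / sqrt(P_xx P_yy) equals the Schur-complement form
    # below, which stays exact when x and y are perfectly rank-correlated
    if k:
        Czz = C[2:, 2:]
        try:
            W = np.linalg.inv(Czz)
        except np.linalg.LinAlgError:
            warnings.warn("singular rank-correlation matrix; using pseudo-inverse")
            W = np.linalg.pinv(Czz)
        cxz, cyz = C[0, 2:], C[1, 2:]
        num = C[0, 1] - cxz @ W @ cyz
        den2 = (1.0 - cxz @ W @ cxz) * (1.0 - cyz @ W @ cyz)
    else:
        num, den2 = C[0, 1], 1.0
    if den2 <= 0:
        raise ValueError("covariates explain x or y completely; partial "
                         "correlation undefined")
    rho = float(np.clip(num / np.sqrt(den2), -1.0, 1.0))

    df = n - 2 - k
    if abs(rho) == 1.0:
        t = np.inf if rho > 0 else -np.inf
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
    p = max(2.0 * stats.t.sf(abs(t), df), P_FLOOR)
    return PartialCorrelation(rho=rho, t=float(t), df=int(df), p=float(p), n=int(n))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _partial_corr_grid(
    F: np.ndarray, O: np.ndarray, Z: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Partial Spearman of every feature column against every outcome column.

    Vectorised Schur-complement form of the precision-matrix estimator: on the
    mid-ranked data, rho_xy.Z = (C_xy - C_xZ W C_Zy) / sqrt((1-R2_x)(1-R2_y))
    with W = C_ZZ^{-1}; identical algebra to inverting each (2+k) correlation
    block.  Returns (rho matrix, effective k) for complete data (no NaNs).
    """
    n = F.shape[0]
    Fr = _rank_matrix(F) if F.size else F
    Or = _rank_matrix(O) if O.size else O
    Zr = _rank_matrix(Z) if Z.size else Z
    if Zr.size:
        Zr = Zr[:, np.ptp(Zr, axis=0) > 0]
    k = Zr.shape[1] if Zr.size else 0

    def _std(M):
        M = M - M.mean(axis=0)
        sd = M.std(axis=0, ddof=0)
        sd[sd == 0] = np.nan  # zero-variance columns flagged as NaN
        return M / sd

    Fs, Os = _std(Fr), _std(Or)
    if k == 0:
        rho = (Fs.T @ Os) / n
        return np.clip(rho, -1, 1), 0
    Zs = _std(Zr)
    C_zz = (Zs.T @ Zs) / n
    C_fz = (Fs.T @ Zs) / n
    C_oz = (Os.T @ Zs) / n
    try:
        W = np.linalg.inv(C_zz)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariate rank-correlation matrix; pseudo-inverse")
        W = np.linalg.pinv(C_zz)
    num = (Fs.T @ Os) / n - C_fz @ W @ C_oz.T
    res_f = 1.0 - np.einsum("ij,jk,ik->i", C_fz, W, C_fz)
    res_o = 1.0 - np.einsum("ij,jk,ik->i", C_oz, W, C_oz)
    res_f = np.where(res_f <= 0, np.nan, res_f)
    res_o = np.where(res_o <= 0, np.nan, res_o)
    rho = num / np.sqrt(res_f[:, None] * res_o[None, :])
    return np.clip(rho, -1, 1), k


def run_association_screen(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    Z: pd.DataFrame | np.ndarray | None,
    family: str,
    feature_type: str = "species",
    min_n: int = 30,
) -> pd.DataFrame:
    """Screen every feature against every outcome with covariate adjustment.

    ``features`` and ``outcomes`` are samples x variables frames aligned on
    index.  Outcomes may contain NaN blocks (metabolites unmeasured in a
    delivery batch); complete cases are taken per missingness pattern, so each
    pair uses every sample with data for it.  BH adjustment is applied jointly
    across all pairs of the screen (one q-value family per call).

    Pairs whose feature or outcome is constant on the complete cases are
    degenerate and dropped (logged), mirroring an undefined rank correlation.
    """
    if features.shape[1] == 0 or outcomes.shape[1] == 0:
        raise ValueError("empty feature or outcome set")
    if not features.index.equals(outcomes.index):
        raise ValueError("features and outcomes must share a sample index")
    if Z is None:
        Zv = np.empty((len(features), 0))
    else:
        Zv = np.asarray(Z, dtype=float)
        if Zv.shape[0] != len(features):
            raise ValueError("covariate matrix not aligned with samples")
    Fv = features.to_numpy(dtype=float)
    Ov = outcomes.to_numpy(dtype=float)
    base = np.all(np.isfinite(Fv), axis=1) & np.all(np.isfinite(Zv), axis=1)

    rows: list[pd.DataFrame] = []
    miss = ~np.isfinite(Ov)
    patterns = {}
    for j in range(Ov.shape[1]):
        key = miss[:, j].tobytes()
        patterns.setdefault(key, []).append(j)
    n_degenerate = 0
    for cols in patterns.values():
        mask = base & ~miss[:, cols[0]]
        n = int(mask.sum())
        if n < min_n:
            logger.info("skipping %d outcomes with n=%d < min_n", len(cols), n)
            continue
        rho, k = _partial_corr_grid(Fv[mask], Ov[np.ix_(mask, cols)], Zv[mask])
        df = n - 2 - k
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt(df / (1.0 - rho**2))
            t = np.where(np.abs(rho) >= 1.0, np.sign(rho) * np.inf, t)
        p = np.maximum(2.0 * stats.t.sf(np.abs(t), df), P_FLOOR)
        fi, oi = np.meshgrid(
            np.arange(Fv.shape[1]), np.asarray(cols), indexing="ij"
        )
        block = pd.DataFrame(
            {
                "feature_id": features.columns.to_numpy()[fi.ravel()],
                "outcome_id": outcomes.columns.to_numpy()[oi.ravel()],
                "n": n,
                "rho": rho.ravel(),
                "t": t.ravel(),
                "df": df,
                "p": p.ravel(),
            }
        )
        bad = ~np.isfinite(block["rho"])
        n_degenerate += int(bad.sum())
        rows.append(block.loc[~bad])
    if not rows:
        raise ValueError("no (feature, outcome) pair met the minimum sample size")
    if n_degenerate:
        logger.warning("dropped %d degenerate zero-variance pairs", n_degenerate)
    table = pd.concat(rows, ignore_index=True)
    table["feature_type"] = feature_type
    table["family"] = family
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table[ASSOCIATION_COLUMNS].sort_values(
        ["feature_id", "outcome_id"], ignore_index=True
    )


def cross_stratum_concordance(
    table_full: pd.DataFrame, table_stratum: pd.DataFrame
) -> float:
    """Pearson correlation of rho between a full-sample and a stratified screen.

    Matches rows on (feature_id, outcome_id); requires at least 3 shared pairs.
    """
    a = table_full.set_index(["feature_id", "outcome_id"])["rho"]
    b = table_stratum.set_index(["feature_id", "outcome_id"])["rho"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared (feature, outcome) pairs")
    return float(stats.pearsonr(a.loc[shared], b.loc[shared])[0])


def top_k_intersection(
    table: pd.DataFrame,
    outcome_neg: str,
    outcome_pos: str,
    k: int = 20,
) -> set[str]:
    """Features in both the k most-negative list for one outcome and the
    k most-positive list for another.

    Emulates mining an atlas for "converter" taxa: organisms depleting a
    precursor (strong negative rho) while producing a product (strong positive
    rho).  Ties on rho break by smaller p, then feature id.
    """
    out: list[set[str]] = []
    for outcome, ascending in ((outcome_neg, True), (outcome_pos, False)):
        sub = table.loc[table["outcome_id"] == outcome]
        if sub.empty:
            raise ValueError(f"outcome {outcome!r} absent from table")
        if k > len(sub):
            raise ValueError(f"k={k} exceeds feature count {len(sub)}")
        sub = sub.sort_values(
            ["rho", "p", "feature_id"], ascending=[ascending, True, True]
        )
        out.append(set(sub["feature_id"].head(k)))
    return out[0] & out[1]


def ratio_outcome(
    numerator: pd.Series, denominator: pd.Series, name: str | None = None
) -> pd.Series:
    """Elementwise ratio of two metabolites on the pre-log (normalized) scale.

    Entries with a nonpositive or missing denominator are set to NaN and
    excluded pairwise downstream.
    """
    num = numerator.astype(float)
    den = denominator.astype(float)
    bad = ~(den > 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} nonpositive denominator entries excluded")
    ratio = num / den.where(~bad)
    ratio.name = name or f"{numerator.name}/{denominator.name}"
    return ratio


def fisher_concordance(
    detected: np.ndarray, prescribed: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Concordance of drug detection in plasma with prescription records.

    Returns ``(odds_ratio, p, table)`` where ``table`` is the 2x2 count matrix
    [[det & presc, det & not], [not det & presc, neither]], p is the two-sided
    Fisher exact probability and the odds ratio is the conditional MLE
    (infinite for zero-cell tables).  A degenerate margin (all-0 or all-1
    vector) yields p = 1 and a NaN odds ratio.
    """
    d = np.asarray(detected).astype(bool)
    r = np.asarray(prescribed).astype(bool)
    if d.shape != r.shape:
        raise ValueError("vectors must cover the same samples")
    table = np.array(
        [
            [int(np.sum(d & r)), int(np.sum(d & ~r))],
            [int(np.sum(~d & r)), int(np.sum(~d & ~r))],
        ]
    )
    if np.all(d) or not np.any(d) or np.all(r) or not np.any(r):
        warnings.warn("degenerate margin in concordance table")
        return float("nan"), 1.0, table
    res = stats.contingency.odds_ratio(table, kind="conditional")
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return float(res.statistic), p, table
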