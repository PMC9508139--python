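"""Adjustment-model matrix construction and stratification schemes.

The main association model adjusts for age, sex, place of birth and a single
combined technical batch variable built by concatenating study site, microbial
DNA extraction plate and metabolomics delivery batch labels (plate and batch
are nested in site, so the concatenation is the full cross-classification
actually observed).  Multi-level categoricals are dummy-coded with the last
declared level dropped.  Sensitivity analyses stratify the cohort by tertiles
of clinical variables or by exclusion of flagged participants; strata keep the
main model unchanged and only change the sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: covariates of the main association model
MAIN_MODEL_CONTINUOUS = ["age"]
MAIN_MODEL_CATEGORICAL = ["sex", "place_of_birth"]

PLACE_OF_BIRTH_LEVELS = ["Scandinavia", "non-Scandinavian Europe", "Asia", "other"]
SEX_LEVELS = ["female", "male"]


@dataclass
class ModelMatrix:
    """Numeric adjustment matrix with column provenance."""

    values: pd.DataFrame
    provenance: dict[str, str]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def k(self) -> int:
        return self.values.shape[1]


def _dummies(series: pd.Series, levels: list[str], name: str) -> pd.DataFrame:
    observed = set(series.dropna().unique())
    unknown = observed - set(levels)
    if unknown:
        raise ValueError(f"{name}: levels {sorted(unknown)} not in declared set")
    cat = pd.Categorical(series, categories=levels)
    dummies = pd.get_dummies(cat, prefix=name, dtype=float)
    dummies.index = series.index
    # drop the dummy of the last declared category
    return dummies.iloc[:, :-1]


def combined_batch_label(cov: pd.DataFrame) -> pd.Series:
    """One technical batch label per sample: ``site|plate|delivery_batch``."""
    lab = (
        cov["site"].astype(str)
        + "|"
        + cov["extraction_plate"].astype(str)
        + "|"
        + cov["delivery_batch"].astype(str)
    )
    lab.name = "batch"
    return lab


def build_model_matrix(
    cov: pd.DataFrame,
    extra: pd.DataFrame | pd.Series | None = None,
    levels: dict[str, list[str]] | None = None,
) -> ModelMatrix:
    """Main-model adjustment matrix: age, sex, place of birth, combined batch.

    ``extra`` appends continuous columns (e.g. Shannon diversity for the
    alpha-diversity-adjusted sensitivity model).  ``levels`` overrides the
    declared level order of any categorical; by default the last level in the
    declared order (lexicographic for batch labels) is the dropped reference.
    """
    levels = dict(levels or {})
    required = ["age", "sex", "place_of_birth", "site", "extraction_plate", "delivery_batch"]
    missing = [c for c in required if c not in cov.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns {missing}")
    if cov[required].isna().any().any():
        raise ValueError("main-model covariates must be complete (no missing values)")

    blocks: list[pd.DataFrame] = []
    provenance: dict[str, str] = {}

    age = cov["age"].astype(float).rename("age")
    blocks.append(age.to_frame())
    provenance["age"] = "continuous:age"

    for name, default_levels in (("sex", SEX_LEVELS), ("place_of_birth", PLACE_OF_BIRTH_LEVELS)):
        lv = levels.get(name, default_levels)
        d = _dummies(cov[name], lv, name)
        blocks.append(d)
        provenance.update({c: f"categorical:{name}" for c in d.columns})

    batch = combined_batch_label(cov)
    batch_levels = levels.get("batch", sorted(batch.unique()))
    d = _dummies(batch, batch_levels, "batch")
    blocks.append(d)
    provenance.update({c: "categorical:batch(site|plate|delivery)" for c in d.columns})

    if extra is not None:
        if isinstance(extra, pd.Series):
            extra = extra.to_frame()
        extra = extra.astype(float).reindex(cov.index)
        blocks.append(extra)
        provenance.update({c: f"continuous:extra:{c}" for c in extra.columns})

    values = pd.concat(blocks, axis=1)
    return ModelMatrix(values=values, provenance=provenance)


@dataclass(frozen=True)
class StratificationScheme:
    """Named stratification: ``tertile``, ``exclusion`` or ``category``."""

    variable: str
    kind: str  # tertile | exclusion | category


def stratify(cov: pd.DataFrame, scheme: StratificationScheme) -> dict[str, pd.Index]:
    """Sample index sets for a stratification scheme.

    Tertiles partition by the empirical 1/3 and 2/3 quantiles (linear
    interpolation, left-closed intervals: ties at a cut point go to the lower
    group).  Exclusion schemes return the complement of flagged samples.
    Category schemes return one set per observed level.
    """
    if scheme.variable not in cov.columns:
        raise ValueError(f"unknown stratification variable {scheme.variable!r}")
    x = cov[scheme.variable]
    if scheme.kind == "tertile":
        v = x.astype(float)
        if v.nunique() < 3:
            raise ValueError(f"{scheme.variable}: fewer than 3 distinct values")
        q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
        return {
            f"{scheme.variable}_T1": cov.index[v <= q1],
            f"{scheme.variable}_T2": cov.index[(v > q1) & (v <= q2)],
            f"{scheme.variable}_T3": cov.index[v > q2],
        }
    if scheme.kind == "exclusion":
        flagged = x.astype(bool)
        return {f"no_{scheme.variable}": cov.index[~flagged]}
    if scheme.kind == "category":
        return {
            f"{scheme.variable}={lvl}": idx
            for lvl, idx in cov.groupby(x, observed=True).groups.items()
        }
    raise ValueError(f"unknown scheme kind {scheme.kind!r}")


def energy_adjust_fiber(fiber_g: pd.Series, energy_kcal: pd.Series) -> pd.Series:
    """Energy-adjusted fiber intake: grams of fiber per kcal of total energy."""
    energy = energy_kcal.astype(float)
    if (energy <= 0).any():
        raise ValueError("total energy intake must be positive")
    out = fiber_g.astype(float) / energy
    out.name = "fiber_per_kcal"
    return out
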