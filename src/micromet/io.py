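"""Table formats, set-definition files, configuration and the full pipeline.

All tabular artifacts are TSV (metabolite nomenclature contains commas), with
floats written at 17 significant digits so a write/read round trip is
lossless.  Set definitions use the GMT convention (set id, description,
member ids, tab-separated); gut-metabolic-module definitions use a flat-text
block format (``MFxxxx<TAB>name`` header line, one reaction step per line,
alternatives separated by ``|``, genes within an alternative separated by
``,``, blocks closed by ``///``).

``run_pipeline`` chains every stage — synthetic cohort (or files on disk),
species profiling, metabolite preprocessing, covariate model matrix,
association screens (main, alpha-diversity-adjusted, strata), variance
explained, enrichment, and drug concordance — into an on-disk atlas bundle
whose metadata (config echo, seeds, file hashes, per-family counts) allows a
bit-identical rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc_mod
from . import covariates as cov_mod
from . import enrichment as enr_mod
from . import metabolites as met_mod
from . import profiling as prof_mod
from . import synthdata as synth_mod
from . import variance as var_mod

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.17g"


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    """Write a TSV with full-precision floats and empty fields for missing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index, na_rep="")
    return path


def read_table(
    path: str | Path,
    schema: dict[str, type] | None = None,
    index_col: int | None = 0,
) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, optionally validating types.

    ``schema`` maps required column names to dtypes; undeclared extra columns
    are preserved with a warning, missing or mistyped columns raise with the
    file and column named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=index_col, float_precision="round_trip")
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        extra = [c for c in df.columns if c not in schema]
        if extra:
            logger.warning("%s: undeclared columns %s preserved", path, extra)
        for col, typ in schema.items():
            try:
                df[col] = df[col].astype(typ)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: column {col!r} is not {typ}: {exc}") from exc
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT set definitions: ``set_id<TAB>description<TAB>member...``."""
    sets: dict[str, set[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT lines need id, description, members")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for name in sorted(sets):
        desc = (descriptions or {}).get(name, "")
        lines.append("\t".join([name, desc, *sorted(sets[name])]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gmm_modules(path: str | Path) -> list[prof_mod.GmmModuleDef]:
    """Parse the flat-text gut-metabolic-module format (see module docstring)."""
    modules: list[prof_mod.GmmModuleDef] = []
    module_id, name, steps = None, "", []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line == "///":
            if module_id is None:
                raise ValueError(f"{path}:{ln}: '///' before any module header")
            modules.append(
                prof_mod.GmmModuleDef(module_id, name, tuple(steps))
            )
            module_id, name, steps = None, "", []
        elif module_id is None:
            parts = line.split("\t")
            module_id, name = parts[0], parts[1] if len(parts) > 1 else ""
        else:
            alts = tuple(
                frozenset(g.strip() for g in alt.split(",") if g.strip())
                for alt in line.split("|")
            )
            steps.append(alts)
    if module_id is not None:
        modules.append(prof_mod.GmmModuleDef(module_id, name, tuple(steps)))
    return modules


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Everything ``run_pipeline`` needs; loadable from YAML."""

    seed: int = 0
    out_dir: str = "atlas_out"
    synth: synth_mod.SynthConfig = field(default_factory=synth_mod.SynthConfig)
    min_nonzero_species: int = 100
    min_measured_metabolites: int = 100
    rarefaction_depth: int | None = None  # None: the synthetic read depth
    screen_min_n: int = 30
    fdr_level: float = 0.05
    ridge_lambdas: tuple[float, float, int] = (1e-3, 1e5, 25)  # min, max, count
    variance_max_metabolites: int | None = None
    enrichment_n_perm: int = 1000
    enrichment_min_size: int = 5
    strata: list[cov_mod.StratificationScheme] = field(
        default_factory=lambda: [
            cov_mod.StratificationScheme("bmi", "tertile"),
            cov_mod.StratificationScheme("antibiotics_12m", "exclusion"),
        ]
    )
    species_sets: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "synth" in raw:
            synth_raw = dict(raw["synth"])
            if "planted_effects" in synth_raw:
                synth_raw["planted_effects"] = [
                    synth_mod.PlantedEffect(**e) for e in synth_raw["planted_effects"]
                ]
            if "drug_spec" in synth_raw:
                synth_raw["drug_spec"] = {
                    k: synth_mod.DrugSpec(**v) for k, v in synth_raw["drug_spec"].items()
                }
            raw["synth"] = synth_mod.SynthConfig(**synth_raw)
        if "strata" in raw:
            raw["strata"] = [
                cov_mod.StratificationScheme(s["variable"], s["kind"])
                for s in raw["strata"]
            ]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def ridge_grid(self) -> var_mod.RidgeGrid:
        lo, hi, num = self.ridge_lambdas
        return var_mod.RidgeGrid(
            lambdas=tuple(np.logspace(np.log10(lo), np.log10(hi), int(num)))
        )


@dataclass
class AtlasBundle:
    """In-memory handles to everything the pipeline wrote."""

    out_dir: Path
    diversity_table: pd.DataFrame
    species_table: pd.DataFrame
    shannon_adjusted_table: pd.DataFrame
    strata_tables: dict[str, pd.DataFrame]
    variance_table: pd.DataFrame
    subclass_enrichment: pd.DataFrame
    species_set_enrichment: pd.DataFrame | None
    concordance: pd.DataFrame
    drug_concordance: pd.DataFrame
    metadata: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def subclass_sets(annotations: pd.DataFrame) -> dict[str, set[str]]:
    """Metabolite-subclass set definitions from the annotation frame."""
    groups = annotations.groupby("subclass").groups
    return {str(sc): set(map(str, idx)) for sc, idx in groups.items() if sc != "drug"}


def run_pipeline(
    config: PipelineConfig | str | Path,
    progress: bool = False,
) -> AtlasBundle:
    """Execute the full atlas pipeline and write the bundle to disk."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s % (2**31)) for s in ss.generate_state(4)]

    # --- synthetic cohort -------------------------------------------------
    synth_cfg = dataclasses.replace(config.synth, seed=config.seed)
    counts, raw_mets, cov, truth = synth_mod.generate_cohort(synth_cfg)

    # --- species profiling ------------------------------------------------
    percent = prof_mod.profile_relative_abundance(counts)
    species_log = prof_mod.filter_and_transform_species(
        percent, min_nonzero=config.min_nonzero_species
    )
    depth = config.rarefaction_depth or synth_cfg.read_depth
    diversity = prof_mod.shannon_downsized(counts, depth=depth, seed=stage_seeds[0])

    # --- metabolites ------------------------------------------------------
    mets = met_mod.process_metabolites(
        raw_mets, min_measured=config.min_measured_metabolites
    )
    drug_cols = mets.drug_columns
    continuous = mets.values.drop(columns=drug_cols)
    all_outcomes = mets.values

    # --- covariates -------------------------------------------------------
    Z_main = cov_mod.build_model_matrix(cov)
    shannon = diversity.H.reindex(cov.index)
    Z_shannon = cov_mod.build_model_matrix(cov, extra=shannon.rename("shannon"))

    # --- association screens ---------------------------------------------
    div_features = shannon.to_frame("shannon_diversity")
    diversity_table = assoc_mod.run_association_screen(
        div_features, all_outcomes, Z_main.values, family="diversity_main",
        feature_type="diversity", min_n=config.screen_min_n,
    )
    species_table = assoc_mod.run_association_screen(
        species_log.values, all_outcomes, Z_main.values, family="species_main",
        min_n=config.screen_min_n,
    )
    shannon_table = assoc_mod.run_association_screen(
        species_log.values, all_outcomes, Z_shannon.values,
        family="species_shannon_adjusted", min_n=config.screen_min_n,
    )

    strata_tables: dict[str, pd.DataFrame] = {}
    concordance_rows = []
    for scheme in config.strata:
        for label, idx in cov_mod.stratify(cov, scheme).items():
            Z_s = cov_mod.build_model_matrix(cov.loc[idx])
            try:
                tab = assoc_mod.run_association_screen(
                    species_log.values.loc[idx], all_outcomes.loc[idx],
                    Z_s.values, family=f"species_main|{label}",
                    min_n=config.screen_min_n,
                )
            except ValueError:
                logger.warning("stratum %s too small for screening; skipped", label)
                continue
            strata_tables[label] = tab
            concordance_rows.append(
                {
                    "stratum": label,
                    "n_pairs": len(tab),
                    "pearson_r": assoc_mod.cross_stratum_concordance(species_table, tab),
                }
            )
    concordance = pd.DataFrame(
        concordance_rows, columns=["stratum", "n_pairs", "pearson_r"]
    )

    # --- variance explained ----------------------------------------------
    var_outcomes = continuous
    if config.variance_max_metabolites is not None:
        var_outcomes = continuous.iloc[:, : config.variance_max_metabolites]
    variance_table = var_mod.variance_explained_screen(
        species_log.values, var_outcomes, grid=config.ridge_grid(), seed=stage_seeds[1]
    )

    # --- enrichment -------------------------------------------------------
    sc_sets = subclass_sets(mets.annotations)
    enr_frames = []
    try:
        div_enr = enr_mod.enrich_bidirectional(
            diversity_table, sc_sets, item_column="outcome_id",
            n_perm=config.enrichment_n_perm, seed=stage_seeds[2],
            min_size=config.enrichment_min_size,
        )
        div_enr.insert(0, "profile", "shannon_diversity")
        enr_frames.append(div_enr)
    except ValueError:
        logger.warning("no subclass reaches the enrichment size floor")
    for sp in species_table["feature_id"].unique():
        slice_ = species_table.loc[species_table["feature_id"] == sp]
        try:
            e = enr_mod.enrich_bidirectional(
                slice_, sc_sets, item_column="outcome_id",
                n_perm=config.enrichment_n_perm, seed=stage_seeds[2],
                min_size=config.enrichment_min_size,
            )
        except ValueError:
            continue
        e.insert(0, "profile", sp)
        enr_frames.append(e)
    enrichment_columns = ["profile", "set_id", "direction", "size", "ES", "p",
                          "leading_edge", "n_perm", "seed", "q"]
    if enr_frames:
        subclass_enrichment = pd.concat(enr_frames, ignore_index=True)
    else:
        subclass_enrichment = pd.DataFrame(columns=enrichment_columns)

    species_set_enrichment = None
    if config.species_sets:
        frames = []
        for m in species_table["outcome_id"].unique():
            slice_ = species_table.loc[species_table["outcome_id"] == m]
            try:
                e = enr_mod.enrich_bidirectional(
                    slice_, config.species_sets, item_column="feature_id",
                    n_perm=config.enrichment_n_perm, seed=stage_seeds[3],
                    min_size=config.enrichment_min_size,
                )
            except ValueError:
                continue
            e.insert(0, "profile", m)
            frames.append(e)
        if frames:
            species_set_enrichment = pd.concat(frames, ignore_index=True)

    # --- drug concordance -------------------------------------------------
    # detection vs prescription uses the raw detection flags: a drug with few
    # detected samples is informative here even when the >=100-measurement
    # analysis filter drops it from the association screens
    drug_rows = []
    all_drugs = raw_mets.annotations.index[
        raw_mets.annotations["is_drug"].astype(bool)
    ]
    for d in all_drugs:
        presc_col = f"presc_{d}"
        if presc_col not in cov.columns:
            continue
        orr, p, table = assoc_mod.fisher_concordance(
            raw_mets.detected[d].to_numpy(), cov[presc_col].to_numpy()
        )
        drug_rows.append(
            {
                "drug": d, "odds_ratio": orr, "p": p,
                "n_detected": int(table[0].sum()),
                "pct_prescribed_detected": 100.0 * table[0, 0] / max(table[0].sum(), 1),
                "pct_prescribed_undetected": 100.0 * table[1, 0] / max(table[1].sum(), 1),
            }
        )
    drug_concordance = pd.DataFrame(
        drug_rows,
        columns=["drug", "odds_ratio", "p", "n_detected",
                 "pct_prescribed_detected", "pct_prescribed_undetected"],
    )

    # --- write bundle -----------------------------------------------------
    files = {
        "diversity_associations.tsv": diversity_table,
        "species_associations.tsv": species_table,
        "species_associations_shannon_adjusted.tsv": shannon_table,
        "variance_explained.tsv": variance_table,
        "subclass_enrichment.tsv": subclass_enrichment,
        "stratum_concordance.tsv": concordance,
        "drug_concordance.tsv": drug_concordance,
        "species_abundance_log1p.tsv": species_log.values,
        "shannon_diversity.tsv": diversity.H.to_frame(),
    }
    if species_set_enrichment is not None:
        files["species_set_enrichment.tsv"] = species_set_enrichment
    for label, tab in strata_tables.items():
        files[f"species_associations_stratum_{label.replace('|', '_')}.tsv"] = tab
    hashes = {}
    for name, df in files.items():
        p = write_table(df, out / name, index=name.endswith(("log1p.tsv", "diversity.tsv")))
        hashes[name] = _sha256(p)

    fdr = config.fdr_level
    metadata = {
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "config": _config_to_jsonable(config),
        "n_samples": int(synth_cfg.n_samples),
        "retained_species": len(species_log.retained_species),
        "retained_metabolites": len(mets.retained),
        "rarefaction_depth": depth,
        "significant_calls": {
            "diversity_main": int((diversity_table["q"] < fdr).sum()),
            "species_main": int((species_table["q"] < fdr).sum()),
            "species_shannon_adjusted": int((shannon_table["q"] < fdr).sum()),
            "subclass_enrichment": int((subclass_enrichment["q"] < fdr).sum()),
        },
        "row_counts": {name: int(len(df)) for name, df in files.items()},
        "file_sha256": hashes,
    }
    (out / "metadata.json").write_text(json.dumps(metadata, indent=2, sort_keys=True))
    logger.info(
        "pipeline complete: %d species-metabolite rows, %d significant",
        len(species_table), metadata["significant_calls"]["species_main"],
    )
    return AtlasBundle(
        out_dir=out,
        diversity_table=diversity_table,
        species_table=species_table,
        shannon_adjusted_table=shannon_table,
        strata_tables=strata_tables,
        variance_table=variance_table,
        subclass_enrichment=subclass_enrichment,
        species_set_enrichment=species_set_enrichment,
        concordance=concordance,
        drug_concordance=drug_concordance,
        metadata=metadata,
    )


def _config_to_jsonable(config: PipelineConfig) -> dict:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"unserialisable {type(o)}")

    return json.loads(json.dumps(dataclasses.asdict(config), default=default))
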