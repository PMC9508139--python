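"""Metagenomic species profiling from signature-gene counts.

A metagenomic species (MGS) is quantified by the reads mapping to its panel of
signature genes (nominally 100 per species).  This module turns a samples x
genes count table into:

* species relative abundances (percent, each sample renormalised to 100%),
  applying the zero-out rule — a species' count is set to zero in any sample
  where reads hit fewer than 3 of its signature genes — and dividing each
  species count by the summed effective length of its signature genes;
* analysis-ready ln(1+percent) values after a prevalence filter (species kept
  only with at least ``min_nonzero`` nonzero samples);
* per-sample Shannon alpha diversity on reads downsized (sampled without
  replacement) to a common depth, so diversity is not confounded by depth;
* taxonomy labels from reference-similarity summaries via a fixed threshold
  table, and gut-metabolic-module (GMM) presence calls from species gene
  content via the 2/3-of-steps rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default rarefaction depth (reads) for alpha diversity
DEFAULT_RAREFACTION_DEPTH = 210_430

#: minimum signature genes with nonzero reads for a species count to stand
MIN_DETECTED_GENES = 3

#: (rank, minimum gene fraction %, minimum percent identity) from deepest to
#: shallowest; a rank is assigned when a single taxon clears both thresholds
TAXONOMY_THRESHOLDS = [
    ("species", 75.0, 95.0),
    ("genus", 60.0, 85.0),
    ("family", 50.0, 75.0),
    ("order", 40.0, 65.0),
    ("class", 30.0, 55.0),
    ("phylum", 25.0, 50.0),
]


@dataclass
class SignatureGeneCounts:
    """Per-sample read counts over species signature genes.

    ``counts``: samples x genes integer frame; ``gene_meta``: one row per gene
    with columns ``species_id`` and ``effective_length`` (bp).
    """

    counts: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.gene_meta.index):
            self.gene_meta = self.gene_meta.loc[self.counts.columns]
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("signature-gene counts must be non-negative")
        if not np.all(self.gene_meta["effective_length"] > 0):
            raise ValueError("effective lengths must be positive")

    @property
    def species(self) -> np.ndarray:
        return self.gene_meta["species_id"].unique()

    def species_counts(self) -> pd.DataFrame:
        """Samples x species counts with the <3-detected-genes zero-out rule."""
        return _species_counts(
            self.counts.to_numpy(), self.gene_meta["species_id"].to_numpy(),
            self.counts.index, sorted(set(self.gene_meta["species_id"])),
        )


def _species_counts(counts, gene_species, sample_index, species_order):
    species_order = list(species_order)
    pos = {s: i for i, s in enumerate(species_order)}
    col = np.array([pos[s] for s in gene_species])
    n, S = counts.shape[0], len(species_order)
    totals = np.zeros((n, S))
    detected = np.zeros((n, S), dtype=int)
    np.add.at(totals.T, col, counts.T)
    np.add.at(detected.T, col, (counts > 0).T.astype(int))
    totals[detected < MIN_DETECTED_GENES] = 0
    return pd.DataFrame(totals, index=sample_index, columns=species_order)


@dataclass
class SpeciesAbundanceMatrix:
    """Species abundances at a declared stage: ``percent`` or ``log1p``."""

    values: pd.DataFrame
    stage: str
    retained_species: list[str] = field(default_factory=list)
    empty_samples: list[str] = field(default_factory=list)


def profile_relative_abundance(counts: SignatureGeneCounts) -> SpeciesAbundanceMatrix:
    """Species relative abundances (percent) from signature-gene counts.

    Per sample: species counts (zero-out rule applied) are divided by the
    summed effective length of each species' signature genes, then rescaled to
    sum to 100.  Samples with no surviving species come out all-zero and are
    flagged in ``empty_samples``.
    """
    sp_counts = counts.species_counts()
    eff_len = counts.gene_meta.groupby("species_id")["effective_length"].sum()
    norm = sp_counts / eff_len.reindex(sp_counts.columns)
    totals = norm.sum(axis=1)
    empty = totals[totals == 0].index.tolist()
    if empty:
        logger.warning("%d samples have zero total abundance after zero-out", len(empty))
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = norm.div(totals.where(totals > 0), axis=0).fillna(0.0) * 100.0
    return SpeciesAbundanceMatrix(
        values=percent, stage="percent",
        retained_species=list(percent.columns), empty_samples=empty,
    )


def filter_and_transform_species(
    abund: SpeciesAbundanceMatrix, min_nonzero: int = 100
) -> SpeciesAbundanceMatrix:
    """Prevalence filter then natural-log(1+x) transform.

    Species observed (nonzero) in fewer than ``min_nonzero`` samples are
    dropped before the ln(1+percent) transform.
    """
    if abund.stage != "percent":
        raise ValueError("expected a percent-stage abundance matrix")
    if min_nonzero > len(abund.values):
        raise ValueError("min_nonzero exceeds the number of samples")
    nonzero = (abund.values > 0).sum(axis=0)
    keep = nonzero[nonzero >= min_nonzero].index.tolist()
    logger.info("prevalence filter kept %d / %d species", len(keep), abund.values.shape[1])
    return SpeciesAbundanceMatrix(
        values=np.log1p(abund.values[keep]),
        stage="log1p",
        retained_species=keep,
        empty_samples=abund.empty_samples,
    )


@dataclass
class DiversityVector:
    """Per-sample Shannon index H (nats) at a fixed rarefaction depth."""

    H: pd.Series
    depth: int
    seed: int
    excluded_samples: list[str] = field(default_factory=list)


def shannon_downsized(
    counts: SignatureGeneCounts,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    seed: int = 0,
) -> DiversityVector:
    """Shannon diversity on reads downsized without replacement.

    Each sample's signature-gene counts are subsampled to ``depth`` reads by a
    multivariate-hypergeometric draw; species counts are rebuilt (with the
    <3-gene zero-out rule) and H = -sum p_i ln p_i over the downsized species
    proportions.  Samples with fewer than ``depth`` reads are excluded and
    reported, not silently kept at native depth.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    raw = counts.counts.to_numpy().astype(np.int64)
    totals = raw.sum(axis=1)
    keep = totals >= depth
    excluded = counts.counts.index[~keep].tolist()
    if excluded:
        logger.warning("%d samples below depth %d excluded from diversity", len(excluded), depth)

    gene_species = counts.gene_meta["species_id"].to_numpy()
    species_order = sorted(set(gene_species))
    down = np.empty((int(keep.sum()), raw.shape[1]), dtype=np.int64)
    for i, row in enumerate(raw[keep]):
        if row.sum() == depth:
            down[i] = row  # full-depth sample: downsizing is the identity
        else:
            down[i] = rng.multivariate_hypergeometric(row, depth, method="marginals")
    sp = _species_counts(down, gene_species, counts.counts.index[keep], species_order)
    H = sp.apply(_shannon_entropy, axis=1)
    H.name = "shannon"
    return DiversityVector(H=H, depth=depth, seed=seed, excluded_samples=excluded)


def _shannon_entropy(row: pd.Series) -> float:
    total = row.sum()
    if total == 0:
        return 0.0
    p = row[row > 0] / total
    return float(-(p * np.log(p)).sum())


def assign_taxonomy(summary: pd.DataFrame) -> pd.DataFrame:
    """Assign each species the deepest rank its similarity profile supports.

    ``summary`` has one row per (species_id, catalog gene) best hit with a
    ``pct_identity`` column and one lineage column per rank in
    ``TAXONOMY_THRESHOLDS``.  For a rank with thresholds (f, s), a taxon
    qualifies when at least f% of the species' catalog genes hit it at >= s%
    identity; the rank is assigned only when exactly one taxon qualifies
    (a tie leaves the rank unassigned).  Species with no qualifying rank are
    labelled ``unclassified``.
    """
    records = []
    for species_id, hits in summary.groupby("species_id", sort=True):
        n_genes = len(hits)
        rank, taxon = "unclassified", None
        for r, frac, ident in TAXONOMY_THRESHOLDS:
            if r not in hits.columns:
                continue
            good = hits.loc[hits["pct_identity"] >= ident, r].dropna()
            if good.empty:
                continue
            shares = good.value_counts() / n_genes * 100.0
            winners = shares[shares >= frac]
            if len(winners) == 1:
                rank, taxon = r, winners.index[0]
                break
        records.append({"species_id": species_id, "rank": rank, "taxon": taxon})
    return pd.DataFrame(records, columns=["species_id", "rank", "taxon"])


@dataclass(frozen=True)
class GmmModuleDef:
    """A gut metabolic module: ordered reaction steps, each a list of
    alternative gene-group sets (any one alternative satisfies the step)."""

    module_id: str
    name: str
    steps: tuple[tuple[frozenset[str], ...], ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"module {self.module_id} has no steps")
        if any(not alts or any(not a for a in alts) for alts in self.steps):
            raise ValueError(f"module {self.module_id} has an empty alternative")


def module_present(gene_content: set[str], module: GmmModuleDef) -> bool:
    """The 2/3 rule: a step is satisfied if the species carries every gene of
    at least one alternative; the module is present when all steps are
    satisfied (modules with fewer than 4 steps) or when satisfied / total
    >= 2/3 (modules with 4 or more steps)."""
    satisfied = sum(
        any(alt <= gene_content for alt in alts) for alts in module.steps
    )
    n = len(module.steps)
    if n < 4:
        return satisfied == n
    return satisfied / n >= 2.0 / 3.0


def assign_gmm_modules(
    species_gene_content: dict[str, set[str]],
    modules: list[GmmModuleDef],
) -> pd.DataFrame:
    """Species x module boolean presence matrix under the 2/3 rule."""
    data = {
        m.module_id: [
            module_present(species_gene_content[s], m)
            for s in species_gene_content
        ]
        for m in modules
    }
    return pd.DataFrame(data, index=list(species_gene_content))
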