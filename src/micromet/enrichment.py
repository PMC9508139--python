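"""One-sided preranked enrichment of item sets in an association profile.

Given one association result per item (metabolites for a species' profile, or
species for a metabolite's profile), items are ranked by ascending p-value
(ties broken by descending |t|, then item id) and the item at sort position r
of m receives the magnitude (m - r + 1)/m, signed by the sign of its rho.
The positive and negative association directions are tested separately as
one-sided tests: for the negative direction all signs are mirrored, so the
tested direction always sits at the top of the ranking.

The enrichment score of a set walks the ranking from the top: a set member
("hit") increments the running sum by |stat| / sum of |stat| over the set, a
non-member decrements it by 1/(m - set size); ES is the maximum positive
deviation, so ES lies in [0, 1].  Significance comes from a permutation null
of random same-size item subsets (exhaustive enumeration when the subset
count is small), and the p-values of both directions are pooled into a single
Benjamini-Hochberg family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .association import bh_adjust

#: subsets up to this count are enumerated exhaustively instead of sampled
EXHAUSTIVE_LIMIT = 100_000

MIN_SET_SIZE = 5


@dataclass
class RankedStats:
    """A ranking ready for the enrichment walk.

    ``items`` are ordered by descending signed statistic (walk order);
    ``stats`` are the signed magnitudes aligned with ``items``.
    """

    items: np.ndarray
    stats: np.ndarray
    direction: str
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.items)


def rank_statistic(
    assoc: pd.DataFrame, direction: str, item_column: str = "outcome_id"
) -> RankedStats:
    """Build the signed rank statistic from one association-table slice.

    ``assoc`` must hold one row per item with columns ``p``, ``t`` and
    ``rho``.  Rows with missing t among tied p-values fall back to an
    id-ordered tie break with a warning.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    if assoc[item_column].duplicated().any():
        raise ValueError("one association per item required")
    df = assoc[[item_column, "p", "t", "rho"]].copy()
    if df["t"].isna().any():
        dup_p = df["p"].duplicated(keep=False)
        if (df["t"].isna() & dup_p).any():
            warnings.warn("missing t among tied p-values; ties broken by item id")
        df["t"] = df["t"].fillna(0.0)
    df["abs_t"] = df["t"].abs()
    df = df.sort_values(
        ["p", "abs_t", item_column], ascending=[True, False, True]
    ).reset_index(drop=True)
    m = len(df)
    magnitude = (m - np.arange(m)) / m  # (m - r + 1)/m for r = 1..m
    sign = np.sign(df["rho"].to_numpy())
    sign[sign == 0] = 1.0
    if direction == "negative":
        sign = -sign
    stats = sign * magnitude
    order = np.lexsort((df[item_column].to_numpy(), -stats))
    return RankedStats(
        items=df[item_column].to_numpy()[order],
        stats=stats[order],
        direction=direction,
    )


def enrichment_score(
    stats: RankedStats, members: set | frozenset, return_leading_edge: bool = False
):
    """One-sided weighted running-sum enrichment score of a set.

    ES is the maximum positive deviation of the running sum over the ranking;
    with hit increments normalised by the set's total |stat| and uniform miss
    decrements, ES is bounded by [0, 1].
    """
    m = len(stats)
    hit = np.isin(stats.items, list(members))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("set has no items in the ranking")
    if n_hit == m:
        raise ValueError("set covers the whole ranking (miss step undefined)")
    es, idx = _es_from_mask(stats.stats, hit)
    if not return_leading_edge:
        return es
    leading = stats.items[: idx + 1][hit[: idx + 1]] if idx >= 0 else np.array([])
    return es, list(leading)


def _es_from_mask(stat_values: np.ndarray, hit: np.ndarray) -> tuple[float, int]:
    m = hit.shape[0]
    n_hit = int(hit.sum())
    weights = np.abs(stat_values)
    denom = weights[hit].sum()
    steps = np.where(
        hit,
        weights / denom if denom > 0 else 1.0 / n_hit,
        -1.0 / (m - n_hit),
    )
    running = np.cumsum(steps)
    idx = int(np.argmax(running))
    return float(max(running[idx], 0.0)), idx


def _null_distribution(
    stat_values: np.ndarray, size: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Null ES values for random same-size subsets; exhaustive when feasible."""
    m = stat_values.shape[0]
    if comb(m, size) <= EXHAUSTIVE_LIMIT:
        null = np.empty(comb(m, size))
        for i, idx in enumerate(combinations(range(m), size)):
            mask = np.zeros(m, dtype=bool)
            mask[list(idx)] = True
            null[i] = _es_from_mask(stat_values, mask)[0]
        return null, True
    null = np.empty(n_perm)
    for i in range(n_perm):
        mask = np.zeros(m, dtype=bool)
        mask[rng.choice(m, size=size, replace=False)] = True
        null[i] = _es_from_mask(stat_values, mask)[0]
    return null, False


def preranked_test(
    stats: RankedStats,
    sets: dict[str, set],
    n_perm: int = 10_000,
    seed: int = 0,
    min_size: int = MIN_SET_SIZE,
) -> pd.DataFrame:
    """Permutation enrichment test of every set against one ranking.

    Sets are restricted to their members present in the ranking and must
    retain at least ``min_size`` items.  The null for each set size is built
    once (random same-size subsets, or exhaustive enumeration when the subset
    count is at most ``EXHAUSTIVE_LIMIT``) and shared across sets of that
    size.  Sampled-null p-values use the add-one estimator and can never fall
    below 1/(n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    universe = set(stats.items)
    surviving = {
        name: frozenset(members) & frozenset(universe) for name, members in sets.items()
    }
    surviving = {k: v for k, v in surviving.items() if min_size <= len(v) < len(universe)}
    if not surviving:
        raise ValueError("no set meets the minimum size within the ranking")
    rng = np.random.default_rng(seed)
    null_cache: dict[int, tuple[np.ndarray, bool]] = {}
    rows = []
    for name in sorted(surviving):
        members = surviving[name]
        es, leading = enrichment_score(stats, members, return_leading_edge=True)
        size = len(members)
        if size not in null_cache:
            null_cache[size] = _null_distribution(stats.stats, size, n_perm, rng)
        null, exhaustive = null_cache[size]
        hits = int(np.sum(null >= es - 1e-12))
        if exhaustive:
            p = hits / null.shape[0]
        else:
            p = (1 + hits) / (null.shape[0] + 1)
        rows.append(
            {
                "set_id": name,
                "direction": stats.direction,
                "size": size,
                "ES": es,
                "p": p,
                "leading_edge": ",".join(map(str, leading)),
                "n_perm": null.shape[0],
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def combine_directions(pos: pd.DataFrame, neg: pd.DataFrame) -> pd.DataFrame:
    """Pool both one-sided direction families and BH-adjust jointly."""
    combined = pd.concat([pos, neg], ignore_index=True)
    if combined.duplicated(["set_id", "direction"]).any():
        raise ValueError("duplicate (set, direction) records")
    combined["q"] = bh_adjust(combined["p"].to_numpy())
    return combined


def enrich_bidirectional(
    assoc: pd.DataFrame,
    sets: dict[str, set],
    item_column: str = "outcome_id",
    n_perm: int = 10_000,
    seed: int = 0,
    min_size: int = MIN_SET_SIZE,
) -> pd.DataFrame:
    """Full enrichment of one association profile: both directions, joint BH."""
    pos = preranked_test(
        rank_statistic(assoc, "positive", item_column), sets, n_perm, seed, min_size
    )
    neg = preranked_test(
        rank_statistic(assoc, "negative", item_column), sets, n_perm, seed, min_size
    )
    return combine_directions(pos, neg)
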