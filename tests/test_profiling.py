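"""Species profiling: zero-out rule, normalization, diversity, rule engines."""

import numpy as np
import pandas as pd
import pytest

import micromet as mm
from conftest import toy_counts


class TestRelativeAbundance:
    def test_two_detected_genes_zeroes_species(self):
        # species A has reads on exactly 2 of its 3 genes -> zeroed out
        counts = toy_counts(
            [[5, 7, 0, 10, 10, 10]],
            ["A", "A", "A", "B", "B", "B"],
            [100, 100, 100, 100, 100, 100],
        )
        ab = mm.profile_relative_abundance(counts)
        assert ab.values.loc["s0", "A"] == 0.0
        assert ab.values.loc["s0", "B"] == 100.0

    def test_three_detected_genes_keeps_species(self):
        counts = toy_counts(
            [[5, 7, 1, 10, 10, 10]],
            ["A", "A", "A", "B", "B", "B"],
            [100] * 6,
        )
        ab = mm.profile_relative_abundance(counts)
        assert ab.values.loc["s0", "A"] > 0

    def test_single_species_gets_100_percent(self):
        counts = toy_counts([[3, 4, 5, 0, 0, 0]], ["A"] * 3 + ["B"] * 3, [80] * 6)
        ab = mm.profile_relative_abundance(counts)
        assert ab.values.loc["s0", "A"] == pytest.approx(100.0)
        assert ab.values.loc["s0", "B"] == 0.0

    def test_equal_length_normalized_values_split_evenly(self):
        # A: 30 reads over 300 bp total; B: 60 reads over 600 bp -> equal
        counts = toy_counts(
            [[10, 10, 10, 20, 20, 20]],
            ["A"] * 3 + ["B"] * 3,
            [100, 100, 100, 200, 200, 200],
        )
        ab = mm.profile_relative_abundance(counts)
        assert ab.values.loc["s0", "A"] == pytest.approx(50.0)
        assert ab.values.loc["s0", "B"] == pytest.approx(50.0)

    def test_rows_sum_to_100(self, processed):
        sums = processed["percent"].values.sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_all_zero_sample_flagged_not_error(self):
        counts = toy_counts([[1, 1, 0, 0]], ["A", "A", "A", "B"], [100] * 4)
        ab = mm.profile_relative_abundance(counts)  # A <3 genes, B <3 genes
        assert ab.values.loc["s0"].sum() == 0.0
        assert "s0" in ab.empty_samples

    def test_profiling_inverts_generator_in_expectation(self, cohort, processed):
        """Mean estimated percent per species tracks the planted composition."""
        est = processed["percent"].values.mean(axis=0) / 100.0
        planted = cohort["truth"].composition.mean(axis=0)
        # Monte-Carlo tolerance: 3 SDs of the mean of n=300 compositions
        mc_sd = cohort["truth"].composition.std(axis=0) / np.sqrt(300)
        resid = (est - planted).abs()
        assert (resid < 3 * mc_sd + 1e-3).all()


class TestPrevalenceFilterAndTransform:
    def test_species_below_threshold_dropped(self):
        vals = pd.DataFrame(0.0, index=range(150), columns=["A", "B"])
        vals.loc[:98, "A"] = 1.0   # nonzero in 99 samples
        vals.loc[:119, "B"] = 1.0  # nonzero in 120 samples
        vals = vals.div(vals.sum(axis=1).replace(0, np.nan), axis=0).fillna(0) * 100
        ab = mm.SpeciesAbundanceMatrix(values=vals, stage="percent")
        out = mm.filter_and_transform_species(ab, min_nonzero=100)
        assert out.retained_species == ["B"]

    def test_log1p_closed_forms(self):
        vals = pd.DataFrame({"A": [0.0, 100.0]})
        ab = mm.SpeciesAbundanceMatrix(values=vals, stage="percent")
        out = mm.filter_and_transform_species(ab, min_nonzero=1)
        assert out.values.loc[0, "A"] == 0.0
        assert out.values.loc[1, "A"] == pytest.approx(np.log(101.0))

    def test_threshold_above_n_samples_rejected(self):
        ab = mm.SpeciesAbundanceMatrix(
            values=pd.DataFrame({"A": [1.0, 2.0]}), stage="percent"
        )
        with pytest.raises(ValueError):
            mm.filter_and_transform_species(ab, min_nonzero=3)


class TestShannonDiversity:
    def test_single_species_zero_entropy(self):
        counts = toy_counts([[40, 30, 30, 0, 0, 0]], ["A"] * 3 + ["B"] * 3, [100] * 6)
        div = mm.shannon_downsized(counts, depth=100, seed=0)
        assert div.H.loc["s0"] == 0.0

    def test_even_community_entropy_is_log_s(self):
        """8 species at equal depth spread over >=3 genes each: H = ln 8."""
        n_sp = 8
        row = np.tile([40, 30, 30], n_sp)  # 100 reads per species
        counts = toy_counts(
            [row], [f"sp{i}" for i in range(n_sp) for _ in range(3)], [100] * (3 * n_sp)
        )
        div = mm.shannon_downsized(counts, depth=800, seed=0)
        assert div.H.loc["s0"] == pytest.approx(np.log(n_sp))

    def test_full_depth_matches_direct_formula(self, cohort):
        """Downsizing at full depth is the identity, so H must equal the
        direct -sum p ln p recomputation on the raw species counts."""
        counts = cohort["counts"]
        div = mm.shannon_downsized(counts, depth=cohort["config"].read_depth, seed=1)
        sp = counts.species_counts()
        p = sp.div(sp.sum(axis=1), axis=0)
        expected = (-p * np.log(p.where(p > 0))).sum(axis=1)
        np.testing.assert_allclose(div.H, expected, atol=1e-12)

    def test_entropy_bounded_by_log_richness(self, cohort):
        depth = 50_000
        div = mm.shannon_downsized(cohort["counts"], depth=depth, seed=3)
        assert (div.H >= 0).all()
        assert (div.H <= np.log(cohort["config"].n_species)).all()

    def test_below_depth_samples_excluded(self):
        counts = toy_counts(
            [[40, 30, 30], [4, 3, 3]], ["A"] * 3, [100] * 3
        )
        div = mm.shannon_downsized(counts, depth=50, seed=0)
        assert div.excluded_samples == ["s1"]
        assert list(div.H.index) == ["s0"]

    def test_nonpositive_depth_rejected(self, cohort):
        with pytest.raises(ValueError):
            mm.shannon_downsized(cohort["counts"], depth=0)


def _hits(species_id, assignments):
    """Build a similarity summary for one species from (identity, lineage) rows."""
    rows = []
    for ident, lineage in assignments:
        rows.append({"species_id": species_id, "pct_identity": ident, **lineage})
    return pd.DataFrame(rows)


FULL = {"species": "s1", "genus": "g1", "family": "f1",
        "order": "o1", "class": "c1", "phylum": "p1"}


class TestTaxonomyAssignment:
    @pytest.mark.parametrize(
        "n_hit,ident,expected_rank",
        [
            (80, 96.0, "species"),   # 80% of genes at >=95% -> species
            (75, 95.0, "species"),   # thresholds are inclusive
            (74, 96.0, "genus"),     # just below species gene fraction
            (70, 94.0, "genus"),     # identity below species cut
            (60, 85.0, "genus"),
            (59, 85.0, "family"),
            (50, 75.0, "family"),
            (45, 70.0, "order"),
            (40, 65.0, "order"),
            (35, 60.0, "class"),
            (30, 55.0, "class"),
            (25, 50.0, "phylum"),
            (24, 50.0, "unclassified"),
            (80, 49.0, "unclassified"),  # identity below every cut
        ],
    )
    def test_threshold_table(self, n_hit, ident, expected_rank):
        hits = _hits("X", [(ident, FULL)] * n_hit + [(0.0, {})] * (100 - n_hit))
        out = mm.assign_taxonomy(hits).set_index("species_id")
        assert out.loc["X", "rank"] == expected_rank

    def test_no_hits_unclassified(self):
        hits = _hits("X", [(0.0, {})] * 10)
        out = mm.assign_taxonomy(hits).set_index("species_id")
        assert out.loc["X", "rank"] == "unclassified"
        assert out.loc["X", "taxon"] is None

    def test_tie_leaves_rank_unassigned(self):
        """Two families at exactly 50% each: family skipped, order assigned."""
        fam_a = dict(FULL, family="fA")
        fam_b = dict(FULL, family="fB")
        hits = _hits("X", [(96.0, fam_a)] * 50 + [(96.0, fam_b)] * 50)
        # species/genus: two candidates sharing... construct distinct species too
        for i in range(50):
            hits.loc[i, "species"] = "sA"
            hits.loc[i, "genus"] = "gA"
        out = mm.assign_taxonomy(hits).set_index("species_id")
        # order is shared by all 100 genes -> assigned at order level
        assert out.loc["X", "rank"] == "order"
        assert out.loc["X", "taxon"] == "o1"

    def test_monotone_in_gene_fraction(self):
        """Raising the hit fraction never loses an achieved rank."""
        rank_order = ["unclassified", "phylum", "class", "order", "family",
                      "genus", "species"]
        achieved = []
        for n_hit in (20, 40, 60, 80, 100):
            hits = _hits("X", [(96.0, FULL)] * n_hit + [(0.0, {})] * (100 - n_hit))
            out = mm.assign_taxonomy(hits).set_index("species_id")
            achieved.append(rank_order.index(out.loc["X", "rank"]))
        assert achieved == sorted(achieved)


def module(mid, *steps):
    return mm.GmmModuleDef(mid, mid, tuple(
        tuple(frozenset(alt) for alt in step) for step in steps
    ))


class TestGmmModules:
    @pytest.mark.parametrize(
        "genes,steps,present",
        [
            # <4 steps: every step required
            ({"a", "b"}, [[{"a"}], [{"b"}]], True),
            ({"a"}, [[{"a"}], [{"b"}]], False),
            ({"a", "b"}, [[{"a"}], [{"b"}], [{"c"}]], False),   # 2/3 not enough
            ({"a", "b", "c"}, [[{"a"}], [{"b"}], [{"c"}]], True),
            # >=4 steps: 2/3 rule
            ({"a", "b", "c"}, [[{"a"}], [{"b"}], [{"c"}], [{"d"}]], True),   # 3/4
            ({"a", "b"}, [[{"a"}], [{"b"}], [{"c"}], [{"d"}]], False),        # 2/4
            ({"a", "b", "c", "d"}, [[{"a"}], [{"b"}], [{"c"}], [{"d"}], [{"e"}], [{"f"}]], True),  # 4/6
            ({"a", "b", "c"}, [[{"a"}], [{"b"}], [{"c"}], [{"d"}], [{"e"}], [{"f"}]], False),       # 3/6
            ({"a", "b", "c", "d"}, [[{"a"}], [{"b"}], [{"c"}], [{"d"}], [{"e"}]], True),  # 4/5
            # alternatives: one satisfied pathway suffices
            ({"b"}, [[{"a"}, {"b"}]], True),
            ({"c"}, [[{"a"}, {"b"}]], False),
            # multi-gene alternative requires every gene of that alternative
            ({"a"}, [[{"a", "b"}, {"c"}]], False),
            ({"a", "b"}, [[{"a", "b"}, {"c"}]], True),
            ({"c"}, [[{"a", "b"}, {"c"}]], True),
        ],
    )
    def test_two_thirds_rule(self, genes, steps, present):
        assert mm.module_present(genes, module("MF0001", *steps)) is present

    def test_assignment_matrix(self):
        mods = [module("MF1", [{"a"}], [{"b"}]), module("MF2", [{"x"}])]
        content = {"sp1": {"a", "b"}, "sp2": {"a"}, "sp3": {"x"}}
        out = mm.assign_gmm_modules(content, mods)
        assert out.loc["sp1", "MF1"] and not out.loc["sp2", "MF1"]
        assert out.loc["sp3", "MF2"] and not out.loc["sp1", "MF2"]

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError):
            module("MF0", *[])
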