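"""Partial Spearman screening, BH control and the table set operations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import micromet as mm
from micromet.experiments import residual_method_rho


class TestPartialSpearman:
    def test_identity_gives_rho_one(self):
        x = np.arange(20.0)
        res = mm.partial_spearman(x, x, None)
        assert res.rho == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        res = mm.partial_spearman(x, np.exp(x), None)
        assert res.rho == pytest.approx(1.0)

    def test_reduces_to_classical_spearman_without_covariates(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        res = mm.partial_spearman(x, y, None)
        rho, p = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(rho, abs=1e-12)
        assert res.p == pytest.approx(p, rel=1e-6)

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n, k = int(rng.integers(30, 120)), int(rng.integers(1, 6))
            Z = rng.normal(size=(n, k))
            x = rng.normal(size=n) + Z @ rng.normal(size=k)
            y = rng.normal(size=n) + 0.4 * x
            res = mm.partial_spearman(x, y, Z)
            assert abs(res.rho - residual_method_rho(x, y, Z)) < 1e-10

    def test_complete_case_filtering(self):
        x = np.array([1.0, 2, 3, 4, 5, np.nan, 7, 8, 9, 10, 11, 12])
        y = 2 * x
        res = mm.partial_spearman(x, y, None)
        assert res.n == 11 and res.rho == pytest.approx(1.0)

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(3)
        res = mm.partial_spearman(rng.normal(size=40), rng.normal(size=40),
                                  rng.normal(size=(40, 3)))
        assert res.df == 40 - 2 - 3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            mm.partial_spearman(np.ones(20), np.arange(20.0), None)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="complete cases"):
            mm.partial_spearman(np.arange(4.0), np.arange(4.0), np.ones((4, 2)))


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert mm.bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_step_up_oracle_example(self):
        q = mm.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(mm.bh_adjust(np.full(7, 0.2)), 0.2)

    def test_matches_inline_step_up_oracle(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(mm.bh_adjust(p), oracle, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            mm.bh_adjust(np.array([0.1, 1.5]))


class TestScreen:
    def test_single_pair_q_equals_p(self):
        rng = np.random.default_rng(5)
        F = pd.DataFrame({"f": rng.normal(size=40)})
        O = pd.DataFrame({"o": rng.normal(size=40)}, index=F.index)
        tab = mm.run_association_screen(F, O, None, "fam", min_n=10)
        assert len(tab) == 1
        assert tab.loc[0, "q"] == pytest.approx(tab.loc[0, "p"])

    def test_grid_matches_pairwise_estimator_exactly(self):
        rng = np.random.default_rng(6)
        F = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        O = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("wxyz"))
        O.iloc[:10, 0] = np.nan  # one missingness pattern
        Z = rng.normal(size=(60, 3))
        tab = mm.run_association_screen(F, O, Z, "fam", min_n=10)
        for _, row in tab.iterrows():
            ref = mm.partial_spearman(F[row.feature_id], O[row.outcome_id], Z)
            assert row.rho == pytest.approx(ref.rho, abs=1e-12)
            assert row.p == pytest.approx(ref.p, rel=1e-9)
            assert row.n == ref.n and row.df == ref.df

    def test_null_p_values_calibrated(self):
        """Independent features vs outcomes: p < 0.05 within 3 binomial SDs."""
        rng = np.random.default_rng(7)
        F = pd.DataFrame(rng.normal(size=(200, 40)),
                         columns=[f"f{i}" for i in range(40)])
        O = pd.DataFrame(rng.normal(size=(200, 40)),
                         columns=[f"o{i}" for i in range(40)])
        Z = rng.normal(size=(200, 4))
        tab = mm.run_association_screen(F, O, Z, "fam")
        frac = (tab["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(tab))

    def test_degenerate_pairs_dropped(self):
        F = pd.DataFrame({"f": np.arange(40.0), "const": np.ones(40)})
        O = pd.DataFrame({"o": np.arange(40.0) * 2})
        tab = mm.run_association_screen(F, O, None, "fam", min_n=10)
        assert set(tab["feature_id"]) == {"f"}

    def test_empty_inputs_rejected(self):
        F = pd.DataFrame(index=range(10))
        O = pd.DataFrame({"o": np.arange(10.0)})
        with pytest.raises(ValueError, match="empty"):
            mm.run_association_screen(F, O, None, "fam")


class TestConcordance:
    def make_table(self, rhos, prefix="f"):
        return pd.DataFrame(
            {
                "feature_id": [f"{prefix}{i}" for i in range(len(rhos))],
                "outcome_id": "m",
                "rho": rhos,
            }
        )

    def test_identical_tables_give_r_one(self):
        t = self.make_table(np.linspace(-0.5, 0.5, 10))
        assert mm.cross_stratum_concordance(t, t) == pytest.approx(1.0)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=30), rng.normal(size=30)
        ta, tb = self.make_table(a), self.make_table(b)
        r = mm.cross_stratum_concordance(ta, tb)
        expected = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_independent_rhos_near_zero(self):
        rng = np.random.default_rng(9)
        rs = [
            mm.cross_stratum_concordance(
                self.make_table(rng.normal(size=500)),
                self.make_table(rng.normal(size=500)),
            )
            for _ in range(20)
        ]
        assert abs(np.mean(rs)) < 0.05

    def test_insufficient_overlap_rejected(self):
        ta = self.make_table([0.1, 0.2])
        with pytest.raises(ValueError, match="3 shared"):
            mm.cross_stratum_concordance(ta, ta)


class TestTopKIntersection:
    def make_table(self):
        rng = np.random.default_rng(10)
        feats = [f"f{i:02d}" for i in range(30)]
        rows = []
        for f in feats:
            base = rng.normal()
            rows.append({"feature_id": f, "outcome_id": "precursor", "rho": -base,
                         "p": 0.01})
            rows.append({"feature_id": f, "outcome_id": "product", "rho": base,
                         "p": 0.01})
        return pd.DataFrame(rows)

    def test_mirrored_rankings_intersect_fully(self):
        tab = self.make_table()
        out = mm.top_k_intersection(tab, "precursor", "product", k=5)
        assert len(out) == 5

    def test_disjoint_lists_empty(self):
        tab = pd.DataFrame(
            {
                "feature_id": ["a", "b", "a", "b"],
                "outcome_id": ["neg", "neg", "pos", "pos"],
                "rho": [-0.9, 0.1, -0.1, 0.9],
                "p": [0.001] * 4,
            }
        )
        assert mm.top_k_intersection(tab, "neg", "pos", k=1) == set()

    def test_k_beyond_feature_count_rejected(self):
        tab = self.make_table()
        with pytest.raises(ValueError, match="exceeds"):
            mm.top_k_intersection(tab, "precursor", "product", k=31)


class TestRatioOutcome:
    def test_scale_invariance(self):
        num = pd.Series([1.0, 2.0, 3.0], name="a")
        den = pd.Series([2.0, 4.0, 8.0], name="b")
        r1 = mm.ratio_outcome(num, den)
        r2 = mm.ratio_outcome(2 * num, 2 * den)
        pd.testing.assert_series_equal(r1, r2, check_names=False)

    def test_nonpositive_denominator_excluded_with_warning(self):
        num = pd.Series([1.0, 2.0, 3.0])
        den = pd.Series([2.0, 0.0, -1.0])
        with pytest.warns(UserWarning, match="nonpositive"):
            out = mm.ratio_outcome(num, den, name="r")
        assert out.notna().tolist() == [True, False, False]

    def test_constant_ratio_flags_zero_variance(self):
        x = pd.Series(np.arange(30.0))
        ratio = mm.ratio_outcome(x + 1, x + 1, name="r")
        with pytest.raises(ValueError, match="zero-variance"):
            mm.partial_spearman(np.arange(30.0), ratio.to_numpy(), None)

    def test_screen_of_ratio_matches_recomputed_oracle(self, processed):
        mets = processed["mets"]
        non_drug = [c for c in mets.normalized.columns
                    if c not in mets.drug_columns][:2]
        num, den = mets.normalized[non_drug[0]], mets.normalized[non_drug[1]]
        ratio = mm.ratio_outcome(num, den, name="ratio")
        feature = processed["species_log"].values.iloc[:, 0]
        res = mm.partial_spearman(feature.to_numpy(), ratio.to_numpy(), None)
        oracle = (num / den).to_numpy()
        rho_oracle = stats.spearmanr(feature, oracle, nan_policy="omit")[0]
        assert res.rho == pytest.approx(rho_oracle, abs=1e-12)


class TestFisherConcordance:
    def test_balanced_table(self):
        det = np.repeat([1, 1, 0, 0], 10).astype(bool)
        presc = np.tile([1, 0], 20).astype(bool)
        orr, p, table = mm.fisher_concordance(det, presc)
        assert table.tolist() == [[10, 10], [10, 10]]
        assert orr == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_perfect_separation_hypergeometric_p(self):
        det = np.array([1] * 5 + [0] * 5, dtype=bool)
        orr, p, _ = mm.fisher_concordance(det, det)
        assert p == pytest.approx(2.0 / 252.0)
        assert np.isinf(orr)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(11)
        det = rng.uniform(size=60) < 0.3
        presc = rng.uniform(size=60) < 0.4
        _, p1, _ = mm.fisher_concordance(det, presc)
        _, p2, _ = mm.fisher_concordance(presc, det)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_degenerate_margin(self):
        with pytest.warns(UserWarning, match="degenerate"):
            orr, p, _ = mm.fisher_concordance(
                np.zeros(10, dtype=bool), np.array([1, 0] * 5, dtype=bool)
            )
        assert p == 1.0 and np.isnan(orr)
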