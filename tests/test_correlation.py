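import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp, spearmanr

import epimuscle as em
from epimuscle.correlation import (
    Ecdf,
    compare_rna_groups,
    ecdf,
    format_p,
    ks_two_sample,
    label_dernas,
    label_strength_association,
    proportion_relevant,
    spearman_matrix,
    two_proportion_ztest,
)


def rho_frame(values, rna_ids=None):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    rna_ids = rna_ids or [f"r{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"cg{i}" for i in range(arr.shape[0])],
                        columns=rna_ids)


class TestSpearmanMatrix:
    def _frame(self, rows, ids, samples=4):
        return pd.DataFrame(rows, index=ids, columns=[f"s{i}" for i in range(samples)])

    def test_perfect_monotone_pairs(self):
        x = self._frame([[1, 2, 3, 4]], ["cg1"])
        y = self._frame([[10, 20, 30, 40], [40, 30, 20, 10]], ["r1", "r2"])
        rho = spearman_matrix(x, y)
        assert rho.loc["cg1", "r1"] == pytest.approx(1.0)
        assert rho.loc["cg1", "r2"] == pytest.approx(-1.0)

    def test_average_rank_ties(self):
        x = self._frame([[1, 2, 2, 4]], ["cg1"])
        y = self._frame([[1, 3, 2, 4]], ["r1"])
        expected = spearmanr([1, 2, 2, 4], [1, 3, 2, 4]).statistic
        rho_val = spearman_matrix(x, y).iloc[0, 0]
        assert rho_val == pytest.approx(expected)
        assert rho_val == pytest.approx(0.9486832980505139)

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(3)
        x = self._frame(rng.normal(size=(6, 12)), [f"cg{i}" for i in range(6)], 12)
        y = self._frame(rng.normal(size=(5, 12)), [f"r{i}" for i in range(5)], 12)
        rho = spearman_matrix(x, y)
        for i in range(6):
            for j in range(5):
                expected = spearmanr(x.iloc[i], y.iloc[j]).statistic
                assert rho.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_row_gives_nan(self):
        x = self._frame([[1, 1, 1, 1]], ["cg1"])
        y = self._frame([[1, 2, 3, 4]], ["r1"])
        assert np.isnan(spearman_matrix(x, y).iloc[0, 0])

    def test_mismatched_samples_rejected(self):
        x = self._frame([[1, 2, 3, 4]], ["cg1"])
        y = pd.DataFrame([[1, 2, 3, 4]], index=["r1"], columns=list("abcd"))
        with pytest.raises(ValueError, match="sample"):
            spearman_matrix(x, y)

    def test_rank_invariance_beta_vs_m(self, small_cohort):
        _, meth, _, expr, _, _ = small_cohort
        beta = meth.beta.iloc[:30]
        rho_beta = spearman_matrix(beta, expr.expr.iloc[:20])
        rho_m = spearman_matrix(em.beta_to_m(beta), expr.expr.iloc[:20])
        np.testing.assert_array_equal(rho_beta.to_numpy(), rho_m.to_numpy())


class TestProportionRelevant:
    def test_strict_inequality_at_threshold(self):
        rho = rho_frame([[0.31, -0.31, 0.30, 0.29]])
        n, x, p = proportion_relevant(rho, rho.columns, tau=0.3)
        assert (n, x, p) == (4, 2, 0.5)

    def test_all_zero(self):
        n, x, p = proportion_relevant(rho_frame([[0.0, 0.0]]), ["r0", "r1"])
        assert x == 0 and p == 0.0

    def test_nan_excluded_from_both_counts(self):
        rho = rho_frame([[0.5, np.nan, 0.1]])
        n, x, p = proportion_relevant(rho, rho.columns)
        assert n == 2 and x == 1

    def test_group_aggregation_consistency(self, small_cohort, small_dmps):
        _, _, _, expr, _, truth = small_cohort
        ds, dmps = small_dmps
        rho = spearman_matrix(ds.beta.loc[dmps.probe_ids], expr.expr)
        derna = sorted(truth.true_derna_ids)
        non = [r for r in rho.columns if r not in truth.true_derna_ids]
        n_a, x_a, _ = proportion_relevant(rho, derna)
        n_b, x_b, _ = proportion_relevant(rho, non)
        n_all, x_all, _ = proportion_relevant(rho, rho.columns)
        assert n_a + n_b == n_all and x_a + x_b == x_all

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            proportion_relevant(rho_frame([[0.1]]), [])


class TestTwoProportionZtest:
    def test_equal_proportions(self):
        res = two_proportion_ztest(5, 10, 50, 100)
        assert res.z == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_known_value(self):
        res = two_proportion_ztest(8, 10, 2, 10)
        assert res.z == pytest.approx(2.683281573, abs=1e-8)
        assert res.p == pytest.approx(0.00729035809, abs=1e-9)

    def test_antisymmetric_in_groups(self):
        a = two_proportion_ztest(8, 10, 2, 10)
        b = two_proportion_ztest(2, 10, 8, 10)
        assert a.z == pytest.approx(-b.z) and a.p == pytest.approx(b.p)

    def test_degenerate_pooled_proportion(self):
        res = two_proportion_ztest(0, 10, 0, 20)
        assert res.degenerate and res.z == 0.0 and res.p == 1.0
        res = two_proportion_ztest(10, 10, 20, 20)
        assert res.degenerate

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_ztest(5, 0, 1, 2)
        with pytest.raises(ValueError):
            two_proportion_ztest(11, 10, 1, 2)

    def test_floor_display(self):
        res = two_proportion_ztest(467460, 2582650, 2049111, 120535965)
        assert res.p_display == "< 2.2e-16"
        assert format_p(0.01) == "0.01"


class TestEcdfAndKs:
    def test_ecdf_basic(self):
        f = ecdf([1, 2, 3])
        assert f(2) == pytest.approx(2 / 3)
        assert f(0.5) == 0.0 and f(3) == 1.0

    def test_ecdf_duplicates(self):
        f = ecdf([1, 1, 2])
        assert f(1) == pytest.approx(2 / 3)

    def test_ecdf_rises_zero_to_one(self):
        f = ecdf(np.random.default_rng(0).normal(size=50))
        assert f.cumulative[0] > 0 and f.cumulative[-1] == pytest.approx(1.0)
        assert np.all(np.diff(f.cumulative) > 0)

    def test_ecdf_empty_rejected(self):
        with pytest.raises(ValueError):
            ecdf([])

    def test_ks_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_ks_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == pytest.approx(1.0)

    def test_ks_interleaved(self):
        d, _ = ks_two_sample([1, 3], [2, 4])
        assert d == pytest.approx(0.5)

    def test_ks_d_matches_scipy_exactly(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.normal(size=rng.integers(3, 40))
            b = rng.normal(rng.normal(), 1, size=rng.integers(3, 40))
            d, _ = ks_two_sample(a, b)
            assert d == pytest.approx(ks_2samp(a, b).statistic, abs=1e-12)

    def test_ks_p_decreases_with_d(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=200)
        p_vals = [ks_two_sample(a, rng.normal(shift, 1, 200))[1]
                  for shift in (0.0, 0.5, 1.5)]
        assert p_vals[0] > p_vals[1] > p_vals[2]

    def test_ks_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestRnaLabelling:
    def test_derna_recovery_on_defaults(self, small_cohort):
        _, _, sheet, expr, _, truth = small_cohort
        lab = label_dernas(expr, sheet)
        sens = lab.loc[sorted(truth.true_derna_ids), "derna"].mean()
        assert sens >= 0.8

    def test_permuted_groups_give_no_flags(self, small_cohort):
        _, _, sheet, expr, _, _ = small_cohort
        rng = np.random.default_rng(0)
        shuffled = sheet.data.copy()
        shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
        lab = label_dernas(expr, em.SampleSheet(shuffled))
        assert lab["derna"].sum() <= 3

    def test_zero_fdr_gives_no_flags(self, small_cohort):
        _, _, sheet, expr, _, _ = small_cohort
        assert not label_dernas(expr, sheet, fdr=0.0)["derna"].any()

    def test_strength_recovery_and_restriction(self, small_cohort):
        _, _, sheet, expr, _, truth = small_cohort
        strength = sheet.data.loc[sheet.is_patient(), "strength"]
        res = label_strength_association(
            expr, strength, derna_flags=expr.labels["derna"]
        )
        sens = res.loc[sorted(truth.strength_coupled_rna_ids),
                       "strength_associated"].mean()
        assert sens >= 0.7
        non_derna = ~expr.labels["derna"]
        assert not res.loc[non_derna, "strength_associated"].any()

    def test_constant_strength_rejected(self, small_cohort):
        _, _, sheet, expr, _, _ = small_cohort
        constant = pd.Series(1.0, index=sheet.sample_ids)
        with pytest.raises(ValueError, match="constant"):
            label_strength_association(expr, constant,
                                       derna_flags=expr.labels["derna"])


class TestCompareRnaGroups:
    def test_full_grid_on_planted_cohort(self, small_cohort, small_dmps):
        _, _, _, expr, _, _ = small_cohort
        ds, dmps = small_dmps
        rho = spearman_matrix(ds.beta.loc[dmps.probe_ids], expr.expr)
        res = compare_rna_groups(rho, expr.labels)
        pairs = set(zip(res.comparisons["group1"], res.comparisons["group2"]))
        assert ("derna", "non_derna") in pairs
        assert ("strength", "non_strength") in pairs
        d = res.comparisons.set_index("group1")
        assert d.loc["derna", "proportion1"] > d.loc["derna", "proportion2"]
        assert d.loc["derna", "z_p"] < 1e-6

    def test_all_labels_false_yields_no_comparisons(self):
        rho = rho_frame(np.random.default_rng(0).uniform(-1, 1, (3, 6)))
        labels = pd.DataFrame(
            {"derna": False, "strength_associated": False, "pathway": "none"},
            index=rho.columns,
        )
        res = compare_rna_groups(rho, labels)
        assert len(res.comparisons) == 0
        assert list(res.groups["group"]) == ["non_derna"]

    def test_group_counts_consistent(self, small_cohort, small_dmps):
        _, _, _, expr, _, _ = small_cohort
        ds, dmps = small_dmps
        rho = spearman_matrix(ds.beta.loc[dmps.probe_ids], expr.expr)
        res = compare_rna_groups(rho, expr.labels)
        g = res.groups.set_index("group")
        assert (
            g.loc["derna", "n_relevant"] + g.loc["non_derna", "n_relevant"]
            == (rho.abs() > res.tau).to_numpy().sum()
        )
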