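import numpy as np
import pandas as pd
import pytest

import epimuscle as em
from epimuscle.dmp import bh_adjust, call_dmps, fit_dmp_models


def brute_force_bh(p):
    """Independent step-up oracle: q_i = min over p_(j) >= p_i of m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    sp = np.sort(p)
    q = np.empty(m)
    for i, pi in enumerate(p):
        candidates = [
            min(m * sp[j] / (j + 1), 1.0) for j in range(m) if sp[j] >= pi - 1e-15
        ]
        q[i] = min(candidates)
    return q


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.5], [0.01, 0.5]),
            ([0.3], [0.3]),
        ],
    )
    def test_known_step_up_values(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(brute_force_bh(p), abs=1e-12)

    def test_input_order_preserved(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        perm = rng.permutation(50)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))

    def test_monotone_along_sorted_p(self):
        rng = np.random.default_rng(2)
        p = np.sort(rng.random(200))
        q = bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_empty_vector(self):
        assert bh_adjust([]).size == 0


class TestFitDmpModels:
    def test_noiseless_group_effect_recovered_exactly(self, tiny_sheet):
        g = tiny_sheet.is_patient().astype(float).to_numpy()
        m = pd.DataFrame([1.0 + 0.5 * g], index=["cgX"],
                         columns=tiny_sheet.sample_ids)
        fit = fit_dmp_models(m, tiny_sheet)
        assert fit.loc["cgX", "delta_m"] == pytest.approx(0.5, abs=1e-10)
        # residual df is 1 after covariates, so even a numerically exact fit
        # bottoms out around machine-epsilon-scale t^-1 tails
        assert fit.loc["cgX", "p_value"] < 1e-10

    def test_age_confounding_is_adjusted_away(self, tiny_sheet):
        # methylation depends only on age; groups differ in age composition,
        # so the unadjusted group difference is non-zero but the adjusted
        # coefficient must vanish
        age = tiny_sheet.data["age"].to_numpy(dtype=float)
        m = pd.DataFrame([0.1 * age], index=["cgA"], columns=tiny_sheet.sample_ids)
        fit = fit_dmp_models(m, tiny_sheet)
        assert fit.loc["cgA", "delta_m"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels_ols(self, small_cohort):
        sm = pytest.importorskip("statsmodels.api")
        _, meth, sheet, _, _, _ = small_cohort
        m = em.beta_to_m(meth.beta)
        fit = fit_dmp_models(m, sheet)
        X = np.column_stack(
            [
                np.ones(len(sheet.data)),
                sheet.is_patient().astype(float),
                sheet.data["age"].astype(float),
                sheet.data["sex"].eq("female").astype(float),
                sheet.data["bmi"].astype(float),
            ]
        )
        for probe in m.index[:5]:
            res = sm.OLS(m.loc[probe].to_numpy(), X).fit()
            assert fit.loc[probe, "delta_m"] == pytest.approx(res.params[1], rel=1e-8)
            assert fit.loc[probe, "p_value"] == pytest.approx(res.pvalues[1], rel=1e-6)

    def test_null_probes_give_uniform_p(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(5)
        n = 60
        sheet = em.SampleSheet(
            pd.DataFrame(
                {
                    "group": ["patient"] * 40 + ["control"] * 20,
                    "age": rng.normal(60, 8, n).round(),
                    "sex": rng.choice(["male", "female"], n),
                    "bmi": rng.normal(27, 4, n).round(1),
                },
                index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
            )
        )
        m = pd.DataFrame(rng.normal(0, 1, size=(1000, n)),
                         index=[f"cg{i}" for i in range(1000)],
                         columns=sheet.sample_ids)
        fit = fit_dmp_models(m, sheet)
        assert (fit["p_value"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)
        assert kstest(fit["p_value"], "uniform").pvalue > 0.01

    def test_collinear_design_rejected_with_names(self, tiny_sheet):
        sheet = em.SampleSheet(tiny_sheet.data.assign(bmi=tiny_sheet.data["age"]))
        m = pd.DataFrame(np.full((1, 6), 0.3), index=["cg1"],
                         columns=sheet.sample_ids)
        with pytest.raises(ValueError, match="bmi|age"):
            fit_dmp_models(em.beta_to_m(m), sheet)

    def test_too_few_samples_per_group_rejected(self):
        sheet = em.SampleSheet(
            pd.DataFrame(
                {
                    "group": ["patient"] * 5 + ["control"],
                    "age": [50, 55, 60, 65, 70, 58.0],
                    "sex": ["male"] * 6,
                    "bmi": [25, 26, 27, 28, 29, 27.0],
                },
                index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
            )
        )
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 6)),
                         index=["a", "b"], columns=sheet.sample_ids)
        with pytest.raises(ValueError, match="2 samples per group"):
            fit_dmp_models(m, sheet)

    def test_moderated_fit_agrees_with_plain_on_strong_effects(self, small_cohort):
        _, meth, sheet, _, _, _ = small_cohort
        m = em.beta_to_m(meth.beta)
        plain = fit_dmp_models(m, sheet)
        mod = fit_dmp_models(m, sheet, moderate=True)
        assert np.allclose(plain["delta_m"], mod["delta_m"])
        # shrinkage perturbs p-values only mildly on a well-behaved dataset
        top_plain = set(plain.nsmallest(20, "p_value").index)
        top_mod = set(mod.nsmallest(20, "p_value").index)
        assert len(top_plain & top_mod) >= 15


class TestCallDmps:
    def test_zero_fdr_gives_empty_table(self, small_cohort):
        _, meth, sheet, _, _, _ = small_cohort
        fit = fit_dmp_models(em.beta_to_m(meth.beta), sheet)
        table = call_dmps(fit, meth.beta, sheet, fdr=0.0)
        assert len(table) == 0
        assert table.summary()["n_dmps"] == 0

    def test_directions_partition_and_match_delta_sign(self, small_dmps):
        _, dmps = small_dmps
        s = dmps.summary()
        assert s["n_hypo"] + s["n_hyper"] == s["n_dmps"]
        assert (dmps.df["direction"].eq("hypo") == (dmps.df["delta_m"] < 0)).all()

    def test_effect_size_is_percentage_point_group_difference(self, small_dmps):
        _, dmps = small_dmps
        expected = 100.0 * (
            dmps.df["mean_beta_patients"] - dmps.df["mean_beta_controls"]
        )
        assert dmps.df["effect_size_pct"].to_numpy() == pytest.approx(
            expected.to_numpy()
        )

    def test_probe_set_mismatch_rejected(self, small_cohort):
        _, meth, sheet, _, _, _ = small_cohort
        fit = fit_dmp_models(em.beta_to_m(meth.beta), sheet)
        with pytest.raises(ValueError, match="share their probe set"):
            call_dmps(fit.iloc[:10], meth.beta.iloc[5:], sheet)

    def test_delta_sign_agrees_with_beta_difference_when_balanced(self):
        # balanced covariates: the adjusted M-scale coefficient and the raw
        # beta-scale group difference must point the same way
        rng = np.random.default_rng(7)
        n = 40
        half = n // 2
        sheet = em.SampleSheet(
            pd.DataFrame(
                {
                    "group": ["patient"] * half + ["control"] * half,
                    "age": np.tile(rng.normal(60, 5, half).round(), 2),
                    "sex": np.tile(rng.choice(["male", "female"], half), 2),
                    "bmi": np.tile(rng.normal(27, 3, half).round(1), 2),
                },
                index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
            )
        )
        g = sheet.is_patient().astype(float).to_numpy()
        base = rng.uniform(0.2, 0.8, 50)
        delta = rng.uniform(-0.15, 0.15, 50)
        mu = np.clip(base[:, None] + np.outer(delta, g), 0.02, 0.98)
        m = em.beta_to_m(mu) + rng.normal(0, 0.15, mu.shape)
        beta = pd.DataFrame(em.m_to_beta(m), index=[f"cg{i}" for i in range(50)],
                            columns=sheet.sample_ids)
        fit = fit_dmp_models(em.beta_to_m(beta), sheet)
        table = call_dmps(fit, beta, sheet, fdr=0.05)
        if len(table):
            assert (
                np.sign(table.df["delta_m"]) == np.sign(table.df["effect_size_pct"])
            ).all()
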