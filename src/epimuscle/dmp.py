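"""Differentially methylated position (DMP) calling.

A per-probe ordinary least squares model is fitted on M-values with design
[intercept, group, age, sex, BMI]; the two-sided t-test on the group
coefficient (patients minus controls) gives the per-probe p-value, corrected
across probes with the Benjamini-Hochberg step-up procedure.  Probes passing
the FDR threshold are reported with their direction (hypo/hyper in patients)
and a beta-scale effect size, 100 x (mean beta patients - mean beta controls),
so effects read as percentage-point methylation differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._lm import aliased_columns, ols_fit
from .datasets import SampleSheet

FIT_COLUMNS = ["probe_id", "delta_m", "t_stat", "p_value", "df"]


def _dmp_design(sheet: SampleSheet) -> tuple[np.ndarray, list[str]]:
    cov = sheet.design_covariates()
    X = np.column_stack(
        [
            np.ones(len(cov)),
            sheet.is_patient().astype(float).to_numpy(),
            cov["age"].to_numpy(),
            cov["sex"].to_numpy(),
            cov["bmi"].to_numpy(),
        ]
    )
    return X, ["intercept", "group", "age", "sex", "bmi"]


def fit_dmp_models(
    m_values: pd.DataFrame, sheet: SampleSheet, moderate: bool = False
) -> pd.DataFrame:
    """Per-probe OLS of M on [intercept, group, age, sex, BMI].

    Returns a DataFrame indexed by probe id with columns delta_m (group
    coefficient, patients minus controls), t_stat, p_value and df.  With
    ``moderate=True`` per-probe residual variances are shrunk toward a common
    prior (empirical-Bayes moderated t-statistics); plain per-probe t-tests
    are the default.
    """
    if not m_values.columns.equals(sheet.sample_ids):
        m_values = m_values.loc[:, sheet.sample_ids]
    groups = sheet.data["group"].value_counts()
    if groups.get("patient", 0) < 2 or groups.get("control", 0) < 2:
        raise ValueError("need at least 2 samples per group")
    X, names = _dmp_design(sheet)
    bad = aliased_columns(X, names)
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    Y = m_values.to_numpy(dtype=float).T  # samples x probes
    coef, _, t, p, df, sigma2, xtx_inv_diag = ols_fit(Y, X)
    g = names.index("group")
    t_g, p_g, df_out = t[g], p[g], float(df)
    if moderate:
        d0, s0_sq = _fit_variance_prior(sigma2, df)
        if np.isfinite(d0):
            s2_post = (d0 * s0_sq + df * sigma2) / (d0 + df)
            df_out = df + d0
        else:  # no excess variability: all variances shrink to the common value
            s2_post = np.full_like(sigma2, s0_sq)
            df_out = np.inf
        se_post = np.sqrt(xtx_inv_diag[g] * s2_post)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_g = np.nan_to_num(coef[g] / se_post, nan=0.0)
        p_g = np.maximum(
            2.0 * stats.t.sf(np.abs(t_g), df_out), np.finfo(float).tiny
        )
    return pd.DataFrame(
        {"delta_m": coef[g], "t_stat": t_g, "p_value": p_g, "df": df_out},
        index=m_values.index.rename("probe_id"),
    )


def _fit_variance_prior(sigma2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (df d0, scale s0^2) to the
    observed per-probe variances via the distribution of log sigma^2."""
    from scipy.optimize import brentq
    from scipy.special import digamma, polygamma

    s2 = np.clip(sigma2, np.finfo(float).tiny, None)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_var = z.var(ddof=1) - polygamma(1, df / 2.0)
    if e_var <= 0:
        return np.inf, float(np.exp(e.mean()))
    # solve trigamma(d0/2) = e_var for d0
    f = lambda d0: polygamma(1, d0 / 2.0) - e_var
    lo, hi = 1e-6, 1e-6
    while f(hi) > 0:
        hi *= 10
        if hi > 1e12:
            return np.inf, float(np.exp(e.mean()))
    d0 = brentq(f, lo, hi) if f(lo) > 0 else lo
    s0_sq = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DmpTable:
    """Called DMPs with effect sizes and directions.

    ``df`` is indexed by probe id with columns delta_m, t_stat, p_value,
    q_value, mean_beta_patients, mean_beta_controls, effect_size_pct and
    direction ('hypo' iff delta_m < 0 else 'hyper').
    """

    df: pd.DataFrame
    fdr: float

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def __len__(self) -> int:
        return len(self.df)

    def directions(self) -> pd.Series:
        return self.df["direction"]

    def summary(self) -> dict:
        """Headline counts: total, hypo/hyper split and |effect size| scale."""
        n = len(self.df)
        n_hypo = int(self.df["direction"].eq("hypo").sum())
        n_hyper = n - n_hypo
        abs_eff = self.df["effect_size_pct"].abs()
        return {
            "n_dmps": n,
            "n_hypo": n_hypo,
            "n_hyper": n_hyper,
            "pct_hypo": round(100.0 * n_hypo / n, 1) if n else 0.0,
            "pct_hyper": round(100.0 * n_hyper / n, 1) if n else 0.0,
            "mean_abs_effect_pct": float(abs_eff.mean()) if n else 0.0,
            "max_abs_effect_pct": float(abs_eff.max()) if n else 0.0,
            "fdr": self.fdr,
        }

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="probe_id", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, fdr: float = 0.05) -> "DmpTable":
        return cls(pd.read_csv(path, sep="\t", index_col="probe_id"), fdr)


def call_dmps(
    fit: pd.DataFrame,
    beta: pd.DataFrame,
    sheet: SampleSheet,
    fdr: float = 0.05,
) -> DmpTable:
    """BH-correct the fitted p-values and retain probes with q < ``fdr``.

    ``fit`` and ``beta`` must share their probe set; BH runs across all
    fitted (QC-retained) probes before thresholding.
    """
    if not fit.index.equals(beta.index):
        if set(fit.index) != set(beta.index):
            raise ValueError("fit results and beta matrix must share their probe set")
        beta = beta.loc[fit.index]
    q = bh_adjust(fit["p_value"].to_numpy())
    is_pat = sheet.is_patient().to_numpy()
    beta_arr = beta.loc[:, sheet.sample_ids].to_numpy(dtype=float)
    mean_pat = beta_arr[:, is_pat].mean(axis=1)
    mean_ctrl = beta_arr[:, ~is_pat].mean(axis=1)
    table = fit.drop(columns="df").assign(
        q_value=q,
        mean_beta_patients=mean_pat,
        mean_beta_controls=mean_ctrl,
        effect_size_pct=100.0 * (mean_pat - mean_ctrl),
        direction=np.where(fit["delta_m"] < 0, "hypo", "hyper"),
    )
    return DmpTable(table[q < fdr].copy(), fdr)
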