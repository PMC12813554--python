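"""Methylation-expression correlation enrichment (eQTM-style).

Every DMP's beta-values are Spearman-correlated with every RNA's normalized
expression across the shared samples (cis and trans alike; no distance
restriction).  For a group of RNAs the summary statistic is the proportion of
DMP-RNA pairs with |rho| strictly above a relevance threshold (default 0.3);
groups are compared with a pooled two-proportion Z-test on those counts and,
over the full rho distributions, with the asymptotic two-sample
Kolmogorov-Smirnov test.

Pairs are pooled as independent observations in the Z-test; the intra-probe /
intra-RNA dependence this ignores is a deliberate fidelity choice, documented
in the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._lm import aliased_columns, ols_fit
from .datasets import PATHWAYS, ExpressionDataset, SampleSheet
from .dmp import bh_adjust

logger = logging.getLogger(__name__)

#: double-precision p-value floor mirrored in report rendering
P_FLOOR = 2.220446e-16

DEFAULT_TAU = 0.3


def format_p(p: float) -> str:
    """Render a p-value, flooring below double precision as '< 2.2e-16'."""
    return "< 2.2e-16" if p < P_FLOOR else f"{p:.4g}"


# ---------------------------------------------------------------------------
# RNA labelling (simplified stand-ins for the upstream transcriptome study)
# ---------------------------------------------------------------------------

def label_dernas(
    expr: ExpressionDataset, sheet: SampleSheet, fdr: float = 0.05
) -> pd.DataFrame:
    """Flag differentially expressed RNAs (patients vs controls).

    Per-RNA OLS of expression on [intercept, group, age, sex, BMI] with BH
    across RNAs; ``derna`` = q < fdr.  Returns a DataFrame indexed by RNA id
    with columns delta, t_stat, p_value, q_value, derna.
    """
    from .dmp import _dmp_design  # same design as the methylation stage

    mat = expr.expr.loc[:, sheet.sample_ids]
    X, names = _dmp_design(sheet)
    bad = aliased_columns(X, names)
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    coef, _, t, p, *_ = ols_fit(mat.to_numpy(dtype=float).T, X)
    g = names.index("group")
    q = bh_adjust(p[g])
    return pd.DataFrame(
        {"delta": coef[g], "t_stat": t[g], "p_value": p[g], "q_value": q,
         "derna": q < fdr},
        index=mat.index.rename("rna_id"),
    )


def label_strength_association(
    expr: ExpressionDataset,
    strength: pd.Series,
    fdr: float = 0.05,
    derna_flags: pd.Series | None = None,
) -> pd.DataFrame:
    """Flag DERNAs whose expression correlates with muscle strength.

    Spearman rho of each RNA's expression against ``strength`` over the
    samples where strength is available (patients), BH across DERNAs only;
    non-DERNAs are never flagged.
    """
    if derna_flags is None:
        if expr.labels is None:
            raise ValueError("provide derna_flags or an ExpressionDataset with labels")
        derna_flags = expr.labels["derna"]
    strength = strength.dropna()
    if strength.nunique() <= 1:
        raise ValueError("strength phenotype is constant; association undefined")
    samples = expr.expr.columns.intersection(strength.index)
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 4 samples with a strength value")
    mat = expr.expr.loc[:, samples].to_numpy(dtype=float)
    ranks_e = stats.rankdata(mat, axis=1)
    ranks_s = stats.rankdata(strength.loc[samples].to_numpy(dtype=float))
    re = ranks_e - ranks_e.mean(axis=1, keepdims=True)
    rs = ranks_s - ranks_s.mean()
    denom = np.sqrt((re**2).sum(axis=1) * (rs**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, re @ rs / denom, np.nan)
    # large-sample t approximation for the Spearman p-value
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1 - rho**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    out = pd.DataFrame(
        {"rho": rho, "p_value": p}, index=expr.expr.index.rename("rna_id")
    )
    out["q_value"] = np.nan
    is_derna = derna_flags.reindex(out.index).fillna(False).astype(bool)
    if is_derna.any():
        out.loc[is_derna, "q_value"] = bh_adjust(out.loc[is_derna, "p_value"].to_numpy())
    out["strength_associated"] = is_derna & (out["q_value"] < fdr)
    return out


# ---------------------------------------------------------------------------
# correlation matrix and summary statistics
# ---------------------------------------------------------------------------

def spearman_matrix(
    dmp_betas: pd.DataFrame, expr: pd.DataFrame, chunk_size: int = 512
) -> pd.DataFrame:
    """Spearman rho for every (probe, RNA) pair over the shared ordered samples.

    Rows are rank-transformed (average ties) and correlated as Pearson on
    ranks, chunked over probes to bound memory.  Constant rows yield NaN,
    excluded from downstream counts with a logged tally.
    """
    if not dmp_betas.columns.equals(expr.columns):
        raise ValueError("probe and RNA matrices must share an ordered sample set")
    n = dmp_betas.shape[1]
    if n < 4:
        raise ValueError("need at least 4 shared samples")

    def _standardize_ranks(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        r = stats.rankdata(mat, axis=1)
        r -= r.mean(axis=1, keepdims=True)
        norm = np.sqrt((r**2).sum(axis=1))
        ok = norm > 0
        r[ok] /= norm[ok, None]
        r[~ok] = np.nan
        return r, ok

    re, ok_e = _standardize_ranks(expr.to_numpy(dtype=float))
    n_const = int((~ok_e).sum())
    out = np.empty((dmp_betas.shape[0], expr.shape[0]))
    for start in range(0, dmp_betas.shape[0], chunk_size):
        block = dmp_betas.iloc[start : start + chunk_size].to_numpy(dtype=float)
        rb, ok_b = _standardize_ranks(block)
        n_const += int((~ok_b).sum())
        out[start : start + chunk_size] = rb @ re.T
    if n_const:
        logger.info("%d constant rows produced undefined correlations (NaN)", n_const)
    return pd.DataFrame(np.clip(out, -1.0, 1.0), index=dmp_betas.index, columns=expr.index)


def proportion_relevant(
    rho: pd.DataFrame, rna_subset, tau: float = DEFAULT_TAU
) -> tuple[int, int, float]:
    """(n_pairs, n_relevant, proportion) of |rho| strictly > tau within an RNA subset.

    Missing correlations are excluded from numerator and denominator.
    """
    rna_subset = [r for r in rna_subset]
    if not rna_subset:
        raise ValueError("empty RNA group")
    vals = rho.loc[:, rna_subset].to_numpy(dtype=float).ravel()
    vals = vals[~np.isnan(vals)]
    n_pairs = int(vals.size)
    n_relevant = int((np.abs(vals) > tau).sum())
    prop = n_relevant / n_pairs if n_pairs else 0.0
    return n_pairs, n_relevant, prop


@dataclass
class ZTestResult:
    z: float
    p: float
    degenerate: bool = False

    @property
    def p_display(self) -> str:
        return format_p(self.p)

    def __iter__(self):
        return iter((self.z, self.p))


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> ZTestResult:
    """Pooled two-proportion Z-test, two-sided, no continuity correction.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion;
    a pooled proportion of exactly 0 or 1 is degenerate (z = 0, p = 1).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ZTestResult(0.0, 1.0, degenerate=True)
    z = (p1 - p2) / np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.norm.sf(abs(z))
    return ZTestResult(float(z), float(min(p, 1.0)))


@dataclass
class Ecdf:
    """Right-continuous empirical CDF: F(x) = proportion of observations <= x."""

    support: np.ndarray
    cumulative: np.ndarray

    def __call__(self, x):
        idx = np.searchsorted(self.support, np.asarray(x, dtype=float), side="right")
        vals = np.concatenate([[0.0], self.cumulative])[idx]
        return float(vals) if np.isscalar(x) else vals


def ecdf(values) -> Ecdf:
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot build an ECDF from an empty sample")
    support, counts = np.unique(vals, return_counts=True)
    return Ecdf(support, np.cumsum(counts) / vals.size)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Asymptotic two-sample Kolmogorov-Smirnov test.

    D = sup |F_a - F_b| over the pooled support; the p-value uses the
    Kolmogorov asymptotic series Q(lambda) = 2 sum_k (-1)^(k-1) exp(-2 k^2
    lambda^2) at lambda = (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) D with effective
    size ne = na*nb/(na+nb).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    fa, fb = ecdf(a), ecdf(b)
    pooled = np.concatenate([fa.support, fb.support])
    d = float(np.max(np.abs(fa(pooled) - fb(pooled))))
    ne = a.size * b.size / (a.size + b.size)
    lam = (np.sqrt(ne) + 0.12 + 0.11 / np.sqrt(ne)) * d
    k = np.arange(1, 101)
    if lam < 0.3:
        # the alternating series converges too slowly for small lambda; use
        # the theta-function representation (exact limit Q(0) = 1)
        if lam <= 0:
            return d, 1.0
        term = np.exp(-((2 * k - 1) ** 2) * np.pi**2 / (8.0 * lam**2))
        p = 1.0 - np.sqrt(2.0 * np.pi) / lam * term.sum()
    else:
        p = 2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k**2 * lam**2))
    return d, float(np.clip(p, 0.0, 1.0))


# ---------------------------------------------------------------------------
# the comparison grid
# ---------------------------------------------------------------------------

@dataclass
class CorrelationEnrichmentResult:
    """Per-RNA-group pair counts and the pairwise comparison statistics.

    ``groups``: one row per RNA group (n_rnas, n_pairs, n_relevant,
    proportion).  ``comparisons``: one row per compared pair with the pooled
    Z statistic/p and the KS D/p, plus floored display strings.
    """

    groups: pd.DataFrame
    comparisons: pd.DataFrame
    tau: float

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "groups": self.groups.to_dict(orient="records"),
            "comparisons": self.comparisons.to_dict(orient="records"),
        }


def _group_values(rho: pd.DataFrame, rna_ids) -> np.ndarray:
    vals = rho.loc[:, list(rna_ids)].to_numpy(dtype=float).ravel()
    return vals[~np.isnan(vals)]


def compare_rna_groups(
    rho: pd.DataFrame, labels: pd.DataFrame, tau: float = DEFAULT_TAU
) -> CorrelationEnrichmentResult:
    """Run the full RNA-group comparison grid on a DMP x RNA rho matrix.

    Groups: DERNA vs non-DERNA; strength-associated vs non-strength DERNAs;
    and within each labelled pathway (mitochondrial, lipid, fibrosis) the
    strength vs non-strength split.  A comparison with an empty side is
    skipped and logged.
    """
    labels = labels.reindex(rho.columns)
    derna = labels["derna"].fillna(False).astype(bool)
    strength = labels["strength_associated"].fillna(False).astype(bool)
    pathway = labels["pathway"].fillna("none")

    group_defs: dict[str, pd.Index] = {
        "derna": rho.columns[derna],
        "non_derna": rho.columns[~derna],
        "strength": rho.columns[derna & strength],
        "non_strength": rho.columns[derna & ~strength],
    }
    for pw in PATHWAYS:
        mask = derna & pathway.eq(pw)
        group_defs[f"{pw}_strength"] = rho.columns[mask & strength]
        group_defs[f"{pw}_non_strength"] = rho.columns[mask & ~strength]

    plan = [("derna", "non_derna"), ("strength", "non_strength")]
    plan += [(f"{pw}_strength", f"{pw}_non_strength") for pw in PATHWAYS]

    group_rows, stats_cache = [], {}
    for name, ids in group_defs.items():
        if len(ids) == 0:
            continue
        n_pairs, n_rel, prop = proportion_relevant(rho, ids, tau)
        stats_cache[name] = (n_pairs, n_rel, prop, _group_values(rho, ids))
        group_rows.append(
            {"group": name, "n_rnas": len(ids), "n_pairs": n_pairs,
             "n_relevant": n_rel, "proportion": prop}
        )

    cmp_rows = []
    for g1, g2 in plan:
        if g1 not in stats_cache or g2 not in stats_cache:
            logger.warning("comparison %s vs %s skipped: empty group", g1, g2)
            continue
        n1, x1, p1, v1 = stats_cache[g1]
        n2, x2, p2, v2 = stats_cache[g2]
        zres = two_proportion_ztest(x1, n1, x2, n2)
        d, ks_p = ks_two_sample(v1, v2)
        cmp_rows.append(
            {"group1": g1, "group2": g2,
             "proportion1": p1, "proportion2": p2,
             "z_stat": zres.z, "z_p": zres.p, "z_p_display": format_p(zres.p),
             "ks_D": d, "ks_p": ks_p, "ks_p_display": format_p(ks_p)}
        )
    return CorrelationEnrichmentResult(
        pd.DataFrame(group_rows), pd.DataFrame(cmp_rows), tau
    )
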