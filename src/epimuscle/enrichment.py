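"""Gene-set over-representation analysis (ORA), plain and probe-bias corrected.

Two tail tests per category, both against a universe of genes carried on the
(QC-filtered) array rather than the genome:

* ``ora_hypergeometric`` — classic one-sided upper-tail hypergeometric test
  on selected-gene overlap (EnrichR-style, gene level).
* ``ora_probe_bias`` — genes carry unequal numbers of CpG probes, so genes
  with more probes are more likely to harbour at least one selected probe.
  The null is therefore a biased urn: Wallenius' noncentral hypergeometric
  distribution with odds omega = (mean probe count of in-category genes) /
  (mean probe count of out-of-category genes).  With equal probe counts
  (omega = 1) this reduces exactly to the central hypergeometric test.

q-values are BH-adjusted within each call, mirroring separate per-database
runs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ProbeAnnotation
from .dmp import bh_adjust

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["category_id", "n_category_genes", "n_overlap", "p_value", "q_value", "method"]


def _finalize(rows: list[dict], method: str) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS[:4])
    df["q_value"] = bh_adjust(df["p_value"].to_numpy()) if len(df) else []
    df["method"] = method
    return df


def ora_hypergeometric(
    selected_genes: set[str],
    universe: set[str],
    categories: dict[str, set[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric ORA of ``selected_genes`` against ``universe``.

    Category gene sets are intersected with the universe; p = P(overlap >= k)
    includes the observed overlap, so a disjoint category yields p = 1.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not selected_genes <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    N, n = len(universe), len(selected_genes)
    rows = []
    for cid, genes in categories.items():
        cat = genes & universe
        K = len(cat)
        if K == 0:
            logger.warning("category '%s' has no genes in the universe; skipped", cid)
            continue
        k = len(selected_genes & cat)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"category_id": cid, "n_category_genes": K, "n_overlap": k,
             "p_value": min(p, 1.0)}
        )
    return _finalize(rows, "hypergeometric")


def wallenius_upper_tail(N: int, K: int, n: int, k: int, omega: float) -> float:
    """P(X >= k) for Wallenius' noncentral hypergeometric (N genes, K in
    category, n drawn, odds ``omega`` favouring category genes)."""
    if n == 0 or K == 0:
        return 1.0 if k <= 0 else 0.0
    if omega == 1.0:
        return float(stats.hypergeom.sf(k - 1, N, K, n))
    dist = stats.nchypergeom_wallenius(N, K, n, omega)
    return float(np.clip(dist.sf(k - 1), 0.0, 1.0))


def ora_probe_bias(
    selected_probes: set[str],
    all_probes: set[str],
    ann: ProbeAnnotation,
    categories: dict[str, set[str]],
) -> pd.DataFrame:
    """Probe-count-bias-corrected ORA at gene level.

    The universe is every gene with >= 1 probe among ``all_probes``; a gene is
    selected when it carries >= 1 probe from ``selected_probes``.  Per
    category the selection bias is summarized by the odds omega defined in the
    module docstring and the upper-tail p comes from Wallenius' distribution.
    """
    if not selected_probes <= all_probes:
        raise ValueError("selected probes must be a subset of the background probes")
    ann.require_probes(all_probes)
    probe_counts = ann.probes_per_gene(all_probes)
    if probe_counts.empty:
        raise ValueError("no gene has a probe in the background set")
    universe = set(probe_counts.index)
    selected_genes = set(ann.links_for(selected_probes)["gene_id"].unique())
    N, n = len(universe), len(selected_genes)
    rows = []
    for cid, genes in categories.items():
        cat = genes & universe
        K = len(cat)
        if K == 0:
            logger.warning("category '%s' has no genes in the universe; skipped", cid)
            continue
        k = len(selected_genes & cat)
        in_mean = probe_counts.loc[sorted(cat)].mean()
        out_genes = universe - cat
        out_mean = probe_counts.loc[sorted(out_genes)].mean() if out_genes else in_mean
        omega = float(in_mean / out_mean)
        p = wallenius_upper_tail(N, K, n, k, omega)
        rows.append(
            {"category_id": cid, "n_category_genes": K, "n_overlap": k,
             "p_value": min(max(p, np.finfo(float).tiny), 1.0)}
        )
    return _finalize(rows, "wallenius")
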