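"""Probe-level quality-control filters and stratified quantile normalization.

Filters mirror standard EPIC-array preprocessing: drop probes whose signal is
poorly detected above background in a large share of samples, and drop probes
overlapping known SNPs.  Both filters only remove probes, so they commute.

Quantile normalization here operates on beta matrices (raw intensities are
out of scope): within each probe stratum (by default the Infinium probe-type
column of the annotation) every sample's values are replaced by the mean
order statistics across samples, preserving within-sample ranks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datasets import MethylationDataset, ProbeAnnotation

logger = logging.getLogger(__name__)


def filter_probes_by_detection(
    ds: MethylationDataset,
    p_threshold: float = 0.01,
    sample_fraction: float = 0.5,
) -> MethylationDataset:
    """Remove probes with detection p > ``p_threshold`` in >= ``sample_fraction`` of samples.

    The per-cell rule is applied exactly: a probe is excluded when the number
    of samples whose detection p exceeds the threshold reaches the given
    fraction of all samples.  Raises if no detection-p matrix is present; pass
    the dataset through unchanged to skip the filter explicitly.
    """
    if ds.detection_p is None:
        raise ValueError(
            "dataset has no detection_p matrix; skip this filter explicitly "
            "if detection p-values are unavailable"
        )
    failed = (ds.detection_p.to_numpy(dtype=float) > p_threshold).mean(axis=1)
    keep = failed < sample_fraction
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("detection filter removed %d/%d probes", n_removed, ds.n_probes)
    return MethylationDataset(ds.beta.loc[keep], ds.detection_p.loc[keep])


def filter_snp_probes(ds: MethylationDataset, ann: ProbeAnnotation) -> MethylationDataset:
    """Remove probes flagged as overlapping a known SNP.

    Every probe in the dataset must be annotated; flags on probes absent from
    the dataset are ignored.
    """
    ann.require_probes(ds.probe_ids)
    flagged = ann.snp_probe_ids()
    keep = ~ds.probe_ids.isin(flagged)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("SNP filter removed %d/%d probes", n_removed, ds.n_probes)
    dp = ds.detection_p.loc[keep] if ds.detection_p is not None else None
    return MethylationDataset(ds.beta.loc[keep], dp)


def quantile_normalize_stratified(
    ds: MethylationDataset,
    strata: pd.Series | None = None,
    ann: ProbeAnnotation | None = None,
    clamp_eps: float = 1e-6,
) -> MethylationDataset:
    """Classical quantile normalization applied separately within probe strata.

    ``strata`` maps probe id -> stratum label; if omitted, the annotation's
    ``probe_type`` column is used.  Within a stratum, each sample's values are
    replaced by the mean order statistics across samples (ties receive the
    mean of the reference values at the tied ranks).  Output is clamped into
    (0, 1).
    """
    if strata is None:
        if ann is None:
            raise ValueError("provide either a strata series or an annotation")
        strata = ann.probes["probe_type"]
    strata = strata.reindex(ds.probe_ids)
    if strata.isna().any():
        missing = ds.probe_ids[strata.isna()].tolist()[:10]
        raise ValueError(f"probes without a stratum assignment: {missing}")

    beta = ds.beta.to_numpy(dtype=float).copy()
    for label, idx in pd.Series(range(ds.n_probes), index=ds.probe_ids).groupby(strata):
        rows = idx.to_numpy()
        if rows.size == 0:
            logger.warning("empty stratum '%s' skipped", label)
            continue
        block = beta[rows, :]
        ref = np.sort(block, axis=0).mean(axis=1)  # mean order statistics
        # average-rank assignment: interpolate the reference at fractional ranks
        ranks = pd.DataFrame(block).rank(axis=0, method="average").to_numpy()
        beta[rows, :] = np.interp(ranks - 1.0, np.arange(ref.size), ref)
    beta = np.clip(beta, clamp_eps, 1.0 - clamp_eps)
    out = pd.DataFrame(beta, index=ds.probe_ids, columns=ds.sample_ids)
    return MethylationDataset(out, ds.detection_p)
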