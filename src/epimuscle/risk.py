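"""Risk-factor association with abnormal methylation at called DMPs.

For each DMP one joint multivariable OLS model is fitted among patients,
with the probe's beta-value as dependent variable and all candidate risk
factors (demographics, ICU exposures, follow-up medication) as regressors.
Associations at unadjusted p < 0.05 are classified by direction: a negative
factor coefficient at a hypomethylated DMP, or a positive coefficient at a
hypermethylated DMP, pushes methylation further from the control mean and is
therefore "harmful"; the opposite signs are "protective".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lm import aliased_columns, ols_fit
from .datasets import SampleSheet
from .dmp import DmpTable

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "probe_id", "factor", "coefficient", "p_value", "significant",
    "dmp_direction", "classification",
]


def classify_direction(coefficient: float, dmp_direction: str) -> str | None:
    """Harmful/protective call for a significant factor association.

    harmful iff (hypo and coefficient < 0) or (hyper and coefficient > 0);
    a zero coefficient is undefined (None) and excluded with a tally.
    """
    if dmp_direction not in ("hypo", "hyper"):
        raise ValueError(f"unknown DMP direction '{dmp_direction}'")
    if coefficient == 0:
        return None
    toward_abnormal = (coefficient < 0) == (dmp_direction == "hypo")
    return "harmful" if toward_abnormal else "protective"


def _build_factor_design(
    sheet_patients: pd.DataFrame,
    factors: list[str],
    categorical_references: dict[str, str] | None,
) -> pd.DataFrame:
    """Numeric design block for the requested factors (dummy-coded categoricals)."""
    categorical_references = categorical_references or {}
    cols = {}
    for f in factors:
        if f not in sheet_patients.columns:
            raise ValueError(f"factor '{f}' is not a sample-sheet column")
        col = sheet_patients[f]
        if col.isna().any():
            raise ValueError(f"factor '{f}' has missing values among patients")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.unique())
            if f == "sex":
                cols["sex"] = col.eq("female").astype(float)
                continue
            ref = categorical_references.get(f, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level '{ref}' not found for factor '{f}'")
            for lev in levels:
                if lev != ref:
                    cols[f"{f}[{lev}]"] = col.eq(lev).astype(float)
        else:
            cols[f] = col.astype(float)
    return pd.DataFrame(cols, index=sheet_patients.index)


def fit_risk_models(
    beta_dmps: pd.DataFrame,
    sheet: SampleSheet,
    factors: list[str],
    dmp_directions: pd.Series,
    p_threshold: float = 0.05,
    categorical_references: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Joint per-DMP OLS of beta on all factors, among patients only.

    Constant factor columns are dropped with a warning; remaining rank
    deficiency (perfectly collinear factors) is resolved by dropping the
    later column of each aliased pair, also with a warning.  Returns one row
    per (probe, retained factor term) with the classification filled for
    significant associations.
    """
    patients = sheet.data[sheet.is_patient()]
    if len(patients) < 3:
        raise ValueError("need at least 3 patients to fit risk-factor models")
    design = _build_factor_design(patients, factors, categorical_references)

    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        logger.warning("dropping constant factor column(s): %s", constant)
        design = design.drop(columns=constant)
    if design.shape[1] == 0:
        raise ValueError("no non-constant factor remains")

    names = ["intercept"] + list(design.columns)
    X = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    bad = aliased_columns(X, names)
    if bad:
        logger.warning("dropping aliased factor column(s): %s", bad)
        design = design.drop(columns=bad)
        names = ["intercept"] + list(design.columns)
        X = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
        still_bad = aliased_columns(X, names)
        if still_bad:
            raise ValueError(f"design remains rank deficient after dropping: {still_bad}")

    Y = beta_dmps.loc[:, patients.index].to_numpy(dtype=float).T
    coef, _, _, p, *_ = ols_fit(Y, X)

    directions = dmp_directions.reindex(beta_dmps.index)
    if directions.isna().any():
        missing = beta_dmps.index[directions.isna()].tolist()[:5]
        raise ValueError(f"no DMP direction for probes {missing}")

    rows, n_zero = [], 0
    factor_names = list(design.columns)
    for j, factor in enumerate(factor_names, start=1):  # skip the intercept
        for i, probe in enumerate(beta_dmps.index):
            c, pv = float(coef[j, i]), float(p[j, i])
            sig = pv < p_threshold
            cls = None
            if sig:
                cls = classify_direction(c, directions.iloc[i])
                if cls is None:
                    n_zero += 1
                    sig = False
            rows.append((probe, factor, c, pv, sig, directions.iloc[i], cls))
    if n_zero:
        logger.info("%d significant associations had a zero coefficient; excluded", n_zero)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


@dataclass
class FactorSummary:
    """Per factor x direction-stratum association counts and harmful/protective split."""

    df: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def summarize_factors(results: pd.DataFrame) -> FactorSummary:
    """Summarize significant associations per factor, split by DMP direction.

    Emits per (factor, stratum in {hypo, hyper}) and per (factor, 'all') the
    number of associations and the percentage classified harmful/protective.
    """
    sig = results[results["significant"] & results["classification"].notna()]
    rows = []
    if len(sig):
        for factor, sub in sig.groupby("factor"):
            strata = [("hypo", sub[sub["dmp_direction"].eq("hypo")]),
                      ("hyper", sub[sub["dmp_direction"].eq("hyper")]),
                      ("all", sub)]
            for stratum, block in strata:
                n = len(block)
                if n == 0:
                    continue
                n_harm = int(block["classification"].eq("harmful").sum())
                rows.append(
                    {"factor": factor, "stratum": stratum, "n_associations": n,
                     "pct_harmful": 100.0 * n_harm / n,
                     "pct_protective": 100.0 * (n - n_harm) / n}
                )
    return FactorSummary(
        pd.DataFrame(rows, columns=["factor", "stratum", "n_associations",
                                    "pct_harmful", "pct_protective"])
    )
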