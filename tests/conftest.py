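import numpy as np
import pandas as pd
import pytest

import epimuscle as em


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    cfg = em.CohortConfig(
        seed=11, n_patients=60, n_controls=20, n_probes=400, n_rnas=300
    )
    meth, sheet, expr, ann, truth = em.generate_cohort(cfg)
    return cfg, meth, sheet, expr, ann, truth


@pytest.fixture(scope="session")
def small_dmps(small_cohort):
    """QC-filtered dataset and called DMPs for the small cohort."""
    _, meth, sheet, _, ann, _ = small_cohort
    ds = em.filter_snp_probes(em.filter_probes_by_detection(meth), ann)
    fit = em.fit_dmp_models(em.beta_to_m(ds.beta), sheet)
    dmps = em.call_dmps(fit, ds.beta, sheet, fdr=0.05)
    return ds, dmps


@pytest.fixture()
def tiny_sheet():
    """Six-sample hand-built sample sheet (balanced groups)."""
    return em.SampleSheet(
        pd.DataFrame(
            {
                "group": ["patient"] * 3 + ["control"] * 3,
                "age": [50.0, 60.0, 70.0, 52.0, 61.0, 69.0],
                "sex": ["male", "female", "male", "male", "female", "male"],
                "bmi": [25.0, 27.0, 29.0, 24.0, 28.0, 30.0],
            },
            index=pd.Index([f"S{i}" for i in range(6)], name="sample_id"),
        )
    )


def make_methylation(beta_rows: dict, samples: list, detection_rows: dict | None = None):
    """Small MethylationDataset builder for rule-level tests."""
    beta = pd.DataFrame.from_dict(beta_rows, orient="index", columns=samples)
    dp = None
    if detection_rows is not None:
        dp = pd.DataFrame.from_dict(detection_rows, orient="index", columns=samples)
    return em.MethylationDataset(beta, dp)
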