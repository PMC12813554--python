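"""Seeded synthetic-cohort generator with planted ground truth.

The generator emulates the statistical structure of a long-term follow-up
methylation/transcriptome study of former ICU patients versus controls:

* probe baseline betas drawn from a bimodal mixture (mostly near 0.1 or 0.9,
  an intermediate minority), per-sample variation as Gaussian noise on the
  M scale;
* a planted set of true DMPs with signed beta-scale shifts in the patient
  group whose mean and maximum absolute effect match configured targets;
* age/sex/BMI covariates with overlapping patient/control distributions and
  planted covariate effects on a probe subset (confounding that the adjusted
  models must absorb);
* a DERNA subset of RNAs with a two-fold expression shift, each coupled to a
  planted DMP through a shared latent signal calibrated to a target Spearman
  correlation; a strength-coupled DERNA sub-subset sharing a latent factor
  that also drives the strength phenotype;
* binary/duration ICU exposure variables with planted "harmful" methylation
  effects (pushing planted DMPs further from the control mean);
* a detection-p matrix that is ~0 almost everywhere with a configurable
  fraction of failed cells and wholly failed probes.

All randomness flows from one seed through per-stage child seeds, so equal
configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import (
    PATHWAYS,
    REGION_GROUPS,
    ExpressionDataset,
    MethylationDataset,
    ProbeAnnotation,
    SampleSheet,
    write_annotation,
    write_expression,
    write_gmt,
    write_matrix_tsv,
    write_sample_sheet,
)
from .transforms import beta_to_m, m_to_beta


@dataclass
class Exposure:
    """One ICU exposure variable: binary (yes/no) or duration (days)."""

    name: str
    kind: str  # "binary" | "duration"
    effect: float  # beta-units per unit exposure, applied to affected probes
    prevalence: float  # fraction of patients with non-zero exposure

    def validate(self) -> None:
        if self.kind not in ("binary", "duration"):
            raise ValueError(f"exposure '{self.name}': kind must be binary or duration")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"exposure '{self.name}': prevalence must lie in [0, 1]")
        if self.effect < 0:
            raise ValueError(f"exposure '{self.name}': effect must be non-negative")


def _default_exposures() -> list[Exposure]:
    return [
        Exposure("glucocorticoids", "binary", 0.030, 0.29),
        Exposure("early_pn", "binary", 0.020, 0.52),
        Exposure("benzodiazepine_days", "duration", 0.004, 0.55),
        Exposure("opioid_days", "duration", 0.003, 0.80),
    ]


@dataclass
class CohortConfig:
    """Study conditions of the emulated cohort (defaults follow the study design)."""

    n_patients: int = 118
    n_controls: int = 30
    n_probes: int = 2000
    n_rnas: int = 2000
    frac_true_dmps: float = 0.15
    mean_abs_delta_beta: float = 0.026
    max_abs_delta_beta: float = 0.25
    frac_hypo: float = 0.636
    frac_dernas: float = 0.175
    frac_strength_coupled: float = 163.0 / 350.0
    coupling_rho: float = 0.5
    noise_sd_m: float = 0.5
    expr_shift_log2: float = 1.0
    expr_noise_sd: float = 1.0
    exposures: list[Exposure] = field(default_factory=_default_exposures)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.0008, "sex": 0.02, "bmi": 0.0015}
    )
    frac_covariate_probes: float = 0.2
    exposure_probe_frac: float = 0.3
    frac_failed_cells: float = 0.002
    frac_failed_probes: float = 0.005
    frac_intergenic: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "frac_true_dmps", "frac_hypo", "frac_dernas", "frac_strength_coupled",
            "frac_covariate_probes", "exposure_probe_frac", "frac_failed_cells",
            "frac_failed_probes", "frac_intergenic",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_controls < 3:
            raise ValueError(f"n_controls must be >= 3, got {self.n_controls}")
        if self.n_patients < 3:
            raise ValueError(f"n_patients must be >= 3, got {self.n_patients}")
        if self.n_probes < 10:
            raise ValueError(f"n_probes must be >= 10, got {self.n_probes}")
        if self.n_rnas < 1:
            raise ValueError(f"n_rnas must be >= 1, got {self.n_rnas}")
        if not (0.0 <= self.mean_abs_delta_beta <= self.max_abs_delta_beta <= 0.5):
            raise ValueError(
                "need 0 <= mean_abs_delta_beta <= max_abs_delta_beta <= 0.5, got "
                f"mean_abs_delta_beta={self.mean_abs_delta_beta}, "
                f"max_abs_delta_beta={self.max_abs_delta_beta}"
            )
        if not -1.0 <= self.coupling_rho <= 1.0:
            raise ValueError(f"coupling_rho must lie in [-1, 1], got {self.coupling_rho}")
        if self.noise_sd_m <= 0:
            raise ValueError(f"noise_sd_m must be positive, got {self.noise_sd_m}")
        for exp in self.exposures:
            exp.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "exposures" in d:
            d["exposures"] = [
                e if isinstance(e, Exposure) else Exposure(**e) for e in d["exposures"]
            ]
        return cls(**d)


@dataclass
class SimulationTruth:
    """Planted ground truth for recovery tests."""

    true_dmps: pd.Series  # probe_id -> signed delta-beta
    true_derna_ids: set[str]
    coupling_map: pd.DataFrame  # columns probe_id, rna_id, rho_target
    strength_coupled_rna_ids: set[str]
    exposure_effect_map: pd.DataFrame  # columns exposure, probe_id, effect

    def true_dmp_ids(self) -> set[str]:
        return set(self.true_dmps.index)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.true_dmps.rename("delta_beta").to_csv(
            outdir / "truth_dmps.tsv", sep="\t", index_label="probe_id"
        )
        pd.DataFrame(
            {
                "rna_id": sorted(self.true_derna_ids),
                "strength_coupled": [
                    r in self.strength_coupled_rna_ids
                    for r in sorted(self.true_derna_ids)
                ],
            }
        ).to_csv(outdir / "truth_rnas.tsv", sep="\t", index=False)
        self.coupling_map.to_csv(outdir / "truth_coupling.tsv", sep="\t", index=False)
        self.exposure_effect_map.to_csv(
            outdir / "truth_exposures.tsv", sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

_CHROMOSOMES = [f"chr{i}" for i in range(1, 23)] + ["chrX"]
_REGION_PROBS = (0.25, 0.20, 0.10, 0.35, 0.10)  # TSS200, TSS1500, 5UTR, Body, 3UTR
_SNP_FRAC = 0.02
_TYPE_I_FRAC = 0.16


def generate_probe_annotation(
    n_probes: int,
    n_genes: int,
    frac_intergenic: float = 0.7,
    seed: int = 0,
) -> ProbeAnnotation:
    """Manifest-style annotation: probe positions, gene links, SNP flags, probe type.

    Each non-intergenic probe receives 1-3 gene links, each with a region
    group; ~2% of probes are flagged as SNP-overlapping; intergenic probes
    (a Bernoulli(frac_intergenic) draw per probe) carry no links.
    """
    if n_probes <= 0 or n_genes <= 0:
        raise ValueError("n_probes and n_genes must be positive")
    if not 0.0 <= frac_intergenic <= 1.0:
        raise ValueError(f"frac_intergenic must lie in [0, 1], got {frac_intergenic}")
    rng = np.random.default_rng(seed)
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    genes = [f"G{i:05d}" for i in range(n_genes)]
    probes = pd.DataFrame(
        {
            "chromosome": rng.choice(_CHROMOSOMES, size=n_probes),
            "position": rng.integers(10_000, 200_000_000, size=n_probes),
            "snp_flag": rng.random(n_probes) < _SNP_FRAC,
            "probe_type": np.where(rng.random(n_probes) < _TYPE_I_FRAC, "I", "II"),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    intergenic = rng.random(n_probes) < frac_intergenic
    rows = []
    for i in np.flatnonzero(~intergenic):
        n_links = rng.choice([1, 2, 3], p=[0.70, 0.20, 0.10])
        linked = rng.choice(n_genes, size=n_links, replace=False)
        regions = rng.choice(REGION_GROUPS, size=n_links, p=_REGION_PROBS)
        for g, r in zip(linked, regions):
            rows.append((probe_ids[i], genes[g], r))
    links = pd.DataFrame(rows, columns=["probe_id", "gene_id", "region_group"])
    return ProbeAnnotation(probes, links)


def generate_categories(
    ann: ProbeAnnotation,
    n_categories: int = 40,
    size_range: tuple[int, int] = (10, 120),
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random gene-set categories over the annotation's genes (GMT fixture)."""
    genes = sorted(ann.links["gene_id"].unique())
    if not genes:
        return {}
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    hi = min(hi, len(genes))
    cats = {}
    for i in range(n_categories):
        size = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        size = min(size, len(genes))
        cats[f"CAT{i:03d}"] = set(rng.choice(genes, size=size, replace=False))
    return cats


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _sample_baseline_mixture(rng: np.random.Generator, size: int) -> np.ndarray:
    """Bimodal beta baselines: low mode ~0.1, high mode ~0.9, intermediate minority."""
    comp = rng.choice(3, size=size, p=[0.44, 0.44, 0.12])
    out = np.empty(size)
    out[comp == 0] = rng.beta(2.5, 22.0, size=(comp == 0).sum())
    out[comp == 1] = rng.beta(22.0, 2.5, size=(comp == 1).sum())
    out[comp == 2] = rng.beta(4.0, 4.0, size=(comp == 2).sum())
    return np.clip(out, 0.02, 0.98)


def _planted_magnitudes(
    rng: np.random.Generator, n: int, mean_abs: float, max_abs: float
) -> np.ndarray:
    """|delta-beta| draws with sample mean == mean_abs and sample max == max_abs.

    Magnitudes are exponential (most effects small, a thin tail of large
    ones), truncated at the maximum; when enough probes are planted the
    largest draw is pinned to the maximum and the rest rescaled so the mean
    is exact.
    """
    if n == 0 or mean_abs == 0:
        return np.zeros(n)
    mags = rng.exponential(scale=mean_abs, size=n)
    mags = np.minimum(np.maximum(mags, 1e-4), max_abs)
    total_target = mean_abs * n
    if n >= 2 and total_target > 1.5 * max_abs:
        top = int(np.argmax(mags))
        rest = np.delete(np.arange(n), top)
        rest_target = total_target - max_abs
        mags[rest] *= rest_target / mags[rest].sum()
        mags[rest] = np.minimum(mags[rest], max_abs)  # guard; negligible at defaults
        mags[top] = max_abs
    else:
        mags *= total_target / mags.sum()
        mags = np.minimum(mags, max_abs)
    return mags


def _compatible_baselines(
    rng: np.random.Generator, deltas: np.ndarray
) -> np.ndarray:
    """Baselines for planted probes resampled from the mixture until the
    shifted patient mean stays inside (0.02, 0.98)."""
    out = np.empty(deltas.size)
    for i, d in enumerate(deltas):
        for _ in range(200):
            b = _sample_baseline_mixture(rng, 1)[0]
            if 0.02 < b + d < 0.98:
                out[i] = b
                break
        else:
            lo = max(0.02, 0.02 - d) + 1e-3
            hi = min(0.98, 0.98 - d) - 1e-3
            out[i] = rng.uniform(lo, hi)
    return out


def generate_cohort(
    config: CohortConfig,
) -> tuple[MethylationDataset, SampleSheet, ExpressionDataset, ProbeAnnotation, SimulationTruth]:
    """Generate one synthetic cohort; equal configs give identical outputs."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    kids = ss.spawn(6)
    ann_seed = int(kids[0].generate_state(1)[0])
    rng_samp = np.random.default_rng(kids[1])
    rng_meth = np.random.default_rng(kids[2])
    rng_expr = np.random.default_rng(kids[3])
    rng_det = np.random.default_rng(kids[4])
    rng_str = np.random.default_rng(kids[5])

    n_pat, n_ctl = config.n_patients, config.n_controls
    n_samples = n_pat + n_ctl
    n_genes = max(config.n_probes // 3, 10)
    ann = generate_probe_annotation(
        config.n_probes, n_genes, config.frac_intergenic, seed=ann_seed
    )
    probe_ids = ann.probe_ids

    # --- sample sheet -----------------------------------------------------
    sample_ids = [f"P{i + 1:03d}" for i in range(n_pat)] + [
        f"C{i + 1:03d}" for i in range(n_ctl)
    ]
    is_pat = np.array([1.0] * n_pat + [0.0] * n_ctl)
    age = np.concatenate(
        [
            np.clip(rng_samp.normal(58.0, 11.0, n_pat), 25, 88),
            np.clip(rng_samp.normal(61.0, 6.0, n_ctl), 40, 82),
        ]
    ).round(0)
    sex_male = np.concatenate(
        [rng_samp.random(n_pat) < 0.796, rng_samp.random(n_ctl) < 0.767]
    )
    bmi = np.concatenate(
        [
            np.clip(rng_samp.normal(27.5, 4.5, n_pat), 17, 45),
            np.clip(rng_samp.normal(26.3, 3.2, n_ctl), 18, 38),
        ]
    ).round(1)
    sheet_df = pd.DataFrame(
        {
            "group": np.where(is_pat == 1.0, "patient", "control"),
            "age": age,
            "sex": np.where(sex_male, "male", "female"),
            "bmi": bmi,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    exposure_values = {}
    for exp in config.exposures:
        vals = np.zeros(n_samples)
        on = rng_samp.random(n_pat) < exp.prevalence
        if exp.kind == "binary":
            vals[:n_pat] = on.astype(float)
        else:  # duration in days
            days = np.minimum(np.round(rng_samp.exponential(6.0, n_pat)) + 1.0, 30.0)
            vals[:n_pat] = np.where(on, days, 0.0)
        exposure_values[exp.name] = vals
        sheet_df[exp.name] = vals

    # --- planted methylation structure ------------------------------------
    base = _sample_baseline_mixture(rng_meth, config.n_probes)
    n_true = int(round(config.frac_true_dmps * config.n_probes))
    planted_idx = np.sort(
        rng_meth.choice(config.n_probes, size=n_true, replace=False)
    )
    mags = _planted_magnitudes(
        rng_meth, n_true, config.mean_abs_delta_beta, config.max_abs_delta_beta
    )
    signs = np.where(rng_meth.random(n_true) < config.frac_hypo, -1.0, 1.0)
    deltas = signs * mags
    base[planted_idx] = _compatible_baselines(rng_meth, deltas)

    delta_full = np.zeros(config.n_probes)
    delta_full[planted_idx] = deltas

    # covariate effects on a probe subset (per covariate), centred values
    cov_numeric = {
        "age": age - age.mean(),
        "sex": (~sex_male).astype(float) - (~sex_male).mean(),
        "bmi": bmi - bmi.mean(),
    }
    cov_term = np.zeros((config.n_probes, n_samples))
    n_cov = int(round(config.frac_covariate_probes * config.n_probes))
    for cov, eff in config.covariate_effects.items():
        if cov not in cov_numeric or eff == 0 or n_cov == 0:
            continue
        idx = rng_meth.choice(config.n_probes, size=n_cov, replace=False)
        sign = rng_meth.choice([-1.0, 1.0], size=n_cov)
        cov_term[idx] += np.outer(sign * eff, cov_numeric[cov])

    # exposure effects: push a subset of planted probes further from control
    exp_rows = []
    exp_term = np.zeros((config.n_probes, n_samples))
    n_exp_probes = int(round(config.exposure_probe_frac * n_true))
    for exp in config.exposures:
        if n_exp_probes == 0 or exp.effect == 0:
            continue
        chosen = rng_meth.choice(planted_idx, size=n_exp_probes, replace=False)
        for i in chosen:
            signed = float(np.sign(delta_full[i]) * exp.effect)
            exp_term[i] += signed * exposure_values[exp.name]
            exp_rows.append((exp.name, probe_ids[i], signed))
    exposure_effect_map = pd.DataFrame(
        exp_rows, columns=["exposure", "probe_id", "effect"]
    )

    # Per-sample disease severity scales the planted shifts: patients vary in
    # how abnormal their methylation is (mean 1, so the average patient shift
    # equals the configured delta), controls sit at 0.  The same severity
    # drives the strength phenotype and the strength-coupled RNAs, creating
    # within-patient covariation between methylation, expression and strength.
    severity = np.concatenate(
        [rng_samp.normal(1.0, 0.5, n_pat), np.zeros(n_ctl)]
    )
    mu = base[:, None] + np.outer(delta_full, severity) + cov_term + exp_term
    mu = np.clip(mu, 0.01, 0.99)
    m_vals = beta_to_m(mu) + rng_meth.normal(
        0.0, config.noise_sd_m, size=mu.shape
    )
    beta = pd.DataFrame(m_to_beta(m_vals), index=probe_ids, columns=sample_ids)

    # --- detection p-values ------------------------------------------------
    det = rng_det.uniform(0.0, 0.005, size=mu.shape)
    fail_cells = rng_det.random(mu.shape) < config.frac_failed_cells
    det[fail_cells] = rng_det.uniform(0.05, 0.9, size=int(fail_cells.sum()))
    n_bad = int(round(config.frac_failed_probes * config.n_probes))
    if n_bad:
        bad_probes = rng_det.choice(config.n_probes, size=n_bad, replace=False)
        for i in bad_probes:
            frac = rng_det.uniform(0.55, 1.0)
            cols = rng_det.choice(
                n_samples, size=int(np.ceil(frac * n_samples)), replace=False
            )
            det[i, cols] = rng_det.uniform(0.05, 0.9, size=cols.size)
    detection_p = pd.DataFrame(det, index=probe_ids, columns=sample_ids)
    meth = MethylationDataset(beta, detection_p)

    # --- expression ---------------------------------------------------------
    rna_ids = [f"R{i:05d}" for i in range(config.n_rnas)]
    n_derna = int(round(config.frac_dernas * config.n_rnas))
    derna_idx = np.sort(rng_expr.choice(config.n_rnas, size=n_derna, replace=False))
    n_strength = int(round(config.frac_strength_coupled * n_derna))
    strength_sel = np.sort(rng_expr.choice(n_derna, size=n_strength, replace=False))
    strength_idx = derna_idx[strength_sel]
    pathway_labels = np.array(["none"] * config.n_rnas, dtype=object)
    pw_draw = rng_expr.choice(
        np.array(list(PATHWAYS) + ["none"], dtype=object),
        size=n_derna,
        p=[0.25, 0.20, 0.12, 0.43],
    )
    pathway_labels[derna_idx] = pw_draw

    # Strength-coupled RNAs load on standardized disease severity.
    sev_std = (severity - severity.mean()) / severity.std()
    lambda_strength = 1.3

    expr = rng_expr.normal(8.0, 2.0, config.n_rnas)[:, None] + rng_expr.normal(
        0.0, config.expr_noise_sd, size=(config.n_rnas, n_samples)
    )

    can_couple = n_true > 0 and config.coupling_rho != 0.0
    rho_target = abs(config.coupling_rho)
    rho_pearson = 2.0 * np.sin(np.pi * rho_target / 6.0)  # Spearman -> Pearson (binormal)
    coupling_rows = []
    is_strength = np.zeros(config.n_rnas, dtype=bool)
    is_strength[strength_idx] = True
    for r in derna_idx:
        s = float(rng_expr.choice([-1.0, 1.0]))
        extra_var = config.expr_noise_sd**2 + (
            lambda_strength**2 if is_strength[r] else 0.0
        )
        if can_couple:
            partner = int(rng_expr.choice(planted_idx))
            z = m_vals[partner]
            z = (z - z.mean()) / z.std()
            # the explicit DE shift must reinforce, not fight, the group gap
            # already carried by the coupled signals: severity (higher in
            # patients) for strength-coupled RNAs, the partner probe's planted
            # direction otherwise
            de_sign = s if is_strength[r] else s * float(np.sign(delta_full[partner]))
            c = rho_pearson * np.sqrt(extra_var / (1.0 - rho_pearson**2))
            expr[r] += s * c * z + de_sign * config.expr_shift_log2 * is_pat
            coupling_rows.append(
                (probe_ids[partner], rna_ids[r], s * np.sign(config.coupling_rho) * rho_target)
            )
        else:
            expr[r] += s * config.expr_shift_log2 * is_pat
        if is_strength[r]:
            expr[r] += s * lambda_strength * sev_std
    coupling_map = pd.DataFrame(
        coupling_rows, columns=["probe_id", "rna_id", "rho_target"]
    )

    # --- strength phenotype -------------------------------------------------
    strength = 100.0 - 15.0 * severity + rng_str.normal(0.0, 5.0, n_samples)
    sheet_df["strength"] = strength.round(2)
    sheet = SampleSheet(sheet_df)

    labels = pd.DataFrame(
        {
            "derna": np.isin(np.arange(config.n_rnas), derna_idx),
            "strength_associated": is_strength,
            "pathway": pathway_labels,
        },
        index=pd.Index(rna_ids, name="rna_id"),
    )
    expression = ExpressionDataset(
        pd.DataFrame(expr, index=rna_ids, columns=sample_ids), labels
    )

    truth = SimulationTruth(
        true_dmps=pd.Series(
            deltas, index=pd.Index([probe_ids[i] for i in planted_idx], name="probe_id")
        ),
        true_derna_ids={rna_ids[i] for i in derna_idx},
        coupling_map=coupling_map,
        strength_coupled_rna_ids={rna_ids[i] for i in strength_idx},
        exposure_effect_map=exposure_effect_map,
    )
    return meth, sheet, expression, ann, truth


def write_cohort(
    outdir: str | Path,
    meth: MethylationDataset,
    sheet: SampleSheet,
    expression: ExpressionDataset,
    ann: ProbeAnnotation,
    truth: SimulationTruth,
    config: CohortConfig | None = None,
    categories: dict[str, set[str]] | None = None,
) -> dict[str, Path]:
    """Write all cohort artifacts as TSV/CSV/GMT/YAML into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "detection_p": outdir / "detection_p.tsv",
        "sample_sheet": outdir / "sample_sheet.csv",
        "annotation": outdir / "annotation.tsv",
        "expression": outdir / "expression.tsv",
        "rna_labels": outdir / "rna_labels.tsv",
    }
    write_matrix_tsv(meth.beta, paths["beta"], "probe_id")
    if meth.detection_p is not None:
        write_matrix_tsv(meth.detection_p, paths["detection_p"], "probe_id")
    write_sample_sheet(sheet, paths["sample_sheet"])
    write_annotation(ann, paths["annotation"])
    write_expression(expression, paths["expression"], paths["rna_labels"])
    truth.write(outdir)
    if config is not None:
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    if categories is not None:
        write_gmt(categories, outdir / "categories.gmt")
        paths["categories"] = outdir / "categories.gmt"
    return paths
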