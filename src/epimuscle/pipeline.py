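"""End-to-end orchestration: simulate -> QC -> DMP -> annotate/enrich ->
correlate -> risk factors, with persisted TSV artifacts and a JSON run report.

Every stage writes its outputs before the next stage reads them, so any
single stage can be re-run from the persisted intermediates.  Identical
config + seed gives byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import correlation as corr
from . import dmp as dmp_mod
from . import enrichment as enr
from . import qc as qc_mod
from . import regions as reg
from . import risk as risk_mod
from .datasets import (
    ExpressionDataset,
    MethylationDataset,
    ProbeAnnotation,
    SampleSheet,
    read_annotation,
    read_expression,
    read_gmt,
    read_methylation,
    read_sample_sheet,
)
from .simulate import CohortConfig, generate_categories, generate_cohort, write_cohort
from .transforms import beta_to_m

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "epimuscle_run"
    seed: int = 0
    simulate: bool = True
    simulate_overrides: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # beta, detection_p, sample_sheet, ...
    detection_p_threshold: float = 0.01
    detection_sample_fraction: float = 0.5
    fdr: float = 0.05
    tau: float = 0.3
    risk_p: float = 0.05
    normalize: bool = True
    patients_only_correlations: bool = False
    risk_factors: list[str] | None = None
    categorical_references: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name, lo, hi in (
            ("detection_p_threshold", 0.0, 1.0),
            ("detection_sample_fraction", 0.0, 1.0),
            ("fdr", 0.0, 1.0),
            ("tau", 0.0, 1.0),
            ("risk_p", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_inputs(paths: dict[str, str | Path]) -> list[dict]:
    """Structural diagnostics over a set of input files (no exceptions raised).

    Checks file existence, id uniqueness, beta/detection shape agreement,
    sample-set consistency across beta / sample sheet / expression, and the
    RNA-label invariants.  Returns a list of violation records.
    """
    issues: list[dict] = []

    def bad(kind: str, detail: str) -> None:
        issues.append({"kind": kind, "detail": detail})

    loaded: dict[str, object] = {}
    for key in ("beta", "detection_p", "sample_sheet", "annotation",
                "expression", "rna_labels"):
        p = paths.get(key)
        if p is None:
            continue
        if not Path(p).exists():
            bad("missing_file", f"{key}: {p}")
            continue
        try:
            if key in ("beta", "detection_p", "expression"):
                loaded[key] = pd.read_csv(p, sep="\t", index_col=0)
            elif key == "sample_sheet":
                loaded[key] = pd.read_csv(p, index_col=0)
            elif key == "annotation":
                loaded[key] = read_annotation(p)
            else:
                loaded[key] = pd.read_csv(p, sep="\t", index_col=0)
        except Exception as exc:  # diagnostics, not exceptions
            bad("unreadable", f"{key}: {exc}")

    for key in ("beta", "detection_p", "expression", "sample_sheet", "rna_labels"):
        df = loaded.get(key)
        if df is not None and pd.Index(df.index).has_duplicates:
            bad("duplicate_ids", f"{key} has duplicated row ids")

    beta = loaded.get("beta")
    dp = loaded.get("detection_p")
    if beta is not None and dp is not None and beta.shape != dp.shape:
        bad("shape_mismatch", f"beta {beta.shape} vs detection_p {dp.shape}")
    sheet = loaded.get("sample_sheet")
    if beta is not None and sheet is not None:
        if set(beta.columns) != set(sheet.index):
            bad("sample_mismatch", "beta columns differ from sample-sheet ids")
    expr = loaded.get("expression")
    if expr is not None and sheet is not None:
        if not set(expr.columns) <= set(sheet.index):
            bad("sample_mismatch", "expression has samples absent from the sample sheet")
    labels = loaded.get("rna_labels")
    if labels is not None:
        if expr is not None and set(labels.index) != set(expr.index):
            bad("rna_mismatch", "rna_labels ids differ from expression ids")
        if {"derna", "strength_associated"} <= set(labels.columns):
            sa = labels["strength_associated"].astype(bool)
            de = labels["derna"].astype(bool)
            if (sa & ~de).any():
                bad("label_invariant", "strength_associated RNA not flagged derna")
    return issues


def _load_inputs(cfg: PipelineConfig):
    required = ("beta", "sample_sheet", "annotation", "expression")
    for key in required:
        p = cfg.inputs.get(key)
        if p is None or not Path(p).exists():
            raise StageError("load", f"missing required input '{key}': {p}")
    meth = read_methylation(cfg.inputs["beta"], cfg.inputs.get("detection_p"))
    sheet = read_sample_sheet(cfg.inputs["sample_sheet"])
    ann = read_annotation(cfg.inputs["annotation"])
    expr = read_expression(cfg.inputs["expression"], cfg.inputs.get("rna_labels"))
    cats = read_gmt(cfg.inputs["categories"]) if cfg.inputs.get("categories") else None
    return meth, sheet, ann, expr, cats


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }

    def stage(name: str):
        t0 = time.perf_counter()

        def done(**counts):
            report["stages"][name] = {
                "wall_time_s": round(time.perf_counter() - t0, 3),
                **counts,
            }

        return done

    # -- simulate / load ----------------------------------------------------
    done = stage("inputs")
    if cfg.simulate:
        sim_cfg = CohortConfig.from_dict({"seed": cfg.seed, **cfg.simulate_overrides})
        meth, sheet, expr, ann, truth = generate_cohort(sim_cfg)
        cats = generate_categories(ann, seed=sim_cfg.seed + 1)
        write_cohort(outdir / "cohort", meth, sheet, expr, ann, truth, sim_cfg, cats)
    else:
        meth, sheet, ann, expr, cats = _load_inputs(cfg)
        truth = None
    done(n_probes=meth.n_probes, n_samples=meth.n_samples,
         n_rnas=len(expr.rna_ids), simulated=cfg.simulate)

    # -- QC -----------------------------------------------------------------
    done = stage("qc")
    try:
        n0 = meth.n_probes
        if meth.detection_p is not None:
            meth = qc_mod.filter_probes_by_detection(
                meth, cfg.detection_p_threshold, cfg.detection_sample_fraction
            )
        meth = qc_mod.filter_snp_probes(meth, ann)
        if cfg.normalize:
            meth = qc_mod.quantile_normalize_stratified(meth, ann=ann)
        meth.beta.to_csv(outdir / "qc_beta.tsv", sep="\t",
                         index_label="probe_id", float_format="%.10g")
    except Exception as exc:
        raise StageError("qc", str(exc)) from exc
    done(probes_in=n0, probes_retained=meth.n_probes)

    # -- DMP calling ----------------------------------------------------------
    done = stage("dmp")
    try:
        m_vals = beta_to_m(meth.beta)
        fit = dmp_mod.fit_dmp_models(m_vals, sheet)
        dmps = dmp_mod.call_dmps(fit, meth.beta, sheet, fdr=cfg.fdr)
        dmps.to_tsv(outdir / "dmp_table.tsv")
    except Exception as exc:
        raise StageError("dmp", str(exc)) from exc
    done(**dmps.summary())

    # -- annotation ------------------------------------------------------------
    done = stage("annotate")
    try:
        region_summary = reg.summarize_regions(dmps, ann)
        region_summary.to_frame().to_csv(
            outdir / "region_summary.tsv", sep="\t", index=False, float_format="%.10g"
        )
        dmgs = reg.aggregate_dmgs(dmps, ann)
        dmgs.to_tsv(outdir / "dmg_table.tsv")
    except Exception as exc:
        raise StageError("annotate", str(exc)) from exc
    done(region_counts=region_summary.counts,
         denominator=region_summary.denominator,
         dmg_classes=dmgs.class_counts())

    # -- enrichment -------------------------------------------------------------
    done = stage("enrich")
    n_enrich = {}
    if cats:
        try:
            hypo, hyper, combined = reg.split_by_direction(dmps)
            all_probes = set(meth.probe_ids)
            universe = set(ann.links_for(all_probes)["gene_id"].unique())
            for label, probes in (("combined", combined), ("hypo", hypo), ("hyper", hyper)):
                if not probes:
                    continue
                genes = set(ann.links_for(probes)["gene_id"].unique())
                gene_res = enr.ora_hypergeometric(genes, universe, cats)
                gene_res.to_csv(outdir / f"ora_gene_{label}.tsv", sep="\t",
                                index=False, float_format="%.10g")
                probe_res = enr.ora_probe_bias(probes, all_probes, ann, cats)
                probe_res.to_csv(outdir / f"ora_probe_bias_{label}.tsv", sep="\t",
                                 index=False, float_format="%.10g")
                n_enrich[label] = {
                    "n_categories": int(len(gene_res)),
                    "n_sig_gene_level": int((gene_res["q_value"] < cfg.fdr).sum()),
                    "n_sig_probe_bias": int((probe_res["q_value"] < cfg.fdr).sum()),
                }
        except Exception as exc:
            raise StageError("enrich", str(exc)) from exc
    done(**n_enrich)

    # -- correlation --------------------------------------------------------------
    done = stage("correlate")
    try:
        if expr.labels is not None:
            labels = expr.labels
        else:
            derna = corr.label_dernas(expr, sheet, fdr=cfg.fdr)
            strength_col = sheet.data.get("strength")
            if strength_col is not None:
                strength_pat = strength_col[sheet.is_patient()]
                sa = corr.label_strength_association(
                    expr, strength_pat, fdr=cfg.fdr, derna_flags=derna["derna"]
                )["strength_associated"]
            else:
                sa = pd.Series(False, index=expr.rna_ids)
            labels = pd.DataFrame(
                {"derna": derna["derna"], "strength_associated": sa, "pathway": "none"}
            )
        samples = sheet.sample_ids[sheet.is_patient()] if cfg.patients_only_correlations \
            else sheet.sample_ids
        comp = corr.CorrelationEnrichmentResult(
            pd.DataFrame(), pd.DataFrame(), cfg.tau
        )
        if len(dmps):
            rho = corr.spearman_matrix(
                meth.beta.loc[dmps.probe_ids, samples], expr.expr.loc[:, samples]
            )
            comp = corr.compare_rna_groups(rho, labels, tau=cfg.tau)
            comp.groups.to_csv(outdir / "correlation_groups.tsv", sep="\t",
                               index=False, float_format="%.10g")
            comp.comparisons.to_csv(outdir / "correlation_comparisons.tsv", sep="\t",
                                    index=False, float_format="%.10g")
    except Exception as exc:
        raise StageError("correlate", str(exc)) from exc
    done(n_groups=int(len(comp.groups)), n_comparisons=int(len(comp.comparisons)),
         comparisons=comp.comparisons.to_dict(orient="records"))

    # -- risk factors -----------------------------------------------------------
    done = stage("riskfactors")
    try:
        factors = cfg.risk_factors
        if factors is None:
            reserved = {"group", "age", "sex", "bmi", "strength"}
            factors = ["age", "sex", "bmi"] + [
                c for c in sheet.data.columns if c not in reserved
            ]
        summary_df = pd.DataFrame()
        n_significant = 0
        if len(dmps):
            results = risk_mod.fit_risk_models(
                meth.beta.loc[dmps.probe_ids], sheet, factors,
                dmps.directions(), p_threshold=cfg.risk_p,
                categorical_references=cfg.categorical_references,
            )
            results.to_csv(outdir / "risk_factor_results.tsv", sep="\t",
                           index=False, float_format="%.10g")
            summary = risk_mod.summarize_factors(results)
            summary.to_tsv(outdir / "risk_factor_summary.tsv")
            summary_df = summary.df
            n_significant = int(results["significant"].sum())
    except Exception as exc:
        raise StageError("riskfactors", str(exc)) from exc
    done(n_factors=len(factors), n_significant=n_significant,
         summary=summary_df.to_dict(orient="records"))

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(obj):
    if hasattr(obj, "item"):
        return obj.item()
    return str(obj)
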