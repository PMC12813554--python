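"""In-memory containers and flat-file IO for the analysis.

All matrices are pandas DataFrames with feature ids as the row index and
sample ids as columns.  Methylation is stored as beta-values (proportion
methylated, in (0,1)); expression as normalized log2-scale values.  The
on-disk formats are plain TSV/CSV mirroring the Illumina-manifest style
annotation table and GMT gene-set files, so every artifact of a run is
human-readable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: closed vocabulary of gene-region groups attached to probe->gene links
REGION_GROUPS = ("TSS200", "TSS1500", "5UTR", "Body", "3UTR")

#: pathway labels an RNA may carry (beyond "none")
PATHWAYS = ("mitochondrial", "lipid", "fibrosis")


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class MethylationDataset:
    """Beta-value matrix (probes x samples) with optional detection-p companion."""

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.beta.index, "probe ids")
        _check_unique(self.beta.columns, "sample ids")
        vals = self.beta.to_numpy(dtype=float)
        if not np.all((vals > 0) & (vals < 1)):
            raise ValueError("beta values must lie strictly within (0, 1)")
        if self.detection_p is not None:
            if self.detection_p.shape != self.beta.shape:
                raise ValueError(
                    "detection_p shape "
                    f"{self.detection_p.shape} != beta shape {self.beta.shape}"
                )
            self.detection_p = self.detection_p.loc[self.beta.index, self.beta.columns]
            dp = self.detection_p.to_numpy(dtype=float)
            if not np.all((dp >= 0) & (dp <= 1)):
                raise ValueError("detection p-values must lie within [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset_probes(self, probe_ids) -> "MethylationDataset":
        """Return a new dataset restricted to ``probe_ids`` (order preserved)."""
        keep = self.beta.index.isin(set(probe_ids))
        dp = self.detection_p.loc[keep] if self.detection_p is not None else None
        return MethylationDataset(self.beta.loc[keep], dp)


# required sample-sheet columns and their checks
_GROUPS = ("patient", "control")
_SEXES = ("male", "female")


@dataclass
class SampleSheet:
    """Per-sample phenotypes: group, age, sex, BMI, plus exposures/strength columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample ids")
        for col in ("group", "age", "sex", "bmi"):
            if col not in df.columns:
                raise ValueError(f"sample sheet misses required column '{col}'")
            if df[col].isna().any():
                bad = df.index[df[col].isna()].tolist()[:5]
                raise ValueError(f"missing values in '{col}' for samples {bad}")
        if not df["group"].isin(_GROUPS).all():
            raise ValueError(f"group column must contain only {_GROUPS}")
        if not df["sex"].isin(_SEXES).all():
            raise ValueError(f"sex column must contain only {_SEXES}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def is_patient(self) -> pd.Series:
        return self.data["group"].eq("patient")

    def design_covariates(self) -> pd.DataFrame:
        """Numeric covariate block [age, sex(female=1), bmi] used for adjustment."""
        return pd.DataFrame(
            {
                "age": self.data["age"].astype(float),
                "sex": self.data["sex"].eq("female").astype(float),
                "bmi": self.data["bmi"].astype(float),
            },
            index=self.data.index,
        )


@dataclass
class ExpressionDataset:
    """Normalized expression matrix (RNAs x samples) with per-RNA labels.

    ``labels`` carries three columns: boolean ``derna`` (differentially
    expressed), boolean ``strength_associated`` (associated with long-term
    muscle strength; implies derna) and ``pathway`` in
    {mitochondrial, lipid, fibrosis, none} (non-none implies derna).
    """

    expr: pd.DataFrame
    labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.expr.index, "rna ids")
        _check_unique(self.expr.columns, "sample ids")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.expr.index)
            lab = self.labels
            for col in ("derna", "strength_associated", "pathway"):
                if col not in lab.columns:
                    raise ValueError(f"labels miss required column '{col}'")
            lab["derna"] = lab["derna"].fillna(False).astype(bool)
            lab["strength_associated"] = (
                lab["strength_associated"].fillna(False).astype(bool)
            )
            lab["pathway"] = lab["pathway"].fillna("none")
            bad = ~lab["pathway"].isin(PATHWAYS + ("none",))
            if bad.any():
                raise ValueError(
                    f"unknown pathway labels: {lab.loc[bad, 'pathway'].unique().tolist()}"
                )
            if (lab["strength_associated"] & ~lab["derna"]).any():
                raise ValueError("strength_associated implies derna")
            if (lab["pathway"].ne("none") & ~lab["derna"]).any():
                raise ValueError("a pathway label implies derna")

    @property
    def rna_ids(self) -> pd.Index:
        return self.expr.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.expr.columns


@dataclass
class ProbeAnnotation:
    """Probe -> (gene, region) links plus SNP flag and probe-type stratum.

    ``probes`` is indexed by probe id with columns chromosome, position,
    snp_flag, probe_type.  ``links`` is a long table (probe_id, gene_id,
    region_group); a probe with no row in ``links`` is intergenic.
    """

    probes: pd.DataFrame
    links: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["probe_id", "gene_id", "region_group"]
        )
    )

    def __post_init__(self) -> None:
        _check_unique(self.probes.index, "probe ids")
        for col in ("chromosome", "position", "snp_flag", "probe_type"):
            if col not in self.probes.columns:
                raise ValueError(f"annotation misses required column '{col}'")
        if len(self.links):
            bad = ~self.links["region_group"].isin(REGION_GROUPS)
            if bad.any():
                raise ValueError(
                    "unknown region groups: "
                    f"{self.links.loc[bad, 'region_group'].unique().tolist()}"
                )
            unknown = set(self.links["probe_id"]) - set(self.probes.index)
            if unknown:
                raise ValueError(
                    f"links refer to probes absent from the table: {sorted(unknown)[:5]}"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.probes.index

    def require_probes(self, probe_ids) -> None:
        missing = set(probe_ids) - set(self.probes.index)
        if missing:
            raise ValueError(f"unannotated probe ids: {sorted(missing)[:10]}")

    def snp_probe_ids(self) -> set[str]:
        return set(self.probes.index[self.probes["snp_flag"].astype(bool)])

    def intergenic_probe_ids(self) -> set[str]:
        return set(self.probes.index) - set(self.links["probe_id"])

    def links_for(self, probe_ids) -> pd.DataFrame:
        wanted = set(probe_ids)
        return self.links[self.links["probe_id"].isin(wanted)]

    def probes_per_gene(self, probe_ids=None) -> pd.Series:
        """Number of distinct probes linked to each gene (optionally within a universe)."""
        links = self.links if probe_ids is None else self.links_for(probe_ids)
        return links.drop_duplicates(["probe_id", "gene_id"]).groupby("gene_id").size()


# ---------------------------------------------------------------------------
# flat-file readers / writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def read_matrix_tsv(path: str | Path, what: str = "matrix") -> pd.DataFrame:
    """Read a feature x sample TSV (first column = feature id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, f"{what} row ids in {path}")
    _check_unique(df.columns, f"{what} column ids in {path}")
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=_FLOAT_FMT)


def read_methylation(
    beta_path: str | Path, detection_p_path: str | Path | None = None
) -> MethylationDataset:
    beta = read_matrix_tsv(beta_path, "beta")
    dp = (
        read_matrix_tsv(detection_p_path, "detection_p")
        if detection_p_path is not None
        else None
    )
    return MethylationDataset(beta, dp)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, index_col=0)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, index_label="sample_id", float_format=_FLOAT_FMT)


def read_expression(
    expr_path: str | Path, labels_path: str | Path | None = None
) -> ExpressionDataset:
    expr = read_matrix_tsv(expr_path, "expression")
    labels = None
    if labels_path is not None:
        labels = pd.read_csv(labels_path, sep="\t", index_col=0)
    return ExpressionDataset(expr, labels)


def write_expression(ds: ExpressionDataset, expr_path: str | Path,
                     labels_path: str | Path | None = None) -> None:
    write_matrix_tsv(ds.expr, expr_path, "rna_id")
    if labels_path is not None and ds.labels is not None:
        ds.labels.to_csv(labels_path, sep="\t", index_label="rna_id")


def read_annotation(path: str | Path) -> ProbeAnnotation:
    """Read the manifest-style annotation TSV.

    Expected columns: probe_id, chromosome, position, gene, region_group,
    snp_flag, probe_type.  ``gene`` and ``region_group`` are parallel
    semicolon-separated lists (empty for intergenic probes).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "region_group": str})
    df = df.set_index("probe_id")
    rows = []
    for pid, gene_s, region_s in zip(
        df.index, df["gene"].fillna(""), df["region_group"].fillna("")
    ):
        if not gene_s:
            continue
        genes = gene_s.split(";")
        regions = region_s.split(";")
        if len(genes) != len(regions):
            raise ValueError(
                f"probe {pid}: gene list and region list have different lengths"
            )
        for g, r in zip(genes, regions):
            rows.append((pid, g, r))
    links = pd.DataFrame(rows, columns=["probe_id", "gene_id", "region_group"])
    probes = df[["chromosome", "position", "snp_flag", "probe_type"]].copy()
    probes["snp_flag"] = probes["snp_flag"].astype(bool)
    return ProbeAnnotation(probes, links)


def write_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    grouped = ann.links.groupby("probe_id")
    gene_s = grouped["gene_id"].agg(";".join)
    region_s = grouped["region_group"].agg(";".join)
    out = ann.probes.copy()
    out["gene"] = gene_s.reindex(out.index).fillna("")
    out["region_group"] = region_s.reindex(out.index).fillna("")
    out = out[["chromosome", "position", "gene", "region_group", "snp_flag", "probe_type"]]
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: one category per line (id, description, genes...)."""
    categories: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            categories[parts[0]] = set(g for g in parts[2:] if g)
    return categories


def write_gmt(categories: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid in categories:
            genes = "\t".join(sorted(categories[cid]))
            fh.write(f"{cid}\t{cid}\t{genes}\n")
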