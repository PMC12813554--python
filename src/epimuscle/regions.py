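"""Region distribution of DMPs and gene-level aggregation (DMGs).

Region conventions: a probe is counted once per genomic category it touches
(promoter = any TSS200 or TSS1500 link, 5'UTR, gene body, 3'UTR), so category
counts may sum to more than the number of DMPs; percentages always use the
total DMP count as denominator.  A probe with no gene link is intergenic,
hence intergenic count + count of linked DMPs = total DMPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datasets import ProbeAnnotation
from .dmp import DmpTable

#: display order of the region categories
REGION_CATEGORIES = ("promoter", "five_utr", "gene_body", "three_utr", "intergenic")

_REGION_TO_CATEGORY = {
    "TSS200": "promoter",
    "TSS1500": "promoter",
    "5UTR": "five_utr",
    "Body": "gene_body",
    "3UTR": "three_utr",
}


@dataclass
class RegionSummary:
    counts: dict[str, int]
    denominator: int

    @property
    def percentages(self) -> dict[str, float]:
        if self.denominator == 0:
            return {k: 0.0 for k in self.counts}
        return {k: 100.0 * v / self.denominator for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "category": list(REGION_CATEGORIES),
                "count": [self.counts[c] for c in REGION_CATEGORIES],
                "percentage": [pct[c] for c in REGION_CATEGORIES],
                "denominator": self.denominator,
            }
        )


def summarize_regions(dmps: DmpTable, ann: ProbeAnnotation) -> RegionSummary:
    """Count DMPs per genomic region category; each probe at most once per category."""
    probe_ids = dmps.probe_ids
    ann.require_probes(probe_ids)
    links = ann.links_for(probe_ids)
    counts = {c: 0 for c in REGION_CATEGORIES}
    if len(links):
        cat = links["region_group"].map(_REGION_TO_CATEGORY)
        per_cat = links.assign(category=cat).drop_duplicates(["probe_id", "category"])
        for c, n in per_cat.groupby("category").size().items():
            counts[c] = int(n)
    linked = set(links["probe_id"])
    counts["intergenic"] = int(len(probe_ids)) - len(linked)
    return RegionSummary(counts, int(len(probe_ids)))


@dataclass
class DmgTable:
    """Differentially methylated genes: every gene harbouring >= 1 DMP.

    ``df`` is indexed by gene id with columns probe_ids (tuple), n_dmps and
    direction_class in {hypo_only, hyper_only, mixed}.
    """

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    def class_counts(self) -> dict[str, int]:
        vc = self.df["direction_class"].value_counts()
        return {
            "hypo_only": int(vc.get("hypo_only", 0)),
            "hyper_only": int(vc.get("hyper_only", 0)),
            "mixed": int(vc.get("mixed", 0)),
            "total": int(len(self.df)),
        }

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out["probe_ids"] = out["probe_ids"].map(";".join)
        out.to_csv(path, sep="\t", index_label="gene_id")


def aggregate_dmgs(dmps: DmpTable, ann: ProbeAnnotation) -> DmgTable:
    """One row per gene with >= 1 DMP; direction class from its probes' directions."""
    ann.require_probes(dmps.probe_ids)
    links = ann.links_for(dmps.probe_ids).drop_duplicates(["probe_id", "gene_id"])
    if not len(links):
        return DmgTable(
            pd.DataFrame(columns=["probe_ids", "n_dmps", "direction_class"]).rename_axis("gene_id")
        )
    links = links.merge(
        dmps.directions().rename("direction"), left_on="probe_id", right_index=True
    )
    rows = []
    for gene, sub in links.groupby("gene_id"):
        probes = tuple(sorted(sub["probe_id"].unique()))
        has_hypo = sub["direction"].eq("hypo").any()
        has_hyper = sub["direction"].eq("hyper").any()
        cls = "mixed" if (has_hypo and has_hyper) else ("hypo_only" if has_hypo else "hyper_only")
        rows.append((gene, probes, len(probes), cls))
    df = pd.DataFrame(rows, columns=["gene_id", "probe_ids", "n_dmps", "direction_class"])
    return DmgTable(df.set_index("gene_id"))


def split_by_direction(dmps: DmpTable) -> tuple[set[str], set[str], set[str]]:
    """(hypo probe set, hyper probe set, combined set); hypo and hyper partition combined."""
    direction = dmps.directions()
    hypo = set(direction.index[direction.eq("hypo")])
    hyper = set(direction.index[direction.eq("hyper")])
    return hypo, hyper, hypo | hyper
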