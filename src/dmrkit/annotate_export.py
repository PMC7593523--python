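"""Annotation of called DMRs and export of categorical result tables.

DMRs are bucketed by region class, effect direction and context; genes
carrying DMRs at their TSS, TES or gene body are indexed; every site
inside a called DMR is exported as a differentially methylated cytosine
(DMC), and a promoter report lists genes with at least a minimum number of
DMCs in their TSS region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .dmr_stats import DmrRecord, write_dmrs
from .genome_regions import REGION_CLASSES

DIRECTIONS = ("hyper", "hypo", "none")


@dataclass
class AnnotatedDmrSet:
    """Called DMRs bucketed by (region_class, direction, context)."""

    buckets: dict[tuple[str, str, str], list[DmrRecord]] = field(default_factory=dict)
    gene_index: dict[str, list[DmrRecord]] = field(default_factory=dict)

    @property
    def n_dmrs(self) -> int:
        return sum(len(v) for v in self.buckets.values())

    def bucket(self, region_class: str, direction: str, context: str) -> list[DmrRecord]:
        return self.buckets.get((region_class, direction, context), [])

    def all_records(self) -> list[DmrRecord]:
        return [r for v in self.buckets.values() for r in v]


def annotate(dmrs: Sequence[DmrRecord]) -> AnnotatedDmrSet:
    """Bucket significant DMRs by class/direction/context and index genes.

    Only records flagged significant enter the set.  Each record lands in
    exactly one bucket (its parent region's class); the gene index covers
    the gene-linked classes TSS, TES and gene body.
    """
    out = AnnotatedDmrSet()
    for rec in dmrs:
        if not rec.significant:
            continue
        p = rec.pair
        key = (p.region_class, rec.direction, p.context)
        out.buckets.setdefault(key, []).append(rec)
        if p.region_class in ("TSS", "TES", "gene_body") and p.gene_name:
            out.gene_index.setdefault(p.gene_name, []).append(rec)
    return out


DMC_COLUMNS = [
    "chrom",
    "pos",
    "gene_name",
    "region_class",
    "context",
    "direction",
    "case_level",
    "control_level",
    "imputed_case",
    "imputed_control",
    "dmr_p_value",
]


def extract_dmcs(
    dmrs: Sequence[DmrRecord], min_dmcs_per_promoter: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site DMCs from called DMRs, plus the promoter-level gene report.

    Every site of a significant DMR is a DMC carrying both condition levels
    and the parent DMR's P-value.  The gene report lists genes whose
    TSS-region DMRs hold at least ``min_dmcs_per_promoter`` DMCs.
    """
    rows = []
    promoter_counts: dict[str, int] = {}
    for rec in dmrs:
        if not rec.significant:
            continue
        p = rec.pair
        for i, pos in enumerate(p.positions):
            rows.append(
                (
                    p.chrom,
                    pos,
                    p.gene_name or ".",
                    p.region_class,
                    p.context,
                    rec.direction,
                    p.case_levels[i],
                    p.control_levels[i],
                    int(p.imputed_case[i]),
                    int(p.imputed_control[i]),
                    rec.p_value,
                )
            )
        if p.region_class == "TSS" and p.gene_name:
            promoter_counts[p.gene_name] = promoter_counts.get(p.gene_name, 0) + p.n_sites
    dmcs = pd.DataFrame(rows, columns=DMC_COLUMNS)
    genes = pd.DataFrame(
        sorted(
            (g, n) for g, n in promoter_counts.items() if n >= min_dmcs_per_promoter
        ),
        columns=["gene_name", "n_promoter_dmcs"],
    )
    return dmcs, genes


def _bed_score(p: float) -> int:
    if p <= 0:
        return 1000
    return min(1000, int(round(-10 * math.log10(p))))


def export_tables(
    annotated: AnnotatedDmrSet,
    out_dir: str | Path,
    label: str,
    context: str,
    min_dmcs_per_promoter: int = 2,
) -> dict[str, Path]:
    """Write the categorical DMR tables, BEDs, DMC table and gene lists.

    One TSV per region class x direction (empty placeholders included so
    the output set is fixed), one BED6 per direction (score =
    ``-10*log10(p)`` capped at 1000), the DMC table, the promoter gene
    report and the gene list of all genes with DMRs at TSS/TES/gene body.
    File names are deterministic from ``label`` and ``context``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{label}_{context}"
    paths: dict[str, Path] = {}

    for cls in REGION_CLASSES:
        for direction in ("hyper", "hypo"):
            recs = sorted(
                annotated.bucket(cls, direction, context),
                key=lambda r: (r.pair.chrom, r.pair.start, r.pair.end),
            )
            p = out_dir / f"{stem}_dmrs_{cls}_{direction}.tsv"
            write_dmrs(recs, p)
            paths[f"dmrs_{cls}_{direction}"] = p

    for direction in ("hyper", "hypo"):
        recs = sorted(
            (
                r
                for (cls, d, ctx), v in annotated.buckets.items()
                if d == direction and ctx == context
                for r in v
            ),
            key=lambda r: (r.pair.chrom, r.pair.start, r.pair.end),
        )
        p = out_dir / f"{stem}_dmrs_{direction}.bed"
        with open(p, "w") as fh:
            for r in recs:
                name = r.pair.gene_name or f"{r.pair.chrom}:{r.pair.start}-{r.pair.end}"
                fh.write(
                    f"{r.pair.chrom}\t{r.pair.start}\t{r.pair.end}\t{name}"
                    f"\t{_bed_score(r.p_value)}\t{r.pair.strand}\n"
                )
        paths[f"bed_{direction}"] = p

    records = [r for r in annotated.all_records() if r.pair.context == context]
    records.sort(key=lambda r: (r.pair.chrom, r.pair.start, r.pair.end))
    dmcs, promoter_genes = extract_dmcs(records, min_dmcs_per_promoter)
    p = out_dir / f"{stem}_dmcs.tsv"
    dmcs.to_csv(p, sep="\t", index=False, float_format="%.17g")
    paths["dmcs"] = p
    p = out_dir / f"{stem}_promoter_genes.tsv"
    promoter_genes.to_csv(p, sep="\t", index=False)
    paths["promoter_genes"] = p

    p = out_dir / f"{stem}_genes.txt"
    with open(p, "w") as fh:
        for g in sorted(
            g
            for g, recs in annotated.gene_index.items()
            if any(r.pair.context == context for r in recs)
        ):
            fh.write(g + "\n")
    paths["genes"] = p
    return paths
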