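"""Gene-model parsing and genomic region extraction.

The genome is partitioned into five region classes around each annotated
transcript -- TSS flank, TES flank, gene body, 5' distance (a distal
upstream window) and intergenic -- plus optional user-supplied regions
(enhancers, CpG islands, ...).  All downstream searches for methylated
regions are confined to these intervals.

Coordinates are 0-based, half-open throughout, matching BED and the UCSC
refFlat txStart/txEnd convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

REGION_CLASSES = (
    "TSS",
    "TES",
    "gene_body",
    "five_prime_distance",
    "intergenic",
    "enhancer",
)

#: region classes that always carry a gene name
GENE_LINKED_CLASSES = ("TSS", "TES", "gene_body", "five_prime_distance")


class ParseError(ValueError):
    """Raised for malformed annotation input, naming the offending line."""


@dataclass(frozen=True)
class GeneModel:
    """One transcript row of a refFlat file (exon structure ignored)."""

    gene_name: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not 0 <= self.tx_start < self.tx_end:
            raise ValueError(
                f"invalid transcript span [{self.tx_start}, {self.tx_end})"
            )


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A typed half-open interval, optionally linked to a gene."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    region_class: str = "enhancer"
    gene_name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chromosome-sizes file into ``{chrom: length}``."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom\\tsize'")
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer size {parts[1]!r}") from exc
            if length <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive size {length}")
            sizes[parts[0]] = length
    return sizes


def read_refflat(path: str | Path, sizes: Mapping[str, int] | None = None) -> list[GeneModel]:
    """Parse an 11-column UCSC refFlat file into gene models.

    Exon/CDS columns are read but ignored.  When ``sizes`` is given, rows on
    chromosomes absent from it are dropped with a logged warning.
    """
    genes: list[GeneModel] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 refFlat columns")
            gene_name, transcript_id, chrom, strand = parts[:4]
            try:
                tx_start, tx_end = int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            if tx_start >= tx_end:
                raise ParseError(
                    f"{path}:{lineno}: txStart {tx_start} >= txEnd {tx_end}"
                )
            if sizes is not None and chrom not in sizes:
                dropped += 1
                continue
            genes.append(GeneModel(gene_name, transcript_id, chrom, strand, tx_start, tx_end))
    if dropped:
        log.warning("read_refflat: dropped %d rows on chromosomes absent from the size table", dropped)
    return genes


def _clip(start: int, end: int, chrom_len: int) -> tuple[int, int]:
    return max(0, start), min(end, chrom_len)


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    if not ivals:
        return []
    ivals = sorted(ivals)
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def extract_regions(
    genes: Iterable[GeneModel],
    sizes: Mapping[str, int],
    *,
    tss_flank: int = 1000,
    tes_flank: int = 1000,
    fpd_near: int = 10_000,
    fpd_far: int = 100_000,
    intergenic_min: int = 2000,
    intergenic_max: int = 100_000,
    intergenic_mode: str = "truncate",
) -> list[GenomicRegion]:
    """Partition the genome into the five region classes.

    For each transcript the TSS region is ``[tss - tss_flank, tss + tss_flank)``
    (the TSS point being ``tx_start`` on '+' and ``tx_end`` on '-'), the TES
    region is the analogue around the transcription end point, the gene body
    is the interval strictly between the two flank regions, and the 5'
    distance region spans ``fpd_near``..``fpd_far`` bp upstream of the TSS,
    strand-aware.  Intergenic regions are the per-chromosome complement of
    the union of all TSS/TES/gene-body regions, dropping segments shorter
    than ``intergenic_min``; segments longer than ``intergenic_max`` are
    either truncated to their first ``intergenic_max`` bases
    (``intergenic_mode='truncate'``, default) or split into consecutive
    max-length chunks (``intergenic_mode='split'``).

    All coordinates are clipped to ``[0, chrom length)``; regions that clip
    to zero length are dropped.  Duplicate regions (identical transcripts)
    are emitted once.  Genes too short for a positive-length gene body are
    kept with their flank regions but no body.
    """
    if not (0 < fpd_near < fpd_far):
        raise ValueError("require 0 < fpd_near < fpd_far")
    if not (0 < intergenic_min < intergenic_max):
        raise ValueError("require 0 < intergenic_min < intergenic_max")
    if tss_flank <= 0 or tes_flank <= 0:
        raise ValueError("flanks must be positive")
    if intergenic_mode not in ("truncate", "split"):
        raise ValueError("intergenic_mode must be 'truncate' or 'split'")

    regions: set[GenomicRegion] = set()
    genic: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}
    n_no_body = 0

    for g in genes:
        chrom_len = sizes.get(g.chrom)
        if chrom_len is None:
            continue
        if g.strand == "+":
            tss_pt, tes_pt = g.tx_start, g.tx_end
        else:
            tss_pt, tes_pt = g.tx_end, g.tx_start

        def add(start: int, end: int, cls: str) -> tuple[int, int] | None:
            s, e = _clip(start, end, chrom_len)
            if s < e:
                regions.add(GenomicRegion(g.chrom, s, e, g.strand, cls, g.gene_name))
                return s, e
            return None

        tss_iv = add(tss_pt - tss_flank, tss_pt + tss_flank, "TSS")
        tes_iv = add(tes_pt - tes_flank, tes_pt + tes_flank, "TES")
        for iv in (tss_iv, tes_iv):
            if iv is not None:
                genic[g.chrom].append(iv)

        # gene body: strictly between the two flank regions
        if g.strand == "+":
            body = (g.tx_start + tss_flank, g.tx_end - tes_flank)
        else:
            body = (g.tx_start + tes_flank, g.tx_end - tss_flank)
        if body[0] < body[1]:
            iv = add(body[0], body[1], "gene_body")
            if iv is not None:
                genic[g.chrom].append(iv)
        else:
            n_no_body += 1

        # 5' distance: 10-100 kb upstream of the TSS, strand-relative
        if g.strand == "+":
            add(tss_pt - fpd_far, tss_pt - fpd_near, "five_prime_distance")
        else:
            add(tss_pt + fpd_near, tss_pt + fpd_far, "five_prime_distance")

    if n_no_body:
        log.warning(
            "extract_regions: %d transcripts too short for a gene body (flank regions kept)",
            n_no_body,
        )

    # intergenic = complement of TSS/TES/gene_body unions
    for chrom, chrom_len in sizes.items():
        occupied = _merge_intervals(genic.get(chrom, []))
        gaps: list[tuple[int, int]] = []
        prev = 0
        for s, e in occupied:
            if s > prev:
                gaps.append((prev, s))
            prev = max(prev, e)
        if prev < chrom_len:
            gaps.append((prev, chrom_len))
        for s, e in gaps:
            if e - s < intergenic_min:
                continue
            if e - s <= intergenic_max:
                regions.add(GenomicRegion(chrom, s, e, ".", "intergenic"))
            elif intergenic_mode == "truncate":
                regions.add(GenomicRegion(chrom, s, s + intergenic_max, ".", "intergenic"))
            else:  # split into consecutive chunks
                pos = s
                while pos < e:
                    chunk_end = min(pos + intergenic_max, e)
                    if chunk_end - pos >= intergenic_min:
                        regions.add(GenomicRegion(chrom, pos, chunk_end, ".", "intergenic"))
                    pos = chunk_end

    return sorted(regions)


def read_region_bed(path: str | Path, region_class: str = "enhancer") -> list[GenomicRegion]:
    """Read a BED3+ file as regions of the given class (default enhancer).

    ``track``/``browser`` header lines are skipped.  Overlapping rows are
    kept as-is, no merging.
    """
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            regions.append(
                GenomicRegion(parts[0], start, end, strand, region_class, name)
            )
    return regions


def write_region_beds(regions: Iterable[GenomicRegion], out_dir: str | Path) -> dict[str, Path]:
    """Write one BED6 file per region class; returns ``{class: path}``.

    These annotation products are computed once per genome and reused
    across experiments.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_class: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        by_class.setdefault(r.region_class, []).append(r)
    paths: dict[str, Path] = {}
    for cls, rs in sorted(by_class.items()):
        p = out_dir / f"regions_{cls}.bed"
        with open(p, "w") as fh:
            for r in sorted(rs):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_name or '.'}\t0\t{r.strand}\n")
        paths[cls] = p
    return paths


def read_region_beds(in_dir: str | Path) -> list[GenomicRegion]:
    """Re-read the per-class BED files written by :func:`write_region_beds`."""
    in_dir = Path(in_dir)
    regions: list[GenomicRegion] = []
    for p in sorted(in_dir.glob("regions_*.bed")):
        cls = p.stem.removeprefix("regions_")
        with open(p) as fh:
            for line in fh:
                chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")
                regions.append(
                    GenomicRegion(
                        chrom,
                        int(start),
                        int(end),
                        strand,
                        cls,
                        "" if name == "." else name,
                    )
                )
    return regions
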