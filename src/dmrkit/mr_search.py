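"""Clustering of methylated sites into methylated regions (MRs).

An MR is a cluster of 5mC or 5hmC sites inside one annotated genomic
region, satisfying a minimum site count and, in adjacency mode, a maximum
gap between consecutive sites.  The minimum count is region-class
dependent: promoter-scale classes (TSS/TES) default to 3 sites, the large
classes (gene body, 5' distance, intergenic) to 5, and user regions
(enhancers) to 3.  An alternative fixed-window mode tiles each region into
equal bins, suited to dense WGBS data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_regions import GenomicRegion

#: classes governed by each minimum-count knob (mc1/mc2/mc3)
MC1_CLASSES = ("TSS", "TES")
MC2_CLASSES = ("gene_body", "five_prime_distance", "intergenic")
MC3_CLASSES = ("enhancer",)


@dataclass(frozen=True)
class MrSearchParams:
    """Stringency parameters for the MR search.

    ``max_adjacency_a`` is the largest allowed gap (bp) between consecutive
    sites in one MR; gaps exactly equal to it are allowed.  ``min_sites_*``
    are the per-region-class minimum site counts (the CLI's mc1/mc2/mc3).
    ``same_trend_isST=1`` restricts the later DMR test to MRs whose
    consecutive level changes all share one sign.
    """

    min_sites_tss_tes: int = 3
    min_sites_body_fpd_intergenic: int = 5
    min_sites_enhancer: int = 3
    max_adjacency_a: int = 2000
    use_windows: bool = False
    window_size: int = 200
    same_trend_isST: int = 0

    def __post_init__(self) -> None:
        if min(self.min_sites_tss_tes, self.min_sites_body_fpd_intergenic, self.min_sites_enhancer) < 1:
            raise ValueError("minimum site counts must be >= 1")
        if self.max_adjacency_a < 1 or self.window_size < 1:
            raise ValueError("adjacency and window size must be >= 1")
        if self.same_trend_isST not in (0, 1):
            raise ValueError("same_trend_isST is 0 or 1")

    def min_sites_for(self, region_class: str) -> int:
        if region_class in MC1_CLASSES:
            return self.min_sites_tss_tes
        if region_class in MC2_CLASSES:
            return self.min_sites_body_fpd_intergenic
        return self.min_sites_enhancer


@dataclass(frozen=True)
class MethylatedRegion:
    """A cluster of methylated sites inside one annotated region."""

    chrom: str
    start: int  # position of first site
    end: int  # position of last site + 1 (half-open bounding interval)
    sites: tuple[int, ...]
    levels: tuple[float, ...]
    region_class: str
    gene_name: str
    context: str
    sample_id: str
    region_start: int = 0  # parent annotated region bounds
    region_end: int = 0

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.levels) or not self.sites:
            raise ValueError("sites/levels must be same nonzero length")
        if any(b <= a for a, b in zip(self.sites, self.sites[1:])):
            raise ValueError("sites must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def _sites_by_chrom(sites: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (positions, levels) arrays sorted by position."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(np.int64)
        lev = grp["level"].to_numpy(float)
        order = np.argsort(pos, kind="stable")
        out[str(chrom)] = (pos[order], lev[order])
    return out


def _emit(
    pos: np.ndarray,
    lev: np.ndarray,
    region: GenomicRegion,
    context: str,
    sample_id: str,
) -> MethylatedRegion:
    return MethylatedRegion(
        chrom=region.chrom,
        start=int(pos[0]),
        end=int(pos[-1]) + 1,
        sites=tuple(int(p) for p in pos),
        levels=tuple(float(v) for v in lev),
        region_class=region.region_class,
        gene_name=region.gene_name,
        context=context,
        sample_id=sample_id,
        region_start=region.start,
        region_end=region.end,
    )


def _single_context(sites: pd.DataFrame) -> tuple[str, str]:
    contexts = sites["context"].unique()
    samples = sites["sample_id"].unique()
    if len(contexts) != 1 or len(samples) != 1:
        raise ValueError("MR search expects one context and one sample per call")
    return str(contexts[0]), str(samples[0])


def find_mrs_adjacency(
    sites: pd.DataFrame,
    regions: Sequence[GenomicRegion],
    params: MrSearchParams = MrSearchParams(),
) -> list[MethylatedRegion]:
    """Find MRs by the adjacency rule within each annotated region.

    Sites in a region (half-open containment) are scanned in coordinate
    order; a new cluster starts whenever the gap to the previous site
    exceeds ``max_adjacency_a``.  Clusters below the region class's minimum
    site count are discarded.
    """
    if sites.empty:
        return []
    context, sample_id = _single_context(sites)
    by_chrom = _sites_by_chrom(sites)
    mrs: list[MethylatedRegion] = []
    for region in regions:
        if region.chrom not in by_chrom:
            continue
        pos, lev = by_chrom[region.chrom]
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        if hi - lo < params.min_sites_for(region.region_class):
            continue
        rpos, rlev = pos[lo:hi], lev[lo:hi]
        breaks = np.nonzero(np.diff(rpos) > params.max_adjacency_a)[0] + 1
        for cpos, clev in zip(np.split(rpos, breaks), np.split(rlev, breaks)):
            if len(cpos) >= params.min_sites_for(region.region_class):
                mrs.append(_emit(cpos, clev, region, context, sample_id))
    return mrs


def find_mrs_windows(
    sites: pd.DataFrame,
    regions: Sequence[GenomicRegion],
    params: MrSearchParams,
) -> list[MethylatedRegion]:
    """Find MRs by tiling each region into fixed windows from its start.

    Sites falling in one window form a candidate MR; the per-class minimum
    count applies as in adjacency mode.  A region shorter than the window
    yields a single window spanning it.
    """
    if sites.empty:
        return []
    context, sample_id = _single_context(sites)
    by_chrom = _sites_by_chrom(sites)
    w = params.window_size
    mrs: list[MethylatedRegion] = []
    for region in regions:
        if region.chrom not in by_chrom:
            continue
        pos, lev = by_chrom[region.chrom]
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        if hi - lo < params.min_sites_for(region.region_class):
            continue
        rpos, rlev = pos[lo:hi], lev[lo:hi]
        bins = (rpos - region.start) // w
        breaks = np.nonzero(np.diff(bins))[0] + 1
        for cpos, clev in zip(np.split(rpos, breaks), np.split(rlev, breaks)):
            if len(cpos) >= params.min_sites_for(region.region_class):
                mrs.append(_emit(cpos, clev, region, context, sample_id))
    return mrs


def find_mrs(
    sites: pd.DataFrame,
    regions: Sequence[GenomicRegion],
    params: MrSearchParams = MrSearchParams(),
) -> list[MethylatedRegion]:
    """Dispatch to adjacency or window mode per ``params.use_windows``."""
    if params.use_windows:
        return find_mrs_windows(sites, regions, params)
    return find_mrs_adjacency(sites, regions, params)


def trend_vector(levels: Sequence[float] | MethylatedRegion) -> tuple[int, ...]:
    """Signs of consecutive level differences along coordinates (+1/-1/0)."""
    if isinstance(levels, MethylatedRegion):
        levels = levels.levels
    arr = np.asarray(levels, dtype=float)
    return tuple(int(s) for s in np.sign(np.diff(arr)))


def is_same_trend(levels: Sequence[float] | MethylatedRegion) -> bool:
    """True when all nonzero consecutive changes share one sign.

    Flat stretches (zero differences) are compatible with either trend; a
    single-site MR is vacuously same-trend.
    """
    signs = {s for s in trend_vector(levels) if s != 0}
    return len(signs) <= 1


MR_TSV_COLUMNS = [
    "chrom",
    "start",
    "end",
    "region_class",
    "gene_name",
    "context",
    "sample_id",
    "n_sites",
    "positions",
    "levels",
    "region_start",
    "region_end",
]


def write_mrs(mrs: Iterable[MethylatedRegion], path: str | Path) -> None:
    """Export MRs as a BED-like TSV with comma-joined positions/levels."""
    rows = [
        (
            m.chrom,
            m.start,
            m.end,
            m.region_class,
            m.gene_name or ".",
            m.context,
            m.sample_id,
            m.n_sites,
            ",".join(str(p) for p in m.sites),
            ",".join(repr(v) for v in m.levels),
            m.region_start,
            m.region_end,
        )
        for m in mrs
    ]
    pd.DataFrame(rows, columns=MR_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mrs(path: str | Path) -> list[MethylatedRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_name": str, "sample_id": str})
    mrs = []
    for row in df.itertuples(index=False):
        mrs.append(
            MethylatedRegion(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                sites=tuple(int(p) for p in str(row.positions).split(",")),
                levels=tuple(float(v) for v in str(row.levels).split(",")),
                region_class=row.region_class,
                gene_name="" if row.gene_name == "." else str(row.gene_name),
                context=row.context,
                sample_id=str(row.sample_id),
                region_start=int(row.region_start),
                region_end=int(row.region_end),
            )
        )
    return mrs
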