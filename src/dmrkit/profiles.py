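"""Genome-wide methylation summaries and per-MR plots.

Three summaries describe the methylation landscape: the relative density
of significantly modified sites per region class (sites above a level
threshold per Mb of class length), the percentage of hyper- vs
hypomethylated DMRs per class, and the metagene profile -- the mean 5mC or
5hmC level over all genes after rescaling each gene's TSS/body/TES to
fixed-length axes, smoothed by a centred moving average and a 1-D Gaussian
filter.  Every figure is written together with a sibling TSV of the
plotted values so plots are regenerable from exports alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import ndimage

from .annotate_export import AnnotatedDmrSet
from .dmr_stats import DmrRecord, PairedMR
from .genome_regions import GenomicRegion, _merge_intervals
from .mr_search import MethylatedRegion

log = logging.getLogger(__name__)

SEGMENTS = ("TSS", "gene_body", "TES")


@dataclass(frozen=True)
class ProfileGrid:
    """Metagene grid: bins per TSS/body/TES sub-axis plus smoothing knobs."""

    n_bins: int = 100
    ma_window: int = 3
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.ma_window < 1 or self.sigma < 0:
            raise ValueError("invalid profile grid parameters")

    @property
    def total_bins(self) -> int:
        return 3 * self.n_bins


def relative_density(
    sites: pd.DataFrame,
    regions: Sequence[GenomicRegion],
    level_threshold: float = 1.0,
) -> pd.DataFrame:
    """Density of significantly modified sites per region class.

    A site counts when its level is strictly above ``level_threshold``
    (default 1.0, the convention for HMST tag-ratio levels; use 0.5 for
    WGBS/RRBS fractions) and it falls in at least one region of the class.
    Density is reported per Mb of the class's merged (non-redundant)
    length.  Classes with zero total length are omitted with a log note.
    """
    sig = sites[sites["level"] > level_threshold]
    pos_by_chrom = {
        str(c): np.sort(g["pos"].to_numpy(np.int64)) for c, g in sig.groupby("chrom")
    }
    classes = sorted({r.region_class for r in regions})
    rows = []
    for cls in classes:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            if r.region_class == cls:
                by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        total = 0
        n_sig = 0
        for chrom, ivals in by_chrom.items():
            merged = _merge_intervals(ivals)
            total += sum(e - s for s, e in merged)
            pos = pos_by_chrom.get(chrom)
            if pos is None:
                continue
            for s, e in merged:
                lo = np.searchsorted(pos, s, side="left")
                hi = np.searchsorted(pos, e, side="left")
                n_sig += int(hi - lo)
        if total == 0:
            log.info("relative_density: class %s has zero total length, omitted", cls)
            continue
        rows.append((cls, n_sig, total, 1e6 * n_sig / total))
    return pd.DataFrame(
        rows, columns=["region_class", "n_significant_sites", "total_bases", "density_per_mb"]
    )


def direction_percentages(annotated: AnnotatedDmrSet, context: str) -> pd.DataFrame:
    """Hyper/hypo DMR percentages per region class (absent when no DMRs)."""
    classes = sorted({cls for (cls, _d, ctx) in annotated.buckets if ctx == context})
    rows = []
    for cls in classes:
        n_hyper = len(annotated.bucket(cls, "hyper", context))
        n_hypo = len(annotated.bucket(cls, "hypo", context))
        total = n_hyper + n_hypo
        if total == 0:
            continue
        rows.append(
            (cls, n_hyper, n_hypo, 100.0 * n_hyper / total, 100.0 * n_hypo / total)
        )
    return pd.DataFrame(
        rows, columns=["region_class", "n_hyper", "n_hypo", "pct_hyper", "pct_hypo"]
    )


def _gene_axes(regions: Sequence[GenomicRegion]) -> dict[str, dict[str, GenomicRegion]]:
    """Per-gene TSS/gene_body/TES sub-intervals (genes with all three)."""
    per_gene: dict[str, dict[str, GenomicRegion]] = {}
    for r in regions:
        if r.region_class in SEGMENTS and r.gene_name:
            per_gene.setdefault(r.gene_name, {})[r.region_class] = r
    return {g: d for g, d in per_gene.items() if len(d) == 3}


def meta_profile(
    mrs: Sequence[MethylatedRegion],
    regions: Sequence[GenomicRegion],
    grid: ProfileGrid = ProfileGrid(),
) -> np.ndarray:
    """Mean methylation over all genes on the equalized TSS-body-TES axis.

    Each gene's three sub-intervals are rescaled to unit length and
    concatenated into a common axis of ``3 * n_bins`` bins ('-'-strand
    genes are flipped so the axis always runs TSS->TES).  Within a gene,
    every bin takes the level of the nearest observed site on the rescaled
    axis (nearest-neighbour interpolation, exact at observed points); the
    profile is the per-bin mean over genes with at least one site.  The
    result is raw: smooth with :func:`smooth_profile` before plotting.
    """
    axes = _gene_axes(regions)
    by_gene: dict[str, list[tuple[float, float]]] = {}
    offsets = {"TSS": 0.0, "gene_body": 1.0, "TES": 2.0}
    for m in mrs:
        if m.region_class not in SEGMENTS or m.gene_name not in axes:
            continue
        seg = axes[m.gene_name][m.region_class]
        span = seg.end - seg.start
        for p, v in zip(m.sites, m.levels):
            frac = (p - seg.start) / span
            if seg.strand == "-":
                frac = 1.0 - frac
            by_gene.setdefault(m.gene_name, []).append(
                (offsets[m.region_class] + frac, float(v))
            )
    centers = (np.arange(grid.total_bins) + 0.5) * (3.0 / grid.total_bins)
    if not by_gene:
        return np.zeros(grid.total_bins)
    acc = np.zeros(grid.total_bins)
    for pts in by_gene.values():
        pts.sort()
        xs = np.array([x for x, _ in pts])
        vs = np.array([v for _, v in pts])
        idx = np.clip(np.searchsorted(xs, centers), 1, len(xs) - 1) if len(xs) > 1 else None
        if idx is None:
            acc += vs[0]
        else:
            left = xs[idx - 1]
            right = xs[idx]
            nearest = np.where(np.abs(centers - left) <= np.abs(right - centers), idx - 1, idx)
            acc += vs[nearest]
    return acc / len(by_gene)


def smooth_profile(
    values: Sequence[float], window_n: int = 3, sigma: float | None = 2.0
) -> np.ndarray:
    """Centred moving average then 1-D Gaussian smoothing (reflective edges).

    ``MA_t = (1/n) * sum_{i=-n/2..n/2} A_{t+i}``: an even ``window_n`` is
    incremented to keep the window centred, and a window longer than the
    vector is clipped (logged).  ``sigma=None`` or 0 skips the Gaussian
    step.  Output length equals input length.
    """
    arr = np.asarray(values, dtype=float)
    if window_n < 1:
        raise ValueError("window_n must be >= 1")
    n = window_n
    if n > len(arr):
        log.info("smooth_profile: window %d clipped to vector length %d", n, len(arr))
        n = len(arr)
    if n % 2 == 0:
        n += 1 if n < len(arr) else -1
    n = max(n, 1)
    out = ndimage.uniform_filter1d(arr, size=n, mode="reflect")
    if sigma:
        out = ndimage.gaussian_filter1d(out, sigma=sigma, mode="reflect")
    return out


# ---------------------------------------------------------------------------
# figures (each with a sibling TSV of plotted values)


def _save_with_table(fig, df: pd.DataFrame, out_path: str | Path) -> tuple[Path, Path]:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    table = out_path.with_suffix(".tsv")
    df.to_csv(table, sep="\t", index=False, float_format="%.17g")
    return out_path, table


def plot_density(density: pd.DataFrame, out_path: str | Path, title: str = "") -> tuple[Path, Path]:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(density["region_class"], density["density_per_mb"], color="#4878d0")
    ax.set_ylabel("significant sites per Mb")
    ax.set_title(title or "Relative density of significantly modified sites")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    return _save_with_table(fig, density, out_path)


def plot_direction_percentages(
    pct: pd.DataFrame, out_path: str | Path, title: str = ""
) -> tuple[Path, Path]:
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(pct))
    ax.bar(x - 0.2, pct["pct_hyper"], width=0.4, label="hyper", color="#d65f5f")
    ax.bar(x + 0.2, pct["pct_hypo"], width=0.4, label="hypo", color="#4878d0")
    ax.set_xticks(x, pct["region_class"], rotation=30)
    ax.set_ylabel("% of DMRs")
    ax.set_title(title or "Hyper/hypo DMR percentages per region class")
    ax.legend()
    fig.tight_layout()
    return _save_with_table(fig, pct, out_path)


def plot_meta_profile(
    profiles: dict[str, np.ndarray],
    grid: ProfileGrid,
    out_path: str | Path,
    title: str = "",
    smoothed: bool = True,
) -> tuple[Path, Path]:
    """Plot one or more metagene profiles on the TSS-body-TES axis.

    ``profiles`` maps a label (sample/context) to a raw profile vector;
    smoothing per ``grid`` is applied here when ``smoothed``.
    """
    fig, ax = plt.subplots(figsize=(7, 4))
    data = {"bin": np.arange(grid.total_bins)}
    for label, prof in profiles.items():
        vals = smooth_profile(prof, grid.ma_window, grid.sigma) if smoothed else np.asarray(prof)
        ax.plot(np.arange(grid.total_bins), vals, label=label)
        data[label] = vals
    for b in (grid.n_bins, 2 * grid.n_bins):
        ax.axvline(b, color="grey", lw=0.8, ls="--")
    ax.set_xticks(
        [grid.n_bins / 2, 1.5 * grid.n_bins, 2.5 * grid.n_bins], ["TSS", "gene body", "TES"]
    )
    ax.set_ylabel("mean methylation level")
    ax.set_title(title or "Genome-wide average methylation profile")
    ax.legend()
    fig.tight_layout()
    return _save_with_table(fig, pd.DataFrame(data), out_path)


def plot_mr_sites(rec: DmrRecord | PairedMR, out_path: str | Path) -> tuple[Path, Path]:
    """Per-MR site plot: original vs imputed levels in both conditions.

    Diamonds mark original (observed) methylation values, circles imputed
    ones.  The title encodes ``chrom:start:end:strand:gene`` followed by
    the P-value when a tested record is given.  The underlying table is
    written alongside the figure.
    """
    if isinstance(rec, PairedMR):
        pair, p_txt = rec, ""
    else:
        pair = rec.pair
        p_txt = f"  p={rec.p_value:.3g}" + (
            f" (adj {rec.p_adjusted:.3g})" if rec.p_adjusted is not None else ""
        )
    pos = np.asarray(pair.positions)
    case = np.asarray(pair.case_levels)
    ctrl = np.asarray(pair.control_levels)
    imp_c = np.asarray(pair.imputed_case)
    imp_w = np.asarray(pair.imputed_control)

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(pos, case, color="#2ca02c", lw=0.8, alpha=0.5)
    ax.plot(pos, ctrl, color="#1f77b4", lw=0.8, alpha=0.5)
    ax.scatter(pos[~imp_c], case[~imp_c], marker="D", color="#d62728", label="case (original)")
    ax.scatter(pos[imp_c], case[imp_c], marker="o", color="#2ca02c", label="case (imputed)")
    ax.scatter(pos[~imp_w], ctrl[~imp_w], marker="D", color="#ff7f0e", label="control (original)")
    ax.scatter(pos[imp_w], ctrl[imp_w], marker="o", color="#1f77b4", label="control (imputed)")
    ax.set_xlabel(f"position on {pair.chrom}")
    ax.set_ylabel("methylation level")
    ax.set_title(
        f"{pair.chrom}:{pair.start}:{pair.end}:{pair.strand}:{pair.gene_name or '.'}{p_txt}",
        fontsize=9,
    )
    ax.legend(fontsize=7)
    fig.tight_layout()

    table = pd.DataFrame(
        {
            "pos": pos,
            "case_level": case,
            "control_level": ctrl,
            "imputed_case": imp_c.astype(int),
            "imputed_control": imp_w.astype(int),
        }
    )
    return _save_with_table(fig, table, out_path)
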