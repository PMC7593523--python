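"""Per-site methylation input: HMST-seq tag counts and WGBS/RRBS levels.

HMST-seq quantifies cytosine modifications at CCGG sites through three
restriction-enzyme tag libraries: MspI (cuts regardless of modification),
BGT (beta-glucosyltransferase protection of 5hmC followed by MspI, so tags
reflect unmodified + 5mC) and HpaII (cuts unmodified cytosine only).  Tag
count ratios between library pairs yield per-site 5mC and 5hmC levels:

    5mC level  = BGT / HpaII
    5hmC level = MspI / BGT

WGBS/RRBS input is a BED-like table of per-base methylation fractions (or
percent), which maps directly onto the 5mC context.

In-memory containers are pandas DataFrames:

* tag-count table -- columns ``chrom, pos, mspI, bgt, hpaII, sample_id,
  condition``;
* site table -- columns ``chrom, pos, level, context, sample_id,
  condition`` with ``context`` in {"5mC", "5hmC"}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TAG_COLUMNS = ["chrom", "pos", "mspI", "bgt", "hpaII", "sample_id", "condition"]
SITE_COLUMNS = ["chrom", "pos", "level", "context", "sample_id", "condition"]


class FormatError(ValueError):
    """Raised for malformed methylation input."""


def read_hmst_tags(
    path: str | Path,
    sample_id: str,
    condition: str,
    columns: Sequence[str] = ("chrom", "pos", "mspI", "bgt", "hpaII"),
) -> pd.DataFrame:
    """Read a per-site HMST-seq normalized tag-count TSV.

    ``columns`` gives the on-disk column order (a header line repeating
    these names is tolerated and skipped).  Sites whose three counts are
    all zero carry no signal and are dropped.
    """
    required = {"chrom", "pos", "mspI", "bgt", "hpaII"}
    missing = required - set(columns)
    if missing:
        raise FormatError(f"column layout lacks {sorted(missing)}")
    df = pd.read_csv(
        path, sep=r"\s+", names=list(columns), comment="#", dtype={"chrom": str}
    )
    if len(df) and not str(df.iloc[0]["pos"]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)  # header row present
    try:
        df["pos"] = df["pos"].astype(np.int64)
        for c in ("mspI", "bgt", "hpaII"):
            df[c] = df[c].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric field: {exc}") from exc
    for c in ("mspI", "bgt", "hpaII"):
        if (df[c] < 0).any():
            bad = df.loc[df[c] < 0].iloc[0]
            raise FormatError(f"{path}: negative {c} count at {bad['chrom']}:{bad['pos']}")
        if not np.isfinite(df[c]).all():
            raise FormatError(f"{path}: non-finite {c} count")
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        positions = df.loc[dup, ["chrom", "pos"]].astype(str).agg(":".join, axis=1)
        raise FormatError(f"{path}: duplicate positions: {', '.join(positions.head(5))}")
    df = df[(df[["mspI", "bgt", "hpaII"]] > 0).any(axis=1)].reset_index(drop=True)
    df["sample_id"] = sample_id
    df["condition"] = condition
    return df[TAG_COLUMNS]


def quantile_normalize(tables: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Quantile-normalize tag counts across samples, per library column.

    Each sample's sorted values in a library column are replaced by the
    across-sample mean at the same rank, so every output column shares one
    reference distribution.  Samples of unequal depth are interpolated onto
    a common quantile grid.  With a single sample this is a no-op (warned).
    """
    if len(tables) < 2:
        log.warning("quantile_normalize: single sample, nothing to normalize")
        return [t.copy() for t in tables]
    out = [t.copy() for t in tables]
    grid_n = max(len(t) for t in tables)
    q = np.linspace(0.0, 1.0, grid_n)
    for col in ("mspI", "bgt", "hpaII"):
        ref = np.mean(
            [np.quantile(t[col].to_numpy(), q, method="linear") for t in tables],
            axis=0,
        )
        for t in out:
            n = len(t)
            if n == 0:
                continue
            order = np.argsort(t[col].to_numpy(), kind="stable")
            ranks = np.empty(n, dtype=float)
            ranks[order] = np.linspace(0.0, 1.0, n) if n > 1 else 0.5
            t[col] = np.interp(ranks, q, ref)
    return out


def tags_to_levels(table: pd.DataFrame, epsilon: float = 1.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert tag counts to (5mC, 5hmC) site tables via library ratios.

    Levels are ``bgt / max(hpaII, epsilon)`` for 5mC and
    ``mspI / max(bgt, epsilon)`` for 5hmC.  The ``epsilon`` floor keeps
    sites whose denominator library has zero tags -- e.g. a fully
    methylated site yields no HpaII tags -- rather than discarding the most
    informative sites.  A site enters a context only when the numerator is
    positive.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    base = table[["chrom", "pos", "sample_id", "condition"]]

    mc = base.copy()
    mc["level"] = table["bgt"].to_numpy() / np.maximum(table["hpaII"].to_numpy(), epsilon)
    mc["context"] = "5mC"
    mc = mc[table["bgt"].to_numpy() > 0]

    hmc = base.copy()
    hmc["level"] = table["mspI"].to_numpy() / np.maximum(table["bgt"].to_numpy(), epsilon)
    hmc["context"] = "5hmC"
    hmc = hmc[table["mspI"].to_numpy() > 0]

    return (
        mc[SITE_COLUMNS].reset_index(drop=True),
        hmc[SITE_COLUMNS].reset_index(drop=True),
    )


def read_bed_levels(
    path: str | Path,
    sample_id: str,
    condition: str,
    scale: str = "auto",
) -> pd.DataFrame:
    """Read WGBS/RRBS per-base methylation as a 5mC site table.

    Accepts BED-like rows ``chrom start [end] level``; the methylated base
    is the 0-based start.  ``scale`` is ``'fraction'``, ``'percent'`` or
    ``'auto'`` (percent if any level exceeds 1).  Output levels are always
    on the 0-1 scale.
    """
    if scale not in ("auto", "fraction", "percent"):
        raise ValueError("scale must be 'auto', 'fraction' or 'percent'")
    rows: list[tuple[str, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                pos = int(parts[1])
                # 4-column BED: chrom start end level; 3-column: chrom pos level
                level = float(parts[3]) if len(parts) >= 4 else float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            rows.append((parts[0], pos, level))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "level"])
    if scale == "auto":
        scale = "percent" if len(df) and df["level"].max() > 1.0 else "fraction"
    hi = 100.0 if scale == "percent" else 1.0
    bad = df[(df["level"] < 0) | (df["level"] > hi)]
    if len(bad):
        r = bad.iloc[0]
        raise FormatError(
            f"{path}: level {r['level']} at {r['chrom']}:{int(r['pos'])} outside [0, {hi:g}]"
        )
    if scale == "percent":
        df["level"] = df["level"] / 100.0
    df["context"] = "5mC"
    df["sample_id"] = sample_id
    df["condition"] = condition
    return df[SITE_COLUMNS]


def write_sites(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a site table as TSV (exact round-trip with :func:`read_sites`)."""
    sites[SITE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_sites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str, "condition": str})
    return df[SITE_COLUMNS]


@dataclass(frozen=True)
class CoverageSummary:
    """Read-depth QC for one sample."""

    sample_id: str
    mean: float
    median: float
    fraction_at_threshold: float
    threshold: float
    n_sites: int

    @property
    def adequate(self) -> bool:
        return self.fraction_at_threshold >= 0.5


def coverage_summary(
    counts: Sequence[float] | np.ndarray,
    threshold: float = 15.0,
    sample_id: str = "",
) -> CoverageSummary:
    """Summarize per-site read counts against a depth threshold.

    Reliable differential-methylation calls want the bulk of sites at or
    above ~15x depth; a warning is logged when fewer than half the sites
    reach the threshold.  The threshold comparison is inclusive (>=).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("coverage_summary: empty input")
    if (arr < 0).any():
        raise ValueError("coverage_summary: negative counts")
    frac = float(np.mean(arr >= threshold))
    summ = CoverageSummary(
        sample_id=sample_id,
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        fraction_at_threshold=frac,
        threshold=threshold,
        n_sites=int(arr.size),
    )
    if frac < 0.5:
        log.warning(
            "coverage_summary(%s): only %.1f%% of sites reach %gx coverage",
            sample_id,
            100 * frac,
            threshold,
        )
    return summ
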