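"""Synthetic methylation data with planted differential loci.

The generator emulates a two-condition methylation experiment at the scale
the pipeline targets: a multi-chromosome genome with regularly spaced
genes, one CpG-site cluster per gene promoter, per-site levels drawn
around a baseline with Gaussian dispersion, and a chosen fraction of loci
carrying a true level shift (delta) of random sign in the case condition.
Output is written in either supported dialect -- WGBS/RRBS BED levels or
HMST-seq three-library tag counts built by inverting the ratio definitions
-- together with the gene annotation inputs and a truth table of planted
loci for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic two-condition methylation experiment.

    One cluster of ``sites_per_locus_min..max`` CpG sites is planted in
    each gene's promoter (within the default +/-1 kb TSS flank), so the
    number of testable promoter loci equals ``n_genes``.  Case levels at a
    planted locus are shifted by ``delta`` (random sign); elsewhere both
    conditions draw independently from the same null distribution.
    ``missing_rate`` drops each site from one condition at random,
    exercising the imputation path.  For the HMST dialect, levels are tag
    ratios around ``baseline`` (default 1.2 so roughly half the null sites
    exceed the customary significance threshold of 1); for WGBS they are
    fractions clipped to [0, 1] around 0.5.
    """

    n_genes: int = 2000
    n_chroms: int = 4
    gene_length: int = 6000
    gene_spacing: int = 30_000
    margin: int = 110_000  # keeps 5'-distance windows inside the chromosome
    frac_planted: float = 0.1
    delta: float = 0.35
    baseline: float = 0.5
    noise_sd: float = 0.1
    sites_per_locus_min: int = 5
    sites_per_locus_max: int = 8
    site_spacing: int = 150
    missing_rate: float = 0.0
    n_enhancers: int = 50
    dialect: str = "wgbs"  # or "hmst"
    hmst_baseline: float = 1.2
    hmst_depth: float = 20.0

    def __post_init__(self) -> None:
        if self.dialect not in ("wgbs", "hmst"):
            raise ValueError("dialect must be 'wgbs' or 'hmst'")
        if not 0 <= self.frac_planted <= 1:
            raise ValueError("frac_planted in [0, 1]")
        if self.sites_per_locus_min < 1 or self.sites_per_locus_max < self.sites_per_locus_min:
            raise ValueError("invalid sites_per_locus bounds")
        max_cluster = (self.sites_per_locus_max - 1) * self.site_spacing
        if max_cluster >= self.gene_spacing - self.gene_length:
            raise ValueError("site cluster does not fit between genes")

    @property
    def genes_per_chrom(self) -> int:
        return -(-self.n_genes // self.n_chroms)  # ceil

    @property
    def chrom_length(self) -> int:
        return 2 * self.margin + self.genes_per_chrom * self.gene_spacing


def _draw_levels(rng: np.random.Generator, n: int, mean: float, sd: float, dialect: str) -> np.ndarray:
    lv = rng.normal(mean, sd, size=n)
    if dialect == "wgbs":
        return np.clip(lv, 0.0, 1.0)
    return np.maximum(lv, 0.05)  # tag ratios stay positive


def generate_fixtures(
    seed: int, spec: FixtureSpec = FixtureSpec(), out_dir: str | Path = "fixtures"
) -> dict[str, Path]:
    """Write a complete synthetic input set; returns ``{name: path}``.

    Files: ``refflat.txt``, ``chrom.sizes``, ``enhancers.bed``, the
    case/control methylation files (``case.bed``/``control.bed`` or
    ``case.tsv``/``control.tsv`` by dialect) and ``truth.tsv`` listing each
    locus with its planted shift and direction.  Identical ``seed`` and
    ``spec`` reproduce the file set byte for byte.
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]

    sizes_path = out / "chrom.sizes"
    with open(sizes_path, "w") as fh:
        for c in chroms:
            fh.write(f"{c}\t{spec.chrom_length}\n")

    # genes on a regular grid, random strand
    gene_rows = []
    for gi in range(spec.n_genes):
        chrom = chroms[gi // spec.genes_per_chrom]
        slot = gi % spec.genes_per_chrom
        tx_start = spec.margin + slot * spec.gene_spacing
        tx_end = tx_start + spec.gene_length
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((f"GENE{gi:05d}", f"TX{gi:05d}", chrom, strand, tx_start, tx_end))
    refflat_path = out / "refflat.txt"
    with open(refflat_path, "w") as fh:
        for name, tx, chrom, strand, s, e in gene_rows:
            fh.write(
                f"{name}\t{tx}\t{chrom}\t{strand}\t{s}\t{e}\t{s}\t{e}\t1\t{s},\t{e},\n"
            )

    # enhancers in gene-free margins (no sites planted there)
    enh_path = out / "enhancers.bed"
    with open(enh_path, "w") as fh:
        for ei in range(spec.n_enhancers):
            chrom = chroms[ei % spec.n_chroms]
            start = 1000 + (ei // spec.n_chroms) * 1500
            fh.write(f"{chrom}\t{start}\t{start + 800}\tENH{ei:04d}\n")

    planted = rng.random(spec.n_genes) < spec.frac_planted
    signs = np.where(rng.random(spec.n_genes) < 0.5, 1, -1)
    signs[~planted] = 0
    base = spec.baseline if spec.dialect == "wgbs" else spec.hmst_baseline

    truth_rows = []
    case_sites: list[tuple[str, int, float]] = []
    ctrl_sites: list[tuple[str, int, float]] = []
    for gi, (name, _tx, chrom, strand, tx_start, tx_end) in enumerate(gene_rows):
        tss_pt = tx_start if strand == "+" else tx_end
        m = int(rng.integers(spec.sites_per_locus_min, spec.sites_per_locus_max + 1))
        first = tss_pt - (m // 2) * spec.site_spacing
        positions = first + np.arange(m) * spec.site_spacing
        ctrl = _draw_levels(rng, m, base, spec.noise_sd, spec.dialect)
        case_mean = base + signs[gi] * spec.delta
        case = _draw_levels(rng, m, case_mean, spec.noise_sd, spec.dialect)
        keep_case = rng.random(m) >= spec.missing_rate
        keep_ctrl = rng.random(m) >= spec.missing_rate
        # a locus must survive in both conditions to stay pairable
        if not keep_case.any():
            keep_case[0] = True
        if not keep_ctrl.any():
            keep_ctrl[0] = True
        for p, v in zip(positions[keep_case], case[keep_case]):
            case_sites.append((chrom, int(p), float(v)))
        for p, v in zip(positions[keep_ctrl], ctrl[keep_ctrl]):
            ctrl_sites.append((chrom, int(p), float(v)))
        truth_rows.append(
            (
                name,
                chrom,
                int(positions[0]),
                int(positions[-1]) + 1,
                int(planted[gi]),
                int(signs[gi]),
                spec.delta if planted[gi] else 0.0,
                m,
            )
        )

    truth_path = out / "truth.tsv"
    pd.DataFrame(
        truth_rows,
        columns=["gene_name", "chrom", "start", "end", "planted", "direction", "delta", "n_sites"],
    ).to_csv(truth_path, sep="\t", index=False)

    paths = {
        "refflat": refflat_path,
        "chrom_sizes": sizes_path,
        "enhancers": enh_path,
        "truth": truth_path,
    }

    if spec.dialect == "wgbs":
        for cond, sites in (("case", case_sites), ("control", ctrl_sites)):
            p = out / f"{cond}.bed"
            with open(p, "w") as fh:
                for chrom, pos, lv in sorted(sites):
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{lv!r}\n")
            paths[cond] = p
    else:
        # invert the ratio definitions: hpaII at fixed depth, bgt = 5mC
        # level * hpaII, mspI = 5hmC level * bgt.  The same generated level
        # plays the 5mC role; an independent null-level series supplies 5hmC.
        for cond, sites in (("case", case_sites), ("control", ctrl_sites)):
            p = out / f"{cond}.tsv"
            hmc = _draw_levels(rng, len(sites), spec.hmst_baseline, spec.noise_sd, "hmst")
            with open(p, "w") as fh:
                fh.write("chrom\tpos\tmspI\tbgt\thpaII\n")
                for (chrom, pos, lv), lh in zip(sorted(sites), hmc):
                    hpa = float(spec.hmst_depth)
                    bgt = float(lv * hpa)
                    msp = float(lh * bgt)
                    fh.write(f"{chrom}\t{pos}\t{msp!r}\t{bgt!r}\t{hpa!r}\n")
            paths[cond] = p

    with open(out / "fixture_spec.txt", "w") as fh:
        fh.write(f"seed\t{seed}\n")
        for k, v in asdict(spec).items():
            fh.write(f"{k}\t{v}\n")
    paths["spec"] = out / "fixture_spec.txt"
    return paths
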