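"""Evaluation of DMR calls against a synthetic truth table.

Runs the promoter-locus analysis (region extraction, MR search, pairing,
testing) on a generated fixture set and joins the per-locus results to the
generator's truth table, yielding the quantities used to characterize the
method: type-I error on null loci, recovery and direction agreement on
planted loci.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from . import dmr_stats, genome_regions, methylation_io, mr_search


def promoter_locus_results(
    paths: Mapping[str, Path],
    cfg: dmr_stats.TestConfig = dmr_stats.TestConfig(),
    params: mr_search.MrSearchParams = mr_search.MrSearchParams(),
    dialect: str = "wgbs",
    context: str = "5mC",
) -> pd.DataFrame:
    """Per-promoter-locus test results joined to the fixture truth table.

    Restricts to TSS-class loci, where the generator plants exactly one
    site cluster per gene, so each row is one locus with columns from the
    truth table (``planted``, ``direction`` as -1/0/+1) plus ``p_value``,
    ``rratio``, ``called`` (p below ``cfg.alpha``) and ``called_direction``.
    """
    sizes = genome_regions.read_chrom_sizes(paths["chrom_sizes"])
    genes = genome_regions.read_refflat(paths["refflat"], sizes)
    regions = [
        r
        for r in genome_regions.extract_regions(genes, sizes)
        if r.region_class == "TSS"
    ]
    if dialect == "wgbs":
        case_sites = methylation_io.read_bed_levels(paths["case"], "case1", "case", "fraction")
        ctrl_sites = methylation_io.read_bed_levels(paths["control"], "control1", "control", "fraction")
    else:
        case_tags = methylation_io.read_hmst_tags(paths["case"], "case1", "case")
        ctrl_tags = methylation_io.read_hmst_tags(paths["control"], "control1", "control")
        idx = 0 if context == "5mC" else 1
        case_sites = methylation_io.tags_to_levels(case_tags)[idx]
        ctrl_sites = methylation_io.tags_to_levels(ctrl_tags)[idx]

    case_mrs = mr_search.find_mrs(case_sites, regions, params)
    ctrl_mrs = mr_search.find_mrs(ctrl_sites, regions, params)
    pairs = dmr_stats.pair_mrs(case_mrs, ctrl_mrs, cfg.impute)
    records, _ = dmr_stats.dmr_search(pairs, cfg)

    rows = [
        (
            r.pair.gene_name,
            r.pair.chrom,
            r.p_value,
            r.rratio,
            bool(r.significant),
            r.direction,
        )
        for r in records
    ]
    results = pd.DataFrame(
        rows, columns=["gene_name", "chrom", "p_value", "rratio", "called", "called_direction"]
    )
    truth = pd.read_csv(paths["truth"], sep="\t")
    return truth.merge(results, on=["gene_name", "chrom"], how="inner")


def summarize_results(df: pd.DataFrame) -> dict[str, float]:
    """Headline metrics from :func:`promoter_locus_results` output."""
    null = df[df["planted"] == 0]
    planted = df[df["planted"] == 1]
    out: dict[str, float] = {
        "n_loci_tested": float(len(df)),
        "n_null_loci": float(len(null)),
        "n_planted_loci": float(len(planted)),
    }
    if len(null):
        out["type_i_fraction"] = float(null["called"].mean())
    if len(planted):
        correct = planted["called"] & (
            planted["called_direction"].map({"hyper": 1, "hypo": -1, "none": 0})
            == planted["direction"]
        )
        out["recovery_rate"] = float(correct.mean())
        called = planted[planted["called"]]
        if len(called):
            sign_match = (
                called["rratio"].apply(lambda v: 1 if v > 0 else (-1 if v < 0 else 0))
                == called["direction"]
            )
            out["direction_agreement"] = float(sign_match.mean())
    return out
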