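"""Eight-stage differential-methylation pipeline with a run manifest.

Stages: qc, annotate_genome, preprocess, find_mrs, prepare_dmr,
dmr_search, annotate_dmrs, summarize.  Each stage writes its products
under the run directory and records a completion marker (keyed by a hash
of the configuration and input digests) in ``manifest.json``; re-running a
completed stage with unchanged inputs is a no-op, and running a stage
before its prerequisites raises an error naming the stage to run first.

The MR search, MR pairing and DMR testing stages shard work by chromosome
across ``n_cpus`` processes; outputs are canonically sorted before
writing, so results are byte-identical for any CPU count.  On HMST input
both the 5mC and 5hmC contexts are processed in a single run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from multiprocessing import get_context
from pathlib import Path

import pandas as pd

from . import annotate_export, dmr_stats, genome_regions, methylation_io, mr_search, profiles

log = logging.getLogger(__name__)

STAGES = (
    "qc",
    "annotate_genome",
    "preprocess",
    "find_mrs",
    "prepare_dmr",
    "dmr_search",
    "annotate_dmrs",
    "summarize",
)

#: prerequisite stages that must have completed first
PREREQUISITES: dict[str, tuple[str, ...]] = {
    "qc": (),
    "annotate_genome": (),
    "preprocess": (),
    "find_mrs": ("annotate_genome", "preprocess"),
    "prepare_dmr": ("find_mrs",),
    "dmr_search": ("prepare_dmr",),
    "annotate_dmrs": ("dmr_search",),
    "summarize": ("annotate_dmrs",),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Full parameter snapshot for one pipeline run."""

    # inputs
    dialect: str = "hmst"  # or "wgbs"
    case_files: tuple[str, ...] = ()
    control_files: tuple[str, ...] = ()
    refflat: str = ""
    chrom_sizes: str = ""
    enhancers: str = ""  # optional BED
    scale: str = "auto"  # wgbs level scale
    # preprocessing
    quantile_norm: bool = False
    epsilon: float = 1.0
    coverage_threshold: float = 15.0
    # region extraction
    tss_flank: int = 1000
    tes_flank: int = 1000
    fpd_near: int = 10_000
    fpd_far: int = 100_000
    intergenic_min: int = 2000
    intergenic_max: int = 100_000
    # MR search (CLI: -mc1/-mc2/-mc3, -a, -W, -isST)
    mc1: int = 3
    mc2: int = 5
    mc3: int = 3
    adjacency: int = 2000
    use_windows: bool = False
    window_size: int = 200
    isST: int = 0
    # DMR testing
    test: str = "ranksum"
    exact_threshold: int = 10
    alpha: float = 0.05
    bh_correct: bool = False
    impute: str = "zeros"
    # summaries
    level_threshold: float = -1.0  # <0: dialect default (1.0 hmst, 0.5 wgbs)
    n_bins: int = 100
    ma_window: int = 3
    sigma: float = 2.0
    min_dmcs_per_promoter: int = 2
    # execution
    n_cpus: int = 1
    seed: int = 0
    label: str = "run"

    def mr_params(self) -> mr_search.MrSearchParams:
        return mr_search.MrSearchParams(
            min_sites_tss_tes=self.mc1,
            min_sites_body_fpd_intergenic=self.mc2,
            min_sites_enhancer=self.mc3,
            max_adjacency_a=self.adjacency,
            use_windows=self.use_windows,
            window_size=self.window_size,
            same_trend_isST=self.isST,
        )

    def test_config(self) -> dmr_stats.TestConfig:
        return dmr_stats.TestConfig(
            test=self.test,
            exact_threshold=self.exact_threshold,
            alpha=self.alpha,
            bh_correct=self.bh_correct,
            impute=self.impute,
            isST=self.isST,
        )

    @property
    def contexts(self) -> tuple[str, ...]:
        return ("5mC", "5hmC") if self.dialect == "hmst" else ("5mC",)

    @property
    def effective_level_threshold(self) -> float:
        if self.level_threshold >= 0:
            return self.level_threshold
        return 1.0 if self.dialect == "hmst" else 0.5


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    pass


# --- multiprocessing workers (module level so they pickle) -----------------


def _mr_worker(args):
    sites, regions, params = args
    return mr_search.find_mrs(sites, regions, params)


def _pair_worker(args):
    case_mrs, control_mrs, impute = args
    return dmr_stats.pair_mrs(case_mrs, control_mrs, impute)


def _test_worker(args):
    pairs, cfg = args
    records, skipped = [], 0
    for p in pairs:
        rec = dmr_stats.test_mr(p, cfg)
        if rec is None:
            skipped += 1
        else:
            records.append(rec)
    return records, skipped


def _parallel_map(worker, jobs, n_cpus: int):
    if n_cpus <= 1 or len(jobs) <= 1:
        return [worker(j) for j in jobs]
    with get_context("fork").Pool(min(n_cpus, len(jobs))) as pool:
        return pool.map(worker, jobs)


class Pipeline:
    """Stage runner bound to one run directory and configuration."""

    def __init__(self, run_dir: str | Path, config: PipelineConfig):
        self.run_dir = Path(run_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self.config = config
        self.manifest_path = self.run_dir / "manifest.json"
        self.manifest = self._load_manifest()

    # --- manifest ---------------------------------------------------------

    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            return json.loads(self.manifest_path.read_text())
        return {
            "run_id": f"{self.config.label}-{self.config.seed}",
            "seed": self.config.seed,
            "params": asdict(self.config),
            "input_digests": {},
            "stages": {},
        }

    def _save_manifest(self) -> None:
        self.manifest["params"] = asdict(self.config)
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))

    def _config_hash(self) -> str:
        cfg = asdict(self.config)
        cfg.pop("n_cpus")  # CPU count must not affect outputs
        digests = {}
        for key in ("refflat", "chrom_sizes", "enhancers"):
            p = getattr(self.config, key)
            if p and Path(p).exists():
                digests[key] = _digest(p)
        for i, p in enumerate(self.config.case_files + self.config.control_files):
            digests[f"input{i}"] = _digest(p)
        self.manifest["input_digests"] = digests
        blob = json.dumps({"cfg": cfg, "digests": digests}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()

    def _stage_done(self, stage: str) -> bool:
        info = self.manifest["stages"].get(stage)
        return bool(info) and info.get("config_hash") == self._config_hash()

    def _check_prerequisites(self, stage: str) -> None:
        missing = [s for s in PREREQUISITES[stage] if not self._stage_done(s)]
        if missing:
            raise StageError(
                f"stage '{stage}' requires completed stage(s) {missing}; run them first"
            )

    def _mark_done(self, stage: str, elapsed: float, **extra) -> None:
        self.manifest["stages"][stage] = {
            "config_hash": self._config_hash(),
            "elapsed_s": round(elapsed, 3),
            **extra,
        }
        self._save_manifest()

    def run_stage(self, stage: str) -> None:
        """Run one stage (skipped when already done with identical config)."""
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if self._stage_done(stage):
            log.info("stage %s: up to date, skipped", stage)
            return
        self._check_prerequisites(stage)
        t0 = time.perf_counter()
        getattr(self, f"_stage_{stage}")()
        self._mark_done(stage, time.perf_counter() - t0)
        log.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)

    def run_all(self) -> None:
        for stage in STAGES:
            self.run_stage(stage)

    # --- sample bookkeeping -------------------------------------------------

    def _samples(self) -> list[tuple[str, str, str]]:
        """(condition, sample_id, path) for every input methylation file."""
        out = []
        for i, p in enumerate(self.config.case_files):
            out.append(("case", f"case{i + 1}", p))
        for i, p in enumerate(self.config.control_files):
            out.append(("control", f"control{i + 1}", p))
        return out

    def _sites_path(self, condition: str, sample_id: str, context: str) -> Path:
        return self.run_dir / "sites" / f"sites_{condition}_{sample_id}_{context}.tsv"

    def _mrs_path(self, condition: str, sample_id: str, context: str) -> Path:
        return self.run_dir / "mrs" / f"mrs_{condition}_{sample_id}_{context}.tsv"

    # --- stages -------------------------------------------------------------

    def _stage_qc(self) -> None:
        out = self.run_dir / "qc"
        out.mkdir(exist_ok=True)
        rows = []
        if self.config.dialect == "hmst":
            for condition, sample_id, path in self._samples():
                tags = methylation_io.read_hmst_tags(path, sample_id, condition)
                counts = tags[["mspI", "bgt", "hpaII"]].mean(axis=1).to_numpy()
                s = methylation_io.coverage_summary(
                    counts, self.config.coverage_threshold, sample_id
                )
                rows.append(
                    (sample_id, condition, s.n_sites, s.mean, s.median,
                     s.fraction_at_threshold, int(s.adequate))
                )
        df = pd.DataFrame(
            rows,
            columns=["sample_id", "condition", "n_sites", "mean_count",
                     "median_count", "fraction_at_threshold", "adequate"],
        )
        df.to_csv(out / "coverage_summary.tsv", sep="\t", index=False, float_format="%.17g")
        if self.config.dialect != "hmst":
            (out / "README.txt").write_text(
                "WGBS/RRBS level input carries no per-site read counts; "
                "coverage QC applies to HMST tag-count input only.\n"
            )

    def _stage_annotate_genome(self) -> None:
        sizes = genome_regions.read_chrom_sizes(self.config.chrom_sizes)
        genes = genome_regions.read_refflat(self.config.refflat, sizes)
        regions = genome_regions.extract_regions(
            genes,
            sizes,
            tss_flank=self.config.tss_flank,
            tes_flank=self.config.tes_flank,
            fpd_near=self.config.fpd_near,
            fpd_far=self.config.fpd_far,
            intergenic_min=self.config.intergenic_min,
            intergenic_max=self.config.intergenic_max,
        )
        if self.config.enhancers:
            regions = regions + genome_regions.read_region_bed(self.config.enhancers)
        genome_regions.write_region_beds(regions, self.run_dir / "regions")

    def _stage_preprocess(self) -> None:
        (self.run_dir / "sites").mkdir(exist_ok=True)
        if self.config.dialect == "hmst":
            samples = self._samples()
            tables = [
                methylation_io.read_hmst_tags(path, sample_id, condition)
                for condition, sample_id, path in samples
            ]
            if self.config.quantile_norm and len(tables) > 1:
                tables = methylation_io.quantile_normalize(tables)
            for (condition, sample_id, _), tags in zip(samples, tables):
                mc, hmc = methylation_io.tags_to_levels(tags, self.config.epsilon)
                methylation_io.write_sites(mc, self._sites_path(condition, sample_id, "5mC"))
                methylation_io.write_sites(hmc, self._sites_path(condition, sample_id, "5hmC"))
        else:
            for condition, sample_id, path in self._samples():
                sites = methylation_io.read_bed_levels(
                    path, sample_id, condition, self.config.scale
                )
                methylation_io.write_sites(sites, self._sites_path(condition, sample_id, "5mC"))

    def _regions(self) -> list[genome_regions.GenomicRegion]:
        return genome_regions.read_region_beds(self.run_dir / "regions")

    def _stage_find_mrs(self) -> None:
        (self.run_dir / "mrs").mkdir(exist_ok=True)
        regions = self._regions()
        regions_by_chrom: dict[str, list] = {}
        for r in regions:
            regions_by_chrom.setdefault(r.chrom, []).append(r)
        params = self.config.mr_params()
        for condition, sample_id, _ in self._samples():
            for context in self.config.contexts:
                sites = methylation_io.read_sites(self._sites_path(condition, sample_id, context))
                jobs = []
                for chrom in sorted(regions_by_chrom):
                    chrom_sites = sites[sites["chrom"] == chrom]
                    if len(chrom_sites):
                        jobs.append((chrom_sites, regions_by_chrom[chrom], params))
                results = _parallel_map(_mr_worker, jobs, self.config.n_cpus)
                mrs = sorted(
                    (m for part in results for m in part),
                    key=lambda m: (m.chrom, m.start, m.end, m.region_class, m.gene_name),
                )
                mr_search.write_mrs(mrs, self._mrs_path(condition, sample_id, context))

    def _stage_prepare_dmr(self) -> None:
        (self.run_dir / "pairs").mkdir(exist_ok=True)
        for context in self.config.contexts:
            case_mrs: list[mr_search.MethylatedRegion] = []
            control_mrs: list[mr_search.MethylatedRegion] = []
            for condition, sample_id, _ in self._samples():
                path = self._mrs_path(condition, sample_id, context)
                mrs = mr_search.read_mrs(path)
                (case_mrs if condition == "case" else control_mrs).extend(mrs)
            chroms = sorted({m.chrom for m in case_mrs} | {m.chrom for m in control_mrs})
            jobs = [
                (
                    [m for m in case_mrs if m.chrom == c],
                    [m for m in control_mrs if m.chrom == c],
                    self.config.impute,
                )
                for c in chroms
            ]
            results = _parallel_map(_pair_worker, jobs, self.config.n_cpus)
            pairs = sorted(
                (p for part in results for p in part),
                key=lambda p: (p.chrom, p.start, p.end, p.region_class, p.gene_name),
            )
            dmr_stats.write_pairs(pairs, self.run_dir / "pairs" / f"pairs_{context}.tsv")

    def _stage_dmr_search(self) -> None:
        (self.run_dir / "dmr").mkdir(exist_ok=True)
        cfg = self.config.test_config()
        for context in self.config.contexts:
            pairs = dmr_stats.read_pairs(self.run_dir / "pairs" / f"pairs_{context}.tsv")
            chroms = sorted({p.chrom for p in pairs})
            jobs = [([p for p in pairs if p.chrom == c], cfg) for c in chroms]
            results = _parallel_map(_test_worker, jobs, self.config.n_cpus)
            records = [r for recs, _ in results for r in recs]
            skipped = sum(s for _, s in results)
            records.sort(key=lambda r: (r.pair.chrom, r.pair.start, r.pair.end,
                                        r.pair.region_class, r.pair.gene_name))
            called = dmr_stats.call_dmrs(records, cfg)
            dmr_stats.write_dmrs(called, self.run_dir / "dmr" / f"dmrs_{context}.tsv")
            if skipped:
                log.info("dmr_search[%s]: %d pairs failed the same-trend gate", context, skipped)

    def _stage_annotate_dmrs(self) -> None:
        for context in self.config.contexts:
            records = dmr_stats.read_dmrs(self.run_dir / "dmr" / f"dmrs_{context}.tsv")
            annotated = annotate_export.annotate(records)
            annotate_export.export_tables(
                annotated,
                self.run_dir / "annotated",
                self.config.label,
                context,
                self.config.min_dmcs_per_promoter,
            )

    def _stage_summarize(self) -> None:
        out = self.run_dir / "summary"
        out.mkdir(exist_ok=True)
        regions = self._regions()
        grid = profiles.ProfileGrid(
            n_bins=self.config.n_bins,
            ma_window=self.config.ma_window,
            sigma=self.config.sigma,
        )
        thr = self.config.effective_level_threshold
        for context in self.config.contexts:
            density_frames = []
            meta: dict[str, object] = {}
            for condition, sample_id, _ in self._samples():
                sites = methylation_io.read_sites(self._sites_path(condition, sample_id, context))
                d = profiles.relative_density(sites, regions, thr)
                d.insert(0, "sample_id", sample_id)
                d.insert(1, "condition", condition)
                density_frames.append(d)
                mrs = mr_search.read_mrs(self._mrs_path(condition, sample_id, context))
                meta[sample_id] = profiles.meta_profile(mrs, regions, grid)
            density = pd.concat(density_frames, ignore_index=True)
            profiles.plot_density(
                density,
                out / f"density_{context}.png",
                title=f"Significant {context} sites per Mb (level > {thr:g})",
            )
            records = dmr_stats.read_dmrs(self.run_dir / "dmr" / f"dmrs_{context}.tsv")
            annotated = annotate_export.annotate(records)
            pct = profiles.direction_percentages(annotated, context)
            profiles.plot_direction_percentages(
                pct, out / f"dmr_direction_{context}.png",
                title=f"Hyper/hypo {context} DMRs per region class",
            )
            profiles.plot_meta_profile(
                meta, grid, out / f"meta_profile_{context}.png",
                title=f"Average {context} profile over TSS-gene-TES",
            )


def run_pipeline(run_dir: str | Path, config: PipelineConfig) -> Pipeline:
    """Run every stage and return the pipeline handle."""
    pipe = Pipeline(run_dir, config)
    pipe.run_all()
    return pipe
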