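"""Differential testing of paired methylated regions.

Case and control MRs sharing a locus are paired, missing per-site values
are imputed, and each pair is tested for a shift in methylation level.
The default test is a Wilcoxon rank-sum whose P-value is computed by exact
enumeration when the site count is small (< 10) and by the normal
approximation of the Mann-Whitney U test (with tie correction) otherwise.
Significant pairs are classified hyper- or hypomethylated by the relative
ratio of the two condition medians.

The exact P-value uses a generating-function ("shift") algorithm over
integer-scaled mid-ranks, so ties are handled identically to an explicit
enumeration of all C(nx+ny, nx) assignments, at polynomial cost.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mr_search import MethylatedRegion, is_same_trend

log = logging.getLogger(__name__)

IMPUTE_STRATEGIES = ("zeros", "median", "nearest_neighbour")
TESTS = ("ranksum", "ks", "ttest")


@dataclass(frozen=True)
class PairedMR:
    """Two same-locus MRs with aligned, imputed level vectors.

    ``positions`` is the sorted union of case and control site positions;
    the level vectors are aligned to it, with imputed entries flagged in
    the masks.  Original (observed) levels are recoverable by masking.
    """

    chrom: str
    start: int
    end: int
    region_class: str
    gene_name: str
    context: str
    positions: tuple[int, ...]
    case_levels: tuple[float, ...]
    control_levels: tuple[float, ...]
    imputed_case: tuple[bool, ...]
    imputed_control: tuple[bool, ...]
    strand: str = "."

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (
            len(self.case_levels)
            == len(self.control_levels)
            == len(self.imputed_case)
            == len(self.imputed_control)
            == n
        ) or n == 0:
            raise ValueError("aligned vectors must share nonzero length")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def observed_case(self) -> np.ndarray:
        return np.asarray(self.case_levels)[~np.asarray(self.imputed_case)]

    def observed_control(self) -> np.ndarray:
        return np.asarray(self.control_levels)[~np.asarray(self.imputed_control)]

    def swapped(self) -> "PairedMR":
        """The same locus with case and control roles exchanged."""
        return replace(
            self,
            case_levels=self.control_levels,
            control_levels=self.case_levels,
            imputed_case=self.imputed_control,
            imputed_control=self.imputed_case,
        )


@dataclass(frozen=True)
class DmrRecord:
    """A tested paired MR with P-value, effect direction and annotation."""

    pair: PairedMR
    p_value: float
    test_name: str
    rratio: float
    direction: str  # hyper | hypo | none
    p_adjusted: float | None = None
    significant: bool = False


@dataclass(frozen=True)
class TestConfig:
    """Statistical-test configuration for the DMR search.

    ``exact_threshold`` is the site count below which the rank-sum P-value
    is enumerated exactly (strict <, applied to the case-side count).
    ``mranksum_rule=True`` switches to the alternative small-sample gate
    ``min(nx, ny) < 10 and nx + ny < 20``.
    """

    test: str = "ranksum"
    exact_threshold: int = 10
    alpha: float = 0.05
    bh_correct: bool = False
    impute: str = "zeros"
    isST: int = 0
    mranksum_rule: bool = False

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise ValueError(f"unknown test {self.test!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.exact_threshold < 2:
            raise ValueError("exact_threshold must be >= 2")
        if self.impute not in IMPUTE_STRATEGIES:
            raise ValueError(f"unknown imputation strategy {self.impute!r}")
        if self.isST not in (0, 1):
            raise ValueError("isST is 0 or 1")


# ---------------------------------------------------------------------------
# pairing and imputation


def _impute(
    positions: np.ndarray,
    observed_pos: np.ndarray,
    observed_lev: np.ndarray,
    strategy: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (levels, imputed_mask) for one condition over the union grid."""
    levels = np.zeros(len(positions), dtype=float)
    mask = np.ones(len(positions), dtype=bool)
    idx = {int(p): i for i, p in enumerate(observed_pos)}
    for i, p in enumerate(positions):
        j = idx.get(int(p))
        if j is not None:
            levels[i] = observed_lev[j]
            mask[i] = False
    missing = np.nonzero(mask)[0]
    if len(missing) == 0:
        return levels, mask
    if strategy == "zeros":
        pass  # already zero: a plausible truly-unmethylated state
    elif strategy == "median":
        levels[missing] = float(np.median(observed_lev))
    elif strategy == "nearest_neighbour":
        for i in missing:
            j = int(np.argmin(np.abs(observed_pos - positions[i])))
            levels[i] = observed_lev[j]
    else:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    return levels, mask


def _pool_condition(mrs: Sequence[MethylatedRegion]) -> tuple[np.ndarray, np.ndarray]:
    """Pool (position, level) pairs of one condition's MRs at a locus.

    Replicate observations at the same position are averaged so the level
    vector stays aligned one-to-one with the union position grid.
    """
    acc: dict[int, list[float]] = {}
    for m in mrs:
        for p, v in zip(m.sites, m.levels):
            acc.setdefault(int(p), []).append(float(v))
    pos = np.array(sorted(acc), dtype=np.int64)
    lev = np.array([float(np.mean(acc[int(p)])) for p in pos], dtype=float)
    return pos, lev


def pair_mrs(
    case_mrs: Sequence[MethylatedRegion],
    control_mrs: Sequence[MethylatedRegion],
    impute: str = "zeros",
) -> list[PairedMR]:
    """Pair case and control MRs sharing a locus and impute missing sites.

    Two MRs share a locus when their bounding intervals overlap by >= 1 bp
    within the same chromosome, region class and gene linkage.  Transitively
    overlapping MRs on either side are merged into one locus.  The paired
    site set is the union of positions; positions unobserved in one
    condition receive imputed levels: ``zeros`` (default -- a missing site
    may be a truly unmethylated state), the ``median`` of that condition's
    observed levels, or the level of the ``nearest_neighbour`` observed
    position.  MRs without a partner in the other condition are dropped
    (counted in the log).
    """
    if impute not in IMPUTE_STRATEGIES:
        raise ValueError(f"unknown imputation strategy {impute!r}")

    def key(m: MethylatedRegion):
        return (m.chrom, m.region_class, m.gene_name)

    buckets: dict[tuple, dict[str, list[MethylatedRegion]]] = {}
    for m in case_mrs:
        buckets.setdefault(key(m), {"case": [], "control": []})["case"].append(m)
    for m in control_mrs:
        buckets.setdefault(key(m), {"case": [], "control": []})["control"].append(m)

    pairs: list[PairedMR] = []
    n_unpaired = 0
    for (chrom, region_class, gene_name), sides in sorted(buckets.items()):
        entries = [("case", m) for m in sides["case"]] + [
            ("control", m) for m in sides["control"]
        ]
        entries.sort(key=lambda e: (e[1].start, e[1].end))
        # sweep: chain entries whose intervals transitively overlap
        components: list[list[tuple[str, MethylatedRegion]]] = []
        cur_end = -1
        for cond, m in entries:
            if not components or m.start >= cur_end:
                components.append([])
                cur_end = m.end
            else:
                cur_end = max(cur_end, m.end)
            components[-1].append((cond, m))
        for comp in components:
            case_side = [m for c, m in comp if c == "case"]
            ctrl_side = [m for c, m in comp if c == "control"]
            if not case_side or not ctrl_side:
                n_unpaired += len(comp)
                continue
            cpos, clev = _pool_condition(case_side)
            wpos, wlev = _pool_condition(ctrl_side)
            positions = np.union1d(cpos, wpos)
            case_levels, case_mask = _impute(positions, cpos, clev, impute)
            ctrl_levels, ctrl_mask = _impute(positions, wpos, wlev, impute)
            pairs.append(
                PairedMR(
                    chrom=chrom,
                    start=int(positions[0]),
                    end=int(positions[-1]) + 1,
                    region_class=region_class,
                    gene_name=gene_name,
                    context=comp[0][1].context,
                    positions=tuple(int(p) for p in positions),
                    case_levels=tuple(float(v) for v in case_levels),
                    control_levels=tuple(float(v) for v in ctrl_levels),
                    imputed_case=tuple(bool(b) for b in case_mask),
                    imputed_control=tuple(bool(b) for b in ctrl_mask),
                )
            )
    if n_unpaired:
        log.info("pair_mrs: %d MRs had no partner in the other condition", n_unpaired)
    return pairs


# ---------------------------------------------------------------------------
# exact rank-sum enumeration


def _scaled_midranks(pooled: np.ndarray) -> np.ndarray:
    """Pooled mid-ranks scaled by 2 so that ties yield exact integers."""
    ranks = stats.rankdata(pooled, method="average") * 2.0
    iranks = np.rint(ranks).astype(np.int64)
    assert np.allclose(ranks, iranks), "mid-ranks must be half-integers"
    return iranks


def exact_ranksum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact Wilcoxon rank-sum P-value by full enumeration.

    The null distribution of the rank-sum of ``x`` is computed over all
    C(nx+ny, nx) equally likely assignments of the pooled mid-ranks (ties
    receive mid-ranks).  The two-sided P-value is twice the smaller tail,
    capped at 1.  The enumeration runs as a subset-sum generating function
    over integer-scaled ranks in exact integer arithmetic, so the result
    equals a literal listing of every assignment.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("exact_ranksum_p: empty sample")
    nx, n = x.size, x.size + y.size
    iranks = _scaled_midranks(np.concatenate([x, y]))
    w_obs = int(iranks[:nx].sum())

    # dp[k][s] = number of k-subsets of the scaled ranks with sum s
    max_sum = int(iranks.sum())
    dp = [dict() for _ in range(nx + 1)]
    dp[0][0] = 1
    for r in iranks.tolist():
        for k in range(min(nx, n) - 1, -1, -1):
            row = dp[k]
            nxt = dp[k + 1]
            for s, c in row.items():
                nxt[s + r] = nxt.get(s + r, 0) + c
    dist = dp[nx]
    total = math.comb(n, nx)
    assert sum(dist.values()) == total
    le = sum(c for s, c in dist.items() if s <= w_obs)
    ge = sum(c for s, c in dist.items() if s >= w_obs)
    p = 2 * Fraction(min(le, ge), total)
    return float(min(p, Fraction(1)))


def approx_ranksum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided normal-approximation Mann-Whitney P-value (tie-corrected)."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# per-pair testing


def rratio(pair: PairedMR) -> float:
    """Relative ratio of condition medians: (m_case - m_ctrl) / mean(medians).

    Medians are taken over the ORIGINAL (non-imputed) levels only.  Returns
    0 when both medians are 0 (direction undefined).
    """
    mu_case = float(np.median(pair.observed_case()))
    mu_ctrl = float(np.median(pair.observed_control()))
    denom = (mu_case + mu_ctrl) / 2.0
    if denom == 0:
        return 0.0
    return (mu_case - mu_ctrl) / denom


def direction_of(r: float) -> str:
    if r > 0:
        return "hyper"
    if r < 0:
        return "hypo"
    return "none"


def _ranksum_p(x: np.ndarray, y: np.ndarray, cfg: TestConfig) -> tuple[float, str]:
    nx, ny = len(x), len(y)
    if cfg.mranksum_rule:
        exact = min(nx, ny) < cfg.exact_threshold and nx + ny < 2 * cfg.exact_threshold
    else:
        exact = nx < cfg.exact_threshold
    if exact:
        return exact_ranksum_p(x, y), "exact_ranksum"
    return approx_ranksum_p(x, y), "mannwhitneyu"


def test_mr(pair: PairedMR, cfg: TestConfig = TestConfig()) -> DmrRecord | None:
    """Test one paired MR for differential methylation.

    Returns ``None`` when ``cfg.isST=1`` and either condition's observed
    level vector is not same-trend (the pair is inadmissible, counted by
    the caller).  The rank-sum test takes the exact path when the case-side
    site count is below ``cfg.exact_threshold`` (strict), otherwise the
    tie-corrected normal approximation.  A zero-variance T-test (identical
    constant vectors) is assigned p = 1 by convention.
    """
    if cfg.isST == 1 and not (
        is_same_trend(pair.observed_case()) and is_same_trend(pair.observed_control())
    ):
        return None
    x = np.asarray(pair.case_levels, dtype=float)
    y = np.asarray(pair.control_levels, dtype=float)
    if cfg.test == "ranksum":
        if np.all(x == y):
            p, name = 1.0, "exact_ranksum" if len(x) < cfg.exact_threshold else "mannwhitneyu"
        else:
            p, name = _ranksum_p(x, y, cfg)
    elif cfg.test == "ks":
        p = float(stats.ks_2samp(x, y, alternative="two-sided").pvalue)
        name = "ks"
    elif cfg.test == "ttest":
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            # zero pooled variance: undefined t statistic; identical constants
            # are no evidence of difference, distinct constants are extreme
            p = 1.0 if x[0] == y[0] else 0.0
            log.debug("test_mr: zero-variance vectors, p=%g by convention", p)
        else:
            p = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
        name = "ttest"
    else:  # pragma: no cover - guarded by TestConfig
        raise ValueError(cfg.test)
    r = rratio(pair)
    return DmrRecord(pair=pair, p_value=p, test_name=name, rratio=r, direction=direction_of(r))


def call_dmrs(records: Sequence[DmrRecord], cfg: TestConfig = TestConfig()) -> list[DmrRecord]:
    """Flag significant records as DMRs, optionally after BH correction.

    With ``cfg.bh_correct`` the Benjamini-Hochberg adjusted P-values are
    computed over the whole record list and the alpha threshold applies to
    them; otherwise to the raw P-values.  Returns new records (all inputs,
    with ``p_adjusted`` and ``significant`` filled in).
    """
    if not records:
        return []
    out: list[DmrRecord] = []
    if cfg.bh_correct:
        raw = np.array([r.p_value for r in records])
        adj = stats.false_discovery_control(raw, method="bh")
        for rec, pa in zip(records, adj):
            out.append(replace(rec, p_adjusted=float(pa), significant=bool(pa < cfg.alpha)))
    else:
        for rec in records:
            out.append(replace(rec, p_adjusted=None, significant=bool(rec.p_value < cfg.alpha)))
    return out


def dmr_search(
    pairs: Sequence[PairedMR], cfg: TestConfig = TestConfig()
) -> tuple[list[DmrRecord], int]:
    """Test all pairs and call DMRs; returns (records, n_skipped_by_isST)."""
    records: list[DmrRecord] = []
    skipped = 0
    for pair in pairs:
        rec = test_mr(pair, cfg)
        if rec is None:
            skipped += 1
        else:
            records.append(rec)
    if skipped:
        log.info("dmr_search: %d pairs skipped by the same-trend (isST) gate", skipped)
    return call_dmrs(records, cfg), skipped


# ---------------------------------------------------------------------------
# TSV export / import

PAIR_TSV_COLUMNS = [
    "chrom",
    "start",
    "end",
    "region_class",
    "gene_name",
    "context",
    "positions",
    "case_levels",
    "control_levels",
    "imputed_case",
    "imputed_control",
]


def write_pairs(pairs: Iterable[PairedMR], path: str | Path) -> None:
    rows = [
        (
            p.chrom,
            p.start,
            p.end,
            p.region_class,
            p.gene_name or ".",
            p.context,
            ",".join(str(q) for q in p.positions),
            ",".join(repr(v) for v in p.case_levels),
            ",".join(repr(v) for v in p.control_levels),
            ",".join(str(int(b)) for b in p.imputed_case),
            ",".join(str(int(b)) for b in p.imputed_control),
        )
        for p in pairs
    ]
    pd.DataFrame(rows, columns=PAIR_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> list[PairedMR]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_name": str})
    pairs = []
    for row in df.itertuples(index=False):
        pairs.append(
            PairedMR(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                region_class=row.region_class,
                gene_name="" if row.gene_name == "." else str(row.gene_name),
                context=row.context,
                positions=tuple(int(q) for q in str(row.positions).split(",")),
                case_levels=tuple(float(v) for v in str(row.case_levels).split(",")),
                control_levels=tuple(float(v) for v in str(row.control_levels).split(",")),
                imputed_case=tuple(bool(int(b)) for b in str(row.imputed_case).split(",")),
                imputed_control=tuple(bool(int(b)) for b in str(row.imputed_control).split(",")),
            )
        )
    return pairs


DMR_TSV_COLUMNS = [
    "chrom",
    "start",
    "end",
    "region_class",
    "gene_name",
    "context",
    "n_sites",
    "p_value",
    "p_adjusted",
    "rratio",
    "direction",
    "test_name",
    "significant",
    "positions",
    "case_levels",
    "control_levels",
    "imputed_case",
    "imputed_control",
]


def write_dmrs(records: Iterable[DmrRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        p = r.pair
        rows.append(
            (
                p.chrom,
                p.start,
                p.end,
                p.region_class,
                p.gene_name or ".",
                p.context,
                p.n_sites,
                repr(r.p_value),
                "NA" if r.p_adjusted is None else repr(r.p_adjusted),
                repr(r.rratio),
                r.direction,
                r.test_name,
                int(r.significant),
                ",".join(str(q) for q in p.positions),
                ",".join(repr(v) for v in p.case_levels),
                ",".join(repr(v) for v in p.control_levels),
                ",".join(str(int(b)) for b in p.imputed_case),
                ",".join(str(int(b)) for b in p.imputed_control),
            )
        )
    pd.DataFrame(rows, columns=DMR_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_dmrs(path: str | Path) -> list[DmrRecord]:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "gene_name": str, "p_adjusted": str},
        keep_default_na=False,
    )
    records: list[DmrRecord] = []
    for row in df.itertuples(index=False):
        pair = PairedMR(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            region_class=row.region_class,
            gene_name="" if row.gene_name == "." else str(row.gene_name),
            context=row.context,
            positions=tuple(int(q) for q in str(row.positions).split(",")),
            case_levels=tuple(float(v) for v in str(row.case_levels).split(",")),
            control_levels=tuple(float(v) for v in str(row.control_levels).split(",")),
            imputed_case=tuple(bool(int(b)) for b in str(row.imputed_case).split(",")),
            imputed_control=tuple(bool(int(b)) for b in str(row.imputed_control).split(",")),
        )
        records.append(
            DmrRecord(
                pair=pair,
                p_value=float(row.p_value),
                test_name=row.test_name,
                rratio=float(row.rratio),
                direction=row.direction,
                p_adjusted=None if row.p_adjusted == "NA" else float(row.p_adjusted),
                significant=bool(int(row.significant)),
            )
        )
    return records
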