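"""Shared test helpers: site-table construction and brute-force oracles."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def make_sites(positions, levels, chrom="chr1", context="5mC", sample_id="s1", condition="case"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "level": np.asarray(levels, dtype=float),
            "context": context,
            "sample_id": sample_id,
            "condition": condition,
        }
    )


def listing_ranksum_p(x, y):
    """Exact two-sided rank-sum P-value by literally enumerating every
    assignment of the pooled mid-ranks to the x group."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(stats.rankdata(pooled) * 2).astype(int)
    nx, n = len(x), len(pooled)
    w_obs = int(ranks2[:nx].sum())
    le = ge = total = 0
    for comb in combinations(range(n), nx):
        w = sum(int(ranks2[i]) for i in comb)
        le += w <= w_obs
        ge += w >= w_obs
        total += 1
    p = 2 * Fraction(min(le, ge), total)
    return float(min(p, Fraction(1)))


def gap_graph_clusters(positions, max_gap):
    """Brute-force O(n^2) clustering oracle: connected components of the
    graph joining sites at distance <= max_gap."""
    positions = sorted(int(p) for p in positions)
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= max_gap:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(positions[i])
    return sorted(sorted(c) for c in comps.values())
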