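"""Brute-force oracles for interval arithmetic and multiple testing.

These deliberately use the slowest, most literal formulations (coverage
bitmaps, all-pairs scans, the step-up definition) so they stay independent
of the library implementations they check.
"""

from __future__ import annotations

import numpy as np

from zinchrom.intervals import GenomicInterval, RegionSet


def _coverage(intervals, chrom, size):
    cov = np.zeros(size, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            cov[iv.start : iv.end] = True
    return cov


def _runs(cov):
    """(start, end) runs of True in a boolean array."""
    padded = np.concatenate([[False], cov, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts, ends))


def merge_oracle(sets, size=10_000):
    chroms = sorted({iv.chrom for s in sets for iv in s})
    out = []
    for chrom in chroms:
        cov = _coverage([iv for s in sets for iv in s], chrom, size)
        out.extend(
            GenomicInterval(chrom, int(a), int(b)) for a, b in _runs(cov)
        )
    return {(iv.chrom, iv.start, iv.end) for iv in out}


def subtract_oracle(regions, blacklist):
    kept = []
    for iv in regions:
        hit = any(
            iv.chrom == b.chrom and iv.start < b.end and b.start < iv.end
            for b in blacklist
        )
        if not hit:
            kept.append(iv)
    return RegionSet(kept)


def intersect_fraction_oracle(a, b, min_frac, size=10_000):
    kept = []
    for iv in a:
        cov = _coverage(b, iv.chrom, size)
        overlap = int(cov[iv.start : iv.end].sum())
        if overlap >= min_frac * len(iv):
            kept.append(iv)
    return RegionSet(kept)


def bh_oracle(p):
    """Literal BH step-up: padj_(i) = min_{j>=i} min(1, m*p_(j)/j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, min(1.0, m * p[idx] / rank))
        adj[idx] = running
    return adj
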