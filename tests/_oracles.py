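"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (per-base boolean arrays, O(n^2)
scans, direct tail enumeration) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def baseset_union(intervals, chrom_len: int) -> np.ndarray:
    """Per-base boolean mask of the union of intervals on one chromosome."""
    mask = np.zeros(chrom_len, dtype=bool)
    for iv in intervals:
        mask[iv.start : iv.end] = True
    return mask


def mask_to_intervals(mask: np.ndarray):
    """(start, end) pairs of maximal True runs in a boolean mask."""
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def brute_window_mean(positions, values, window_bp):
    """O(n^2) neighbour scan: mean over |pos - pos_p| <= window_bp / 2."""
    half = window_bp / 2.0
    out = np.empty(len(positions))
    for i, p in enumerate(positions):
        sel = np.abs(np.asarray(positions) - p) <= half
        out[i] = np.mean(np.asarray(values)[sel])
    return out


def brute_running_mean(bits, window_points, mode="centered"):
    """Direct truncated windowed average."""
    bits = np.asarray(bits, dtype=float)
    n = bits.size
    out = np.empty(n)
    for i in range(n):
        if mode == "centered":
            half = window_points // 2
            lo, hi = max(0, i - half), min(n - 1, i + half)
        else:
            lo, hi = max(0, i - window_points + 1), i
        out[i] = bits[lo : hi + 1].mean()
    return out


def brute_count_overlap_reads(read_spans, start, end):
    """Count reads overlapping [start, end) by >= 1 bp, one scan per read."""
    return sum(1 for s, e in read_spans if s < end and e > start)


def brute_feature_in(feature, domains, mode):
    """Per-feature membership scan (midpoint or any_overlap)."""
    for dom in domains:
        if dom.chrom != feature.chrom:
            continue
        if mode == "midpoint":
            mid = (feature.start + feature.end) // 2
            if dom.start <= mid < dom.end:
                return True
        else:
            if feature.start < dom.end and dom.start < feature.end:
                return True
    return False


def fisher_two_sided_enum(a, b, c, d):
    """Two-sided Fisher p by full enumeration of the hypergeometric support.

    Sums P(X = k) over all k whose point probability does not exceed the
    observed one (with a small relative slack against float noise).
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = hypergeom(n, row1, col1)
    k_lo = max(0, col1 - (c + d))
    k_hi = min(row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(k_lo, k_hi + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def fisher_greater_enum(a, b, c, d):
    """One-sided (greater) Fisher p by direct upper-tail summation."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = hypergeom(n, row1, col1)
    k_hi = min(row1, col1)
    return min(sum(rv.pmf(k) for k in range(a, k_hi + 1)), 1.0)
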