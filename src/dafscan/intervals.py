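"""Low-level interval arithmetic on parallel (starts, ends) arrays.

All coordinates are 0-based half-open. Functions accept unsorted,
possibly overlapping input and return merged, sorted output unless
noted otherwise. These primitives back every region-set operation in
the package (class construction, SNP assignment, subtraction rules,
distance subsets), so they are kept dependency-free and exhaustively
tested against brute-force per-base oracles.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge_arrays",
    "subtract_arrays",
    "intersect_arrays",
    "total_length",
    "points_in",
    "gap_distance",
]


def _as_arrays(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(starts, dtype=np.int64)
    e = np.asarray(ends, dtype=np.int64)
    if s.shape != e.shape:
        raise ValueError("starts and ends must have equal length")
    if np.any(e <= s):
        raise ValueError("every interval must satisfy end > start")
    return s, e


def merge_arrays(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or book-ended intervals into a minimal sorted set."""
    s, e = _as_arrays(starts, ends)
    if s.size == 0:
        return s, e
    order = np.lexsort((e, s))
    s, e = s[order], e[order]
    # running maximum of ends; a new block starts where s exceeds the
    # max end seen so far (book-ended intervals [a,b),[b,c) merge too)
    cummax = np.maximum.accumulate(e)
    new_block = np.empty(s.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] > cummax[:-1]
    idx = np.flatnonzero(new_block)
    out_s = s[idx]
    out_e = np.empty(idx.size, dtype=np.int64)
    out_e[:-1] = cummax[idx[1:] - 1]
    out_e[-1] = cummax[-1]
    return out_s, out_e


def total_length(starts, ends) -> int:
    """Summed length of the merged union of the given intervals."""
    s, e = merge_arrays(starts, ends)
    return int(np.sum(e - s))


def subtract_arrays(a_starts, a_ends, b_starts, b_ends):
    """Bases of A not covered by B, as merged sorted intervals."""
    a_s, a_e = merge_arrays(a_starts, a_ends)
    if len(b_starts) == 0:
        return a_s, a_e
    b_s, b_e = merge_arrays(b_starts, b_ends)
    out_s: list[int] = []
    out_e: list[int] = []
    # for each A block, walk the B blocks that can overlap it
    j0 = np.searchsorted(b_e, a_s, side="right")
    for i in range(a_s.size):
        cur = int(a_s[i])
        end = int(a_e[i])
        j = int(j0[i])
        while j < b_s.size and b_s[j] < end:
            if b_s[j] > cur:
                out_s.append(cur)
                out_e.append(int(b_s[j]))
            cur = max(cur, int(b_e[j]))
            j += 1
        if cur < end:
            out_s.append(cur)
            out_e.append(end)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def intersect_arrays(a_starts, a_ends, b_starts, b_ends):
    """Bases covered by both A and B, as merged sorted intervals."""
    if len(a_starts) == 0 or len(b_starts) == 0:
        empty = np.asarray([], dtype=np.int64)
        return empty, empty.copy()
    a_s, a_e = merge_arrays(a_starts, a_ends)
    b_s, b_e = merge_arrays(b_starts, b_ends)
    out_s: list[int] = []
    out_e: list[int] = []
    j0 = np.searchsorted(b_e, a_s, side="right")
    for i in range(a_s.size):
        j = int(j0[i])
        while j < b_s.size and b_s[j] < a_e[i]:
            lo = max(int(a_s[i]), int(b_s[j]))
            hi = min(int(a_e[i]), int(b_e[j]))
            if hi > lo:
                out_s.append(lo)
                out_e.append(hi)
            j += 1
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def points_in(starts, ends, positions) -> np.ndarray:
    """Boolean membership of each position in the union of the intervals.

    ``starts``/``ends`` need not be pre-merged. A position p is a member
    iff the 1-bp interval [p, p+1) intersects some interval, i.e.
    start <= p < end under half-open semantics.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if len(starts) == 0:
        return np.zeros(pos.shape, dtype=bool)
    s, e = merge_arrays(starts, ends)
    idx = np.searchsorted(s, pos, side="right") - 1
    ok = idx >= 0
    res = np.zeros(pos.shape, dtype=bool)
    res[ok] = pos[ok] < e[idx[ok]]
    return res


def gap_distance(q_start: int, q_end: int, starts, ends) -> int:
    """Minimum edge-to-edge gap between [q_start, q_end) and any interval.

    Returns 0 when the query intersects an interval. Raises ValueError on
    an empty interval set (callers decide the no-neighbour sentinel).
    """
    s = np.asarray(starts, dtype=np.int64)
    e = np.asarray(ends, dtype=np.int64)
    if s.size == 0:
        raise ValueError("gap_distance requires at least one interval")
    left = s - q_end   # interval lies right of query
    right = q_start - e  # interval lies left of query
    gaps = np.maximum(np.maximum(left, right), 0)
    return int(gaps.min())
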