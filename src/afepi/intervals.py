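"""Small genomic-interval engine on sorted numpy arrays.

All coordinates are 0-based half-open.  Functions here operate on per-chromosome
``(starts, ends)`` arrays; :class:`afepi.tracks.RegionSet` dispatches per
chromosome.  Kept deliberately minimal — merging, subtraction and overlap
lengths are the only primitives the pipeline needs, and each is checked against
a brute-force per-base oracle in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge_intervals",
    "cluster_overlapping",
    "overlap_length",
    "subtract_intervals",
    "nearest_point_distance",
]


def _as_sorted(starts, ends):
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size and np.any(ends <= starts):
        raise ValueError("intervals must satisfy start < end")
    order = np.argsort(starts, kind="stable")
    return starts[order], ends[order], order


def merge_intervals(starts, ends, gap: int = 0):
    """Merge intervals whose gap is <= ``gap`` bp.

    ``gap=0`` merges overlapping *and* book-ended intervals.  Returns sorted
    ``(starts, ends)`` arrays.
    """
    starts, ends, _ = _as_sorted(starts, ends)
    if starts.size == 0:
        return starts, ends
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - out_e[-1] <= gap:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def cluster_overlapping(starts, ends):
    """Cluster intervals by transitive >=1 bp overlap.

    Book-ended intervals (end == next start) share no base and are *not*
    clustered.  Returns ``(cluster_starts, cluster_ends, labels)`` where
    ``labels[i]`` maps input interval ``i`` (original order) to its cluster.
    """
    starts_s, ends_s, order = _as_sorted(starts, ends)
    n = starts_s.size
    labels_sorted = np.zeros(n, dtype=np.int64)
    if n == 0:
        return starts_s, ends_s, labels_sorted
    c_s, c_e = [starts_s[0]], [ends_s[0]]
    for i in range(1, n):
        if starts_s[i] < c_e[-1]:  # strict: needs a shared base
            c_e[-1] = max(c_e[-1], ends_s[i])
            labels_sorted[i] = len(c_s) - 1
        else:
            c_s.append(starts_s[i])
            c_e.append(ends_s[i])
            labels_sorted[i] = len(c_s) - 1
    labels = np.empty(n, dtype=np.int64)
    labels[order] = labels_sorted
    return np.array(c_s, dtype=np.int64), np.array(c_e, dtype=np.int64), labels


def overlap_length(start: int, end: int, starts, ends) -> int:
    """Total bp of ``[start, end)`` covered by a *merged, sorted* interval set."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return 0
    lo = int(np.searchsorted(ends, start, side="right"))
    hi = int(np.searchsorted(starts, end, side="left"))
    total = 0
    for i in range(lo, hi):
        total += max(0, min(end, ends[i]) - max(start, starts[i]))
    return total


def subtract_intervals(starts, ends, sub_starts, sub_ends):
    """Set-difference: parts of the first interval set not covered by the second.

    The subtrahend must be merged and sorted.  Fragments inherit no metadata;
    callers re-attach scores as needed.  Returns ``(starts, ends, src_index)``
    with ``src_index`` pointing at the originating interval.
    """
    sub_starts = np.asarray(sub_starts, dtype=np.int64)
    sub_ends = np.asarray(sub_ends, dtype=np.int64)
    out_s, out_e, out_i = [], [], []
    for idx, (s, e) in enumerate(zip(starts, ends)):
        cur = int(s)
        lo = int(np.searchsorted(sub_ends, s, side="right"))
        hi = int(np.searchsorted(sub_starts, e, side="left"))
        for j in range(lo, hi):
            if sub_starts[j] > cur:
                out_s.append(cur)
                out_e.append(min(int(sub_starts[j]), int(e)))
                out_i.append(idx)
            cur = max(cur, int(sub_ends[j]))
        if cur < e:
            out_s.append(cur)
            out_e.append(int(e))
            out_i.append(idx)
    return (
        np.array(out_s, dtype=np.int64),
        np.array(out_e, dtype=np.int64),
        np.array(out_i, dtype=np.int64),
    )


def nearest_point_distance(start: int, end: int, points) -> int:
    """Distance from interval ``[start, end)`` to the nearest point (0 if inside)."""
    points = np.sort(np.asarray(points, dtype=np.int64))
    if points.size == 0:
        raise ValueError("no points supplied")
    inside = (points >= start) & (points < end)
    if inside.any():
        return 0
    d_left = start - points[points < start]
    d_right = points[points >= end] - end
    best = np.inf
    if d_left.size:
        best = min(best, int(d_left.min()))
    if d_right.size:
        best = min(best, int(d_right.min()))
    return int(best)
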