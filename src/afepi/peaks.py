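"""Simplified peak calling on binned coverage.

Per-sample peaks are called from a one-sided Poisson upper-tail test of the
ChIP bin count against a local/global input-derived background rate — the
binned analogue of a standard peak caller.  Group reference peaks combine the
per-replicate bin p-values with Fisher's method.  A greylist collects regions
reproducibly enriched in the input libraries alone, which downstream stages
subtract as artifacts.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import CoverageTrack, RegionSet

__all__ = [
    "normalize_depth",
    "poisson_upper_tail",
    "call_sample_peaks",
    "call_group_reference_peaks",
    "compute_greylist",
    "subtract_greylist",
    "annotate_tss_distance",
]

P_FLOOR = 1e-300  # keep -log10 finite


def normalize_depth(track: CoverageTrack, target_depth: float = 20_000_000) -> CoverageTrack:
    """Scale bin counts to a common library depth.

    Counts are multiplied by ``target_depth / total_reads``.  Low-depth
    libraries (total below target) are returned unscaled with
    ``meta['depth_scaled'] = False``, mirroring the convention of keeping all
    available reads rather than upscaling.
    """
    if track.total_reads <= 0:
        raise ValueError("cannot depth-normalise a zero-depth track")
    out = track.copy()
    if track.total_reads < target_depth:
        out.meta["depth_scaled"] = False
        return out
    factor = target_depth / track.total_reads
    out.counts = {c: v * factor for c, v in out.counts.items()}
    out.total_reads = target_depth
    out.meta["depth_scaled"] = True
    return out


def poisson_upper_tail(count, lam):
    """P(X >= count) for X ~ Poisson(lam); vectorised, one-sided upper tail."""
    count = np.asarray(count, dtype=float)
    lam = np.maximum(np.asarray(lam, dtype=float), 1e-12)
    # sf(k-1) = P(X >= k); counts may be fractional after depth scaling, so
    # test at ceil(count) which is conservative for the discrete null.
    k = np.ceil(count)
    return np.clip(stats.poisson.sf(k - 1, lam), P_FLOOR, 1.0)


def _local_lambda(input_counts: np.ndarray, bin_size: int, window_bp: int = 5000,
                  global_mean: Optional[float] = None) -> np.ndarray:
    """MACS-style background rate: max(bin, local mean over +-window, global mean)."""
    half = max(1, window_bp // bin_size)
    kernel = np.ones(2 * half + 1)
    local = np.convolve(input_counts, kernel, mode="same") / np.convolve(
        np.ones_like(input_counts), kernel, mode="same")
    g = float(np.mean(input_counts)) if global_mean is None else global_mean
    return np.maximum.reduce([input_counts, local, np.full_like(input_counts, g)])


def _bins_to_regions(chrom: str, sig: np.ndarray, neglog10p: np.ndarray,
                     bin_size: int, min_len: int, max_gap: int) -> List[tuple]:
    """Merge significant bins across gaps <= max_gap bp, drop short regions."""
    idx = np.flatnonzero(sig)
    if idx.size == 0:
        return []
    regions = []
    run = [idx[0]]
    for i in idx[1:]:
        gap_bp = (i - run[-1] - 1) * bin_size
        if gap_bp <= max_gap:
            run.append(i)
        else:
            regions.append(run)
            run = [i]
    regions.append(run)
    rows = []
    for run in regions:
        start, end = run[0] * bin_size, (run[-1] + 1) * bin_size
        if end - start >= min_len:
            rows.append((chrom, start, end, float(neglog10p[run].max())))
    return rows


def _bin_pvalues(chip: CoverageTrack, input_: CoverageTrack) -> Dict[str, np.ndarray]:
    if not chip.same_binning(input_):
        raise ValueError("ChIP and input tracks have mismatched binning")
    all_bins = np.concatenate([input_.counts[c] for c in input_.counts])
    global_mean = float(all_bins.mean())
    pvals = {}
    for chrom in chip.counts:
        lam = _local_lambda(input_.counts[chrom], input_.bin_size, global_mean=global_mean)
        pvals[chrom] = poisson_upper_tail(chip.counts[chrom], lam)
    return pvals


def call_sample_peaks(chip: CoverageTrack, input_: CoverageTrack,
                      p_thresh: float = 1e-5, min_len: int = 300,
                      max_gap: int = 100) -> RegionSet:
    """Per-sample peaks: Poisson upper-tail per bin, merge, length filter.

    No multiplicity correction is applied, matching conventional peak-caller
    behaviour at a fixed per-bin p threshold.  Region score is
    -log10(min bin p).
    """
    pvals = _bin_pvalues(chip, input_)
    rows = []
    for chrom, p in pvals.items():
        rows.extend(_bins_to_regions(chrom, p < p_thresh, -np.log10(p),
                                     chip.bin_size, min_len, max_gap))
    return RegionSet.from_intervals(rows)


def call_group_reference_peaks(chips: Sequence[CoverageTrack],
                               inputs: Sequence[CoverageTrack],
                               p_thresh: float = 1e-5, min_len: int = 300,
                               max_gap: int = 100) -> RegionSet:
    """Reference peaks for one sample group.

    Per-bin p-values are computed per replicate (each ChIP against its own
    input) and combined with Fisher's method (chi-square with 2r df); the
    combined p is thresholded and merged exactly as in per-sample calling.
    With one replicate this reduces to :func:`call_sample_peaks`.
    """
    if len(chips) != len(inputs) or not chips:
        raise ValueError("need matched, non-empty ChIP and input lists")
    per_rep = [_bin_pvalues(c, i) for c, i in zip(chips, inputs)]
    r = len(per_rep)
    rows = []
    for chrom in chips[0].counts:
        stat = np.zeros_like(per_rep[0][chrom])
        for rep in per_rep:
            stat += -2.0 * np.log(rep[chrom])
        combined = np.clip(stats.chi2.sf(stat, df=2 * r), P_FLOOR, 1.0)
        rows.extend(_bins_to_regions(chrom, combined < p_thresh, -np.log10(combined),
                                     chips[0].bin_size, min_len, max_gap))
    return RegionSet.from_intervals(rows)


def compute_greylist(inputs: Sequence[CoverageTrack], min_fraction: float = 0.5,
                     p_thresh: float = 1e-5, min_len: int = 300,
                     max_gap: int = 100) -> RegionSet:
    """Regions reproducibly enriched in input libraries alone.

    Each input is tested against its own genome-wide flat rate; bins called in
    at least ``min_fraction`` of the inputs are merged into the greylist.
    """
    if not inputs:
        raise ValueError("no input tracks supplied")
    votes = {c: np.zeros_like(v) for c, v in inputs[0].counts.items()}
    for track in inputs:
        flat = CoverageTrack(
            {c: np.full_like(v, float(np.concatenate(list(track.counts.values())).mean()))
             for c, v in track.counts.items()},
            track.bin_size)
        for chrom, p in _bin_pvalues(track, flat).items():
            votes[chrom] += (p < p_thresh).astype(float)
    need = int(np.ceil(min_fraction * len(inputs)))
    rows = []
    for chrom, v in votes.items():
        rows.extend(_bins_to_regions(chrom, v >= need, v, inputs[0].bin_size,
                                     min_len, max_gap))
    return RegionSet.from_intervals(rows)


def subtract_greylist(regions: RegionSet, greylist: RegionSet,
                      min_len: int = 1) -> RegionSet:
    """Remove greylisted bases from a region set (fragments below min_len drop)."""
    return regions.subtract(greylist, min_len=min_len)


def annotate_tss_distance(regions: RegionSet, genes: pd.DataFrame,
                          signed: bool = False) -> pd.DataFrame:
    """Distance from each region to the nearest annotated TSS.

    Distance is 0 when a TSS lies inside the region.  Unsigned by default;
    with ``signed=True`` TSSs at larger coordinates than the region get
    positive sign (strand-independent genomic direction).
    """
    rows = []
    by_chrom = {c: np.sort(g["tss"].values) for c, g in genes.groupby("chrom")}
    for row in regions.df.itertuples(index=False):
        tss = by_chrom.get(row.chrom)
        if tss is None or tss.size == 0:
            rows.append((row.chrom, row.start, row.end, np.nan))
            continue
        inside = (tss >= row.start) & (tss < row.end)
        if inside.any():
            d = 0
        else:
            left = tss[tss < row.start]
            right = tss[tss >= row.end]
            d_left = int(row.start - left.max()) if left.size else None
            d_right = int(right.min() - row.end) if right.size else None
            if d_right is None or (d_left is not None and d_left <= d_right):
                d = -d_left if signed else d_left
            else:
                d = d_right
        rows.append((row.chrom, row.start, row.end, d))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tss_distance"])
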