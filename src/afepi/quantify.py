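"""Region-level coverage quantification and normalisation.

FPKM per region (with bp-apportioned partial bins), input-ratio
normalisation, quantile normalisation and the sample-similarity summaries
(Pearson correlation matrix, principal components) used to inspect the
cohort.  The conventional order is FPKM -> input ratio -> quantile
normalisation -> log2.
"""

from __future__ import annotations

from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .tracks import CoverageTrack, RegionSet

__all__ = [
    "region_fpkm",
    "region_matrix",
    "input_normalize",
    "quantile_normalize",
    "sample_correlations",
    "principal_components",
]


def region_fpkm(track: CoverageTrack, regions: RegionSet) -> np.ndarray:
    """FPKM per region: reads_in_region / (region_kb * total_reads_millions).

    Bin counts are apportioned by the bp fraction of the bin covered by the
    region, so partially overlapped edge bins contribute proportionally.
    """
    if track.total_reads <= 0:
        raise ValueError("zero-depth track")
    bs = track.bin_size
    out = np.zeros(len(regions))
    for i, row in enumerate(regions.df.itertuples(index=False)):
        counts = track.counts[row.chrom]
        b0, b1 = row.start // bs, (row.end - 1) // bs
        reads = 0.0
        for b in range(b0, b1 + 1):
            ov = min(row.end, (b + 1) * bs) - max(row.start, b * bs)
            reads += counts[b] * ov / bs
        kb = (row.end - row.start) / 1000.0
        out[i] = reads / (kb * track.total_reads / 1e6)
    return out


def region_matrix(tracks: Mapping[str, CoverageTrack], regions: RegionSet) -> pd.DataFrame:
    """Regions x samples FPKM matrix; rows keyed ``chrom:start-end``."""
    index = [f"{r.chrom}:{r.start}-{r.end}" for r in regions.df.itertuples(index=False)]
    return pd.DataFrame({name: region_fpkm(t, regions) for name, t in tracks.items()},
                        index=pd.Index(index, name="region"))


def input_normalize(chip: pd.DataFrame, input_: pd.DataFrame,
                    pseudocount: float = 0.1) -> pd.DataFrame:
    """ChIP coverage normalised by input: (chip + ps) / (input + ps)."""
    if not chip.index.equals(input_.index) or list(chip.columns) != list(input_.columns):
        raise ValueError("chip and input matrices must be aligned")
    return (chip + pseudocount) / (input_ + pseudocount)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalisation across columns.

    Each column's sorted values are replaced by the cross-column mean of
    sorted values; tied values within a column receive the mean of the
    reference values over their span (so the map is well defined and the
    operation idempotent and rank-preserving).
    """
    x = matrix.to_numpy(dtype=float)
    n, m = x.shape
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(m):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col[order[k + 1]] == col[order[i]]:
                k += 1
            assigned[order[i:k + 1]] = ref[i:k + 1].mean()
            i = k + 1
        out[:, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def upward_shift_pvalues(matrix: pd.DataFrame,
                         region_ids_by_group: Mapping[str, list],
                         samples_by_group: Mapping[str, list]) -> pd.Series:
    """One-sided Wilcoxon rank-sum test of the expected coverage shift.

    For each group, coverage values over that group's enriched regions in
    group samples are tested against the same regions in all other samples
    (alternative: greater), with Bonferroni correction across groups.
    """
    from scipy import stats as _st

    out = {}
    groups = list(region_ids_by_group)
    for group in groups:
        ids = [i for i in region_ids_by_group[group] if i in matrix.index]
        own = samples_by_group[group]
        others = [s for g, ss in samples_by_group.items() if g != group for s in ss]
        if not ids or not own or not others:
            out[group] = np.nan
            continue
        x = matrix.loc[ids, own].to_numpy().ravel()
        y = matrix.loc[ids, others].to_numpy().ravel()
        p = _st.mannwhitneyu(x, y, alternative="greater").pvalue
        out[group] = min(1.0, float(p) * len(groups))
    return pd.Series(out, name="bonferroni_p")


def sample_correlations(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between sample columns."""
    return matrix.corr(method="pearson")


def principal_components(matrix: pd.DataFrame, k: int = 2) -> Dict[str, object]:
    """Principal components of the samples (columns) of a regions x samples matrix.

    Variables (regions) are centred; components are ordered by decreasing
    variance and each is sign-fixed so its largest-magnitude loading is
    positive.  Returns scores (samples x k), explained variance per component
    and the total variance, which is conserved across all components.
    """
    x = matrix.to_numpy(dtype=float).T  # samples x regions
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    n = x.shape[0]
    var = s ** 2 / max(n - 1, 1)
    k = min(k, len(s))
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] *= -1
            scores[:, j] *= -1
    return {
        "scores": pd.DataFrame(scores, index=matrix.columns,
                               columns=[f"PC{i + 1}" for i in range(k)]),
        "explained_variance": var[:k],
        "total_variance": float(var.sum()),
    }
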