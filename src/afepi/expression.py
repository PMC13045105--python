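"""Simplified negative-binomial differential expression.

Median-of-ratios size factors, gene-wise method-of-moments dispersion shrunk
toward a mean-dispersion trend, a per-gene NB GLM with log link and
size-factor offsets, a Wald test on the contrast coefficient and
Benjamini-Hochberg correction.  This is deliberately a small, testable
stand-in for a full DE package: no outlier refitting, no independent
filtering, no shrunken fold changes — the downstream integration stage only
needs calibrated p-values and accurate log2 fold changes at toy scale.

P-values use a t reference distribution with the model's residual degrees of
freedom, the small-sample choice appropriate for the 5-per-group study
conditions this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .tracks import StudyDesign

__all__ = ["filter_genes", "size_factors", "nb_wald_de", "bh_adjust", "CONTRASTS"]

# contrast name -> (design column, numerator level, denominator level)
CONTRASTS = {
    "side": ("side", "LA", "RA"),
    "disease": ("disease", "AF", "SR"),
    "AF-LA_vs_SR-LA": ("group", "AF-LA", "SR-LA"),
    "AF-RA_vs_SR-RA": ("group", "AF-RA", "SR-RA"),
    "AF-LA_vs_AF-RA": ("group", "AF-LA", "AF-RA"),
    "SR-LA_vs_SR-RA": ("group", "SR-LA", "SR-RA"),
}


def filter_genes(counts: pd.DataFrame, annotation: pd.DataFrame,
                 min_total: int = 5, biotype: str = "protein_coding") -> pd.DataFrame:
    """Keep protein-coding genes with at least ``min_total`` reads across samples."""
    ann = annotation.set_index("gene")
    keep = []
    for g in counts.index:
        if g in ann.index and ann.loc[g, "biotype"] == biotype \
                and counts.loc[g].sum() >= min_total:
            keep.append(g)
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For each sample, the factor is the median over genes of
    count / geometric-mean; genes with any zero count are excluded from the
    median so all-zero genes cannot move the estimate.
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with all-positive counts")
    logx = np.log(x[positive])
    log_geomean = logx.mean(axis=1)
    factors = np.exp(np.median(logx - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs pass through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    m = pm.size
    if m == 0:
        return out
    order = np.argsort(pm)
    ranked = pm[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[mask] = adj
    return out


def _dispersions(norm_counts: np.ndarray, groups: np.ndarray,
                 shrink_weight: float) -> np.ndarray:
    """Gene-wise MoM dispersion from within-group residuals, shrunk (in log
    space) toward a fitted a0 + a1/mean trend."""
    means = np.zeros_like(norm_counts)
    for g in np.unique(groups):
        cols = groups == g
        means[:, cols] = norm_counts[:, cols].mean(axis=1, keepdims=True)
    n, k = norm_counts.shape[1], len(np.unique(groups))
    resid_var = ((norm_counts - means) ** 2).sum(axis=1) / max(n - k, 1)
    mu = norm_counts.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        genewise = np.clip((resid_var - mu) / mu ** 2, 1e-8, 10.0)
    ok = mu > 0
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, genewise[ok], rcond=None)
    trend = np.clip(coef[0] + coef[1] / np.maximum(mu, 1e-8), 1e-8, 10.0)
    w = shrink_weight
    return np.exp(w * np.log(trend) + (1 - w) * np.log(genewise))


def nb_wald_de(counts: pd.DataFrame, design: StudyDesign, contrast: str,
               shrink_weight: float = 0.5, sf: Optional[pd.Series] = None) -> pd.DataFrame:
    """Per-gene NB GLM Wald test for one contrast.

    Returns a DataFrame with base mean, log2 fold change, its standard error,
    the Wald p-value and the BH-adjusted p-value.  All-zero genes are excluded
    from testing (their p-values are NaN).
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; one of {sorted(CONTRASTS)}")
    column, lev1, lev0 = CONTRASTS[contrast]
    table = design.table.copy()
    table["group"] = table["disease"] + "-" + table["side"]
    keep = table[table[column].isin([lev0, lev1])]
    for lev in (lev0, lev1):
        if (keep[column] == lev).sum() < 2:
            raise ValueError(f"contrast level {lev!r} has fewer than 2 samples")
    samples = list(keep["sample"])
    sub = counts[samples]
    sf = size_factors(sub) if sf is None else sf[samples]
    indicator = (keep[column] == lev1).to_numpy(dtype=float)

    y = sub.to_numpy(dtype=float)
    norm = y / sf.to_numpy()[None, :]
    disp = _dispersions(norm, indicator, shrink_weight)
    offset = np.log(sf.to_numpy())
    X = np.column_stack([np.ones(len(samples)), indicator])
    df_resid = len(samples) - X.shape[1]

    rows = []
    for i, gene in enumerate(sub.index):
        if y[i].sum() == 0:
            rows.append((gene, 0.0, np.nan, np.nan, np.nan))
            continue
        try:
            fam = sm.families.NegativeBinomial(alpha=float(disp[i]))
            fit = sm.GLM(y[i], X, family=fam, offset=offset).fit(maxiter=100)
            beta, se = fit.params[1], fit.bse[1]
            wald = beta / se if se > 0 else 0.0
            p = 2.0 * stats.t.sf(abs(wald), df=df_resid)
        except Exception:
            beta, se, p = np.nan, np.nan, np.nan
        rows.append((gene, float(norm[i].mean()), beta / np.log(2) if np.isfinite(beta) else np.nan,
                     se / np.log(2) if np.isfinite(se) else np.nan, p))
    out = pd.DataFrame(rows, columns=["gene", "base_mean", "log2fc", "se", "pvalue"])
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    out["contrast"] = contrast
    return out.set_index("gene")
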