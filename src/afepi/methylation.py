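"""Per-CpG EWAS and differentially methylated region (DMR) calling.

The EWAS is an ordinary least-squares regression of each CpG's beta-values on
a disease indicator plus optional covariates and surrogate variables
(instantiated as top principal components of the design-residualised beta
matrix).  Candidate DMR windows are maximal runs of >= 2 consecutive CpGs at
most 500 bp apart with same-sign effect estimates; each window's per-CpG
statistics are aggregated by inverse-variance weighting under the residual
correlation of its member CpGs, with Bonferroni control over candidate
windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MethylationData
from .tracks import RegionSet

__all__ = [
    "EwasResult",
    "ewas",
    "find_candidate_windows",
    "dmr_statistics",
    "classify_dmrs",
    "link_dmrs_to_loci",
]


@dataclass
class EwasResult:
    """Per-CpG association statistics plus the residual matrix for DMR use."""

    stats: pd.DataFrame       # cpg, chrom, pos, estimate, se, t, pvalue
    residuals: pd.DataFrame   # CpGs x samples, residuals of the fitted model
    model_columns: List[str]


def _design_matrix(meth: MethylationData, covariates: Optional[pd.DataFrame],
                   n_svs: int) -> Tuple[np.ndarray, List[str]]:
    samples = list(meth.betas.columns)
    disease = meth.design.set_index("sample").loc[samples, "disease"]
    cols = [np.ones(len(samples)), (disease == "AF").to_numpy(dtype=float)]
    names = ["intercept", "disease_AF"]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates.loc[samples, c].to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for j in range(2, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise ValueError(f"collinear covariate: {names[j]}")
        raise ValueError("collinear design matrix")
    if n_svs > 0:
        # surrogate variables: top PCs of betas after regressing out the design
        Y = meth.betas.to_numpy(dtype=float).T  # samples x CpGs
        H = X @ np.linalg.pinv(X)
        R = Y - H @ Y
        u, s, _ = np.linalg.svd(R - R.mean(axis=0, keepdims=True), full_matrices=False)
        k = min(n_svs, len(s))
        X = np.column_stack([X, u[:, :k] * s[:k]])
        names += [f"SV{i + 1}" for i in range(k)]
    return X, names


def ewas(meth: MethylationData, covariates: Optional[pd.DataFrame] = None,
         n_svs: int = 2) -> EwasResult:
    """OLS of beta on disease status (AF minus SR) per CpG, vectorised.

    Two-sided t p-values with the model's residual degrees of freedom.
    Constant CpGs are reported with estimate 0 and p 1 (untestable).
    """
    counts = meth.design["disease"].value_counts()
    if counts.get("AF", 0) < 2 or counts.get("SR", 0) < 2:
        raise ValueError("need >= 2 samples per disease status")
    X, names = _design_matrix(meth, covariates, n_svs)
    Y = meth.betas.to_numpy(dtype=float)  # CpGs x samples
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ xtx_inv.T                       # CpGs x k
    resid = Y - B @ X.T
    df = n - k
    sigma2 = (resid ** 2).sum(axis=1) / max(df, 1)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    b = B[:, 1]
    constant = Y.std(axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=max(df, 1))
    b = np.where(constant, 0.0, b)
    p = np.where(constant | (se == 0), 1.0, p)
    out = meth.cpg_map.copy().reset_index(drop=True)
    out["estimate"] = b
    out["se"] = np.where(se > 0, se, np.nan)
    out["t"] = t
    out["pvalue"] = p
    return EwasResult(
        stats=out,
        residuals=pd.DataFrame(resid, index=meth.betas.index, columns=meth.betas.columns),
        model_columns=names,
    )


def find_candidate_windows(ewas_result: EwasResult, max_gap: int = 500) -> List[List[int]]:
    """Maximal runs of >= 2 consecutive CpGs with adjacent gaps <= ``max_gap``
    and same-sign effect estimates.  A sign flip (or zero) or a larger gap
    breaks the run.  Returns lists of row indices into ``ewas_result.stats``."""
    df = ewas_result.stats.sort_values(["chrom", "pos"], kind="stable")
    windows: List[List[int]] = []
    run: List[int] = []

    def flush():
        if len(run) >= 2:
            windows.append(list(run))

    prev_chrom, prev_pos, prev_sign = None, None, 0
    for idx, row in df.iterrows():
        sign = int(np.sign(row["estimate"]))
        if (row["chrom"] != prev_chrom or sign == 0 or sign != prev_sign
                or row["pos"] - prev_pos > max_gap):
            flush()
            run = [idx] if sign != 0 else []
        else:
            run.append(idx)
        prev_chrom, prev_pos, prev_sign = row["chrom"], row["pos"], sign
    flush()
    return windows


def dmr_statistics(windows: Sequence[Sequence[int]], ewas_result: EwasResult,
                   alpha: float = 0.05, cond_max: float = 1e8,
                   ridge: float = 1e-6) -> pd.DataFrame:
    """Inverse-variance aggregation of per-CpG statistics per candidate window.

    With member estimates ``b``, standard errors ``s`` and residual
    correlation ``R``, the covariance is ``Sigma_ij = s_i s_j R_ij`` and the
    aggregate effect ``B = (1' Sigma^-1 b) / (1' Sigma^-1 1)`` with
    ``SE = (1' Sigma^-1 1)^(-1/2)``; ``z = B/SE`` is referred to the standard
    normal, and Bonferroni correction is applied over candidate windows.
    Near-singular ``Sigma`` is ridge-regularised on its diagonal.
    """
    import warnings

    rows = []
    stats_df = ewas_result.stats
    resid = ewas_result.residuals
    for w in windows:
        sub = stats_df.loc[list(w)]
        b = sub["estimate"].to_numpy()
        s = sub["se"].to_numpy()
        if np.any(~np.isfinite(s)):
            continue
        r = resid.loc[sub["cpg"]].to_numpy()
        R = np.corrcoef(r)
        R = np.nan_to_num(R, nan=0.0)
        np.fill_diagonal(R, 1.0)
        sigma = np.outer(s, s) * R
        if np.linalg.cond(sigma) > cond_max:
            warnings.warn("near-singular DMR covariance; ridge applied",
                          RuntimeWarning, stacklevel=2)
            sigma = sigma + ridge * np.diag(np.diag(sigma))
        ones = np.ones(len(b))
        sigma_inv = np.linalg.inv(sigma)
        denom = ones @ sigma_inv @ ones
        B = (ones @ sigma_inv @ b) / denom
        se_b = denom ** -0.5
        z = B / se_b
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({
            "chrom": sub["chrom"].iloc[0],
            "start": int(sub["pos"].min()),
            "end": int(sub["pos"].max()) + 2,
            "n_cpgs": len(w),
            "cpgs": list(sub["cpg"]),
            "effect": B,
            "se": se_b,
            "z": z,
            "pvalue": p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = np.minimum(out["pvalue"] * len(out), 1.0)
        out["significant"] = out["padj"] < alpha
        out["direction"] = np.where(out["effect"] > 0, "hyper", "hypo")
    else:
        out = pd.DataFrame(columns=["chrom", "start", "end", "n_cpgs", "cpgs", "effect",
                                    "se", "z", "pvalue", "padj", "significant", "direction"])
    return out


def classify_dmrs(dmrs: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Partition significant DMRs into hyper- (AF > SR) and hypomethylated."""
    sig = dmrs[dmrs["significant"]] if "significant" in dmrs else dmrs
    return {
        "hyper": sig[sig["effect"] > 0].reset_index(drop=True),
        "hypo": sig[sig["effect"] < 0].reset_index(drop=True),
    }


def link_dmrs_to_loci(dmrs: pd.DataFrame, candidate_loci: pd.DataFrame,
                      domains: pd.DataFrame,
                      regions_by_group: Mapping[str, RegionSet]) -> pd.DataFrame:
    """Link DMRs to candidate loci at the locus level.

    A DMR is linked to a candidate locus when it overlaps the gene's
    regulatory domain or one of the locus's associated enriched regions;
    direct >= 1 bp DMR-region overlaps are reported separately (they are
    expected to be limited for array-based DMRs).
    """
    dom = domains.set_index("gene")
    all_regions = []
    for group, rs in regions_by_group.items():
        for row in rs.df.itertuples(index=False):
            all_regions.append((row.chrom, row.start, row.end, group))
    rows = []
    for di, dmr in dmrs.iterrows():
        direct = [f"{c}:{s}-{e}" for c, s, e, _ in all_regions
                  if c == dmr["chrom"] and s < dmr["end"] and e > dmr["start"]]
        for row in candidate_loci.itertuples(index=False):
            if row.gene not in dom.index:
                continue
            d = dom.loc[row.gene]
            in_domain = (d["chrom"] == dmr["chrom"] and d["start"] < dmr["end"]
                         and d["end"] > dmr["start"])
            region_hit = False
            for key in str(row.regions).split(";"):
                if ":" not in key:
                    continue
                chrom, span = key.split(":")
                s, e = (int(x) for x in span.split("-"))
                if chrom == dmr["chrom"] and s < dmr["end"] and e > dmr["start"]:
                    region_hit = True
            if in_domain or region_hit:
                rows.append({
                    "dmr_index": di,
                    "dmr": f"{dmr['chrom']}:{dmr['start']}-{dmr['end']}",
                    "direction": dmr.get("direction", ""),
                    "gene": row.gene,
                    "via_domain": bool(in_domain),
                    "via_region": bool(region_hit),
                    "direct_region_overlaps": ";".join(direct),
                })
    return pd.DataFrame(rows, columns=["dmr_index", "dmr", "direction", "gene",
                                       "via_domain", "via_region",
                                       "direct_region_overlaps"])
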