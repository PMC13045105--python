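"""qPCR validation arithmetic for the replication cohort.

Relative expression by the delta-Ct method against a reference gene,
double-normalised ChIP-qPCR enrichment
(2^-[(Ct_target - Ct_ref)_ChIP - (Ct_target - Ct_ref)_Input]),
directional one-sided Welch t-test validation calls at a lenient alpha, and
the per-category / overall validation-rate summary (a region validates when
any of its assayed amplicons does).

Ct tables are long-format with columns
``sample, group, target, fraction, ct, rep`` where fraction is one of
RT / ChIP / Input and technical replicates are averaged on the Ct scale
before any transformation.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "rt_relative_expression",
    "chip_qpcr_enrichment",
    "validate_target",
    "validation_summary",
    "anova_groups",
]


def _mean_ct(ct: pd.DataFrame, fraction: str) -> pd.DataFrame:
    sub = ct[ct["fraction"] == fraction]
    if sub.empty:
        raise ValueError(f"no rows for fraction {fraction!r}")
    return (sub.groupby(["sample", "group", "target"], as_index=False)["ct"].mean())


def rt_relative_expression(ct: pd.DataFrame, ref_gene: str = "TBP") -> pd.DataFrame:
    """Per-sample relative expression: 2^-(Ct_target - Ct_ref), RT fraction.

    Technical replicates are averaged on the Ct scale first.  Returns a long
    DataFrame (sample, group, target, value).
    """
    mean = _mean_ct(ct, "RT")
    ref = mean[mean["target"] == ref_gene].set_index("sample")["ct"]
    missing = set(mean["sample"]) - set(ref.index)
    if missing:
        raise ValueError(f"reference gene {ref_gene!r} missing for samples {sorted(missing)}")
    out = mean[mean["target"] != ref_gene].copy()
    out["value"] = 2.0 ** -(out["ct"].values - ref.loc[out["sample"]].values)
    return out[["sample", "group", "target", "value"]].reset_index(drop=True)


def chip_qpcr_enrichment(ct: pd.DataFrame, ref_locus: str = "GAPDH_ref") -> pd.DataFrame:
    """Per-sample ChIP enrichment normalised to a reference locus over input:
    value = 2^-[(Ct_t - Ct_ref)_ChIP - (Ct_t - Ct_ref)_Input]."""
    chip = _mean_ct(ct, "ChIP")
    inp = _mean_ct(ct, "Input")
    refs = {}
    for name, frame in (("ChIP", chip), ("Input", inp)):
        r = frame[frame["target"] == ref_locus].set_index("sample")["ct"]
        missing = set(frame["sample"]) - set(r.index)
        if missing:
            raise ValueError(f"reference locus missing in {name} for {sorted(missing)}")
        refs[name] = r
    chip_t = chip[chip["target"] != ref_locus].set_index(["sample", "target"])
    inp_t = inp[inp["target"] != ref_locus].set_index(["sample", "target"])
    joined = chip_t.join(inp_t, lsuffix="_chip", rsuffix="_input", how="inner")
    d_chip = joined["ct_chip"].values - refs["ChIP"].loc[
        joined.index.get_level_values("sample")].values
    d_input = joined["ct_input"].values - refs["Input"].loc[
        joined.index.get_level_values("sample")].values
    out = joined.reset_index()[["sample", "target"]]
    out["group"] = joined.reset_index()["group_chip"].values
    out["value"] = 2.0 ** -(d_chip - d_input)
    return out[["sample", "group", "target", "value"]]


def validate_target(values: Sequence[float], groups: Sequence[str],
                    expected_up: str, alpha: float = 0.2) -> Dict[str, object]:
    """Directional validation call for one target.

    Validated iff the group-mean difference has the expected sign AND the
    one-sided Welch t-test of (expected-up group) > (other group) has
    p < alpha.  Identical groups are never validated (p = 0.5).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    other = levels[0] if levels[1] == expected_up else levels[1]
    x_up = values[groups == expected_up]
    x_dn = values[groups == other]
    if len(x_up) < 2 or len(x_dn) < 2:
        raise ValueError("need >= 2 values per group")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        t, p_two = stats.ttest_ind(x_up, x_dn, equal_var=False)
    if not np.isfinite(t):  # zero within-group variance, identical means
        t, p_two = 0.0, 1.0
    p_one = p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0
    direction_ok = x_up.mean() > x_dn.mean()
    return {
        "t": float(t),
        "pvalue": float(p_one),
        "direction_ok": bool(direction_ok),
        "validated": bool(direction_ok and p_one < alpha),
    }


def validation_summary(calls: pd.DataFrame,
                       region_col: str = "locus",
                       category_col: Optional[str] = "category") -> pd.DataFrame:
    """Per-category and overall validation rates.

    ``calls`` has one row per assayed amplicon with a boolean ``validated``
    column; a region/locus is validated when at least one of its amplicons
    is.  Returns a table with counts and percentage per category plus an
    ``overall`` row.  Empty input returns an empty table (no division).
    """
    if calls.empty:
        return pd.DataFrame(columns=["category", "validated", "tested", "rate_pct"])
    per_region = calls.groupby(
        ([category_col] if category_col and category_col in calls else []) + [region_col]
    )["validated"].any().reset_index()
    rows = []
    if category_col and category_col in per_region:
        for cat, sub in per_region.groupby(category_col):
            rows.append((cat, int(sub["validated"].sum()), len(sub),
                         100.0 * sub["validated"].sum() / len(sub)))
    rows.append(("overall", int(per_region["validated"].sum()), len(per_region),
                 100.0 * per_region["validated"].sum() / len(per_region)))
    return pd.DataFrame(rows, columns=["category", "validated", "tested", "rate_pct"])


def anova_groups(values: Sequence[float], groups: Sequence[str]) -> Tuple[float, float]:
    """One-way ANOVA across sample groups (F statistic, p-value)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    arrays = [values[groups == g] for g in sorted(set(groups))]
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
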