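"""Immunoreactivity-score (IRS) computation and group comparison.

IRS = staining intensity grade (0-3; 0 admits fully negative staining)
times percent positive cells (0-100), giving scores on a 0-300 scale.
Group summaries report sample mean and SD (n-1 denominator); group
comparison uses classical one-way ANOVA; protein-protein co-expression
uses the Pearson correlation with its t-based two-sided p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

VALID_GRADES = (0, 1, 2, 3)


def irs_score(intensity: int, percent_positive: float) -> float:
    """Immunoreactivity score: intensity grade x percent positive."""
    if intensity not in VALID_GRADES:
        raise ValueError(f"intensity grade must be one of {VALID_GRADES}")
    if not (0.0 <= percent_positive <= 100.0):
        raise ValueError("percent_positive must lie in [0, 100]")
    return float(intensity) * float(percent_positive)


def add_irs(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a per-specimen table with an ``irs`` column."""
    out = records.copy()
    out["irs"] = [
        irs_score(int(i), float(p))
        for i, p in zip(out["intensity"], out["percent_positive"])
    ]
    return out


def group_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD (ddof=1, NA for n=1) and n of IRS per group x protein."""
    scored = records if "irs" in records.columns else add_irs(records)
    rows = []
    for (group, protein), sub in scored.groupby(["group", "protein"], sort=True):
        vals = sub["irs"].to_numpy(dtype=float)
        rows.append(
            {
                "group": group,
                "protein": protein,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows, columns=["group", "protein", "mean", "sd", "n"])


def one_way_anova(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA: F = MS_between / MS_within, F-dist p.

    Raises when within-group variance is zero everywhere (F undefined)
    unless the group means also coincide, in which case F=0, p=1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >=2 groups with >=2 observations each")
    within_var = sum(float(np.var(g, ddof=1)) for g in groups)
    means = [float(np.mean(g)) for g in groups]
    if within_var == 0.0:
        if np.ptp(means) == 0.0:
            return 0.0, 1.0
        raise ValueError("zero within-group variance everywhere: F undefined")
    F, p = stats.f_oneway(*groups)
    return float(F), float(p)


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with its two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("Pearson needs >=3 paired observations")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def protein_correlations(records: pd.DataFrame) -> pd.DataFrame:
    """Pairwise protein IRS correlations within each specimen group.

    Specimens are matched on a shared suffix-free id when possible;
    otherwise proteins are paired by within-group record order.
    Pairs whose correlation cannot be computed (constant values, too few
    pairs) are reported with NaN.
    """
    scored = records if "irs" in records.columns else add_irs(records)
    rows = []
    for group, sub in scored.groupby("group", sort=True):
        proteins = sorted(sub["protein"].unique())
        for i, a in enumerate(proteins):
            for b in proteins[i + 1 :]:
                va = sub[sub["protein"] == a]["irs"].to_numpy(dtype=float)
                vb = sub[sub["protein"] == b]["irs"].to_numpy(dtype=float)
                m = min(len(va), len(vb))
                r = p = np.nan
                if m >= 3:
                    va, vb = va[:m], vb[:m]
                    if np.std(va) > 0 and np.std(vb) > 0:
                        r, p = pearson(va, vb)
                rows.append(
                    {"group": group, "protein_a": a, "protein_b": b, "r": r, "p": p}
                )
    return pd.DataFrame(rows, columns=["group", "protein_a", "protein_b", "r", "p"])
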