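"""Statistical battery for density and intensity comparisons.

Thin, typed wrappers around scipy / pingouin covering the
analyses this pipeline feeds: Pearson and Spearman correlation (density vs
fluorescence intensity), unpaired and paired t tests, one-way ANOVA with
Tukey's HSD post hoc for region comparisons, and one-way repeated-measures
ANOVA with Greenhouse-Geisser correction (the per-animal design, where the
same subject contributes one value per region).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "TTestResult",
    "AnovaResult",
    "correlate",
    "ttest",
    "anova_oneway",
    "anova_rm",
]


@dataclass
class CorrelationResult:
    method: str
    r: float
    p: float
    n: int


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    paired: bool


@dataclass
class AnovaResult:
    design: str  # "one_way" | "repeated_measures"
    F: float
    df_num: float
    df_den: float
    p: float
    tukey: pd.DataFrame | None = None  # columns: group1, group2, mean_diff, p_adj


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Product-moment or rank correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if x.size < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method, float(res.statistic), float(res.pvalue), x.size)


def ttest(a, b, paired: bool = False) -> TTestResult:
    """Student's t test: pooled-variance unpaired (df = n1 + n2 - 2) or
    paired on difference scores (df = n - 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape or a.size < 2:
            raise ValueError("paired test needs equal-length samples, n >= 2")
        res = sps.ttest_rel(a, b)
        df = a.size - 1
    else:
        if a.size < 2 or b.size < 2:
            raise ValueError("each group needs n >= 2")
        res = sps.ttest_ind(a, b, equal_var=True)
        df = a.size + b.size - 2
    return TTestResult(float(res.statistic), float(df), float(res.pvalue), paired)


def _tukey_table(groups: list[np.ndarray], names: list[str]) -> pd.DataFrame:
    res = sps.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "mean_diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def anova_oneway(
    groups: dict[str, np.ndarray] | list[np.ndarray], tukey: bool = True
) -> AnovaResult:
    """One-way ANOVA across independent groups, optionally with Tukey HSD.

    df_num = k - 1 and df_den = N - k for k groups of total size N; each
    group needs at least two observations.
    """
    if isinstance(groups, dict):
        names = list(groups)
        arrays = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i + 1}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for name, g in zip(names, arrays):
        if g.size < 2:
            raise ValueError(f"group {name!r} has n < 2")
    F, p = sps.f_oneway(*arrays)
    k = len(arrays)
    N = sum(g.size for g in arrays)
    table = _tukey_table(arrays, names) if tukey else None
    return AnovaResult("one_way", float(F), float(k - 1), float(N - k), float(p), table)


def anova_rm(data: pd.DataFrame, dv: str, within: str, subject: str,
             tukey: bool = True) -> AnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``data`` is long-format with one row per subject x condition; the grid
    must be complete. Reported df are the sphericity-corrected (fractional)
    degrees of freedom, and the p-value is the corrected one whenever the
    correction applies (more than two conditions). The post hoc table is
    Tukey's HSD on the condition values.
    """
    import pingouin as pg

    counts = data.groupby(subject)[within].nunique()
    n_cond = data[within].nunique()
    if n_cond < 2:
        raise ValueError("need at least two conditions")
    if (counts != n_cond).any():
        raise ValueError("incomplete subject x condition grid")
    aov = pg.rm_anova(data=data, dv=dv, within=within, subject=subject,
                      correction=True, detailed=True)
    aov = aov.rename(columns=lambda c: c.replace("-", "_"))
    row = aov.iloc[0]
    eps = float(row["eps"]) if "eps" in aov.columns and np.isfinite(row.get("eps", np.nan)) else 1.0
    if "p_GG_corr" in aov.columns and np.isfinite(row.get("p_GG_corr", np.nan)):
        p = float(row["p_GG_corr"])
    else:
        p = float(row["p_unc"])
        eps = 1.0
    df_num = float(row["DF"]) * eps
    df_den = float(aov.iloc[1]["DF"]) * eps if len(aov) > 1 else np.nan
    F = float(row["F"])
    table = None
    if tukey:
        conds = sorted(data[within].unique())
        arrays = [data.loc[data[within] == c, dv].to_numpy(dtype=float) for c in conds]
        table = _tukey_table(arrays, [str(c) for c in conds])
    return AnovaResult("repeated_measures", F, df_num, df_den, p, table)
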