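"""Retrograde cell-count quantification and afferent phenotype classification.

Counts of retrogradely labelled neurons per brain region, per animal, in two
transgenic genotypes (vGAT-Cre marking GABAergic and vGLUT2-Cre marking
glutamatergic projection neurons) are normalized to each animal's total
subcortical cell count, summarized as mean +/- SEM fractions across animals,
and each region is called GABAergic / mixed / glutamatergic from the ratio
of its glutamatergic to GABAergic fraction:

    r = vGLUT2 fraction / vGAT fraction
    r < 0.2            -> GABAergic   (at least 5x more vGAT+ cells)
    0.2 <= r <= 5      -> mixed
    r > 5              -> glutamatergic

Regions contributing less than a reporting floor (default 3% of labelled
cells) are pooled into a "scattered/other" remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "normalize_counts",
    "summarize_regions",
    "classify_region",
    "coverage_summary",
    "double_label_fraction",
    "REFERENCE_REGION_MEANS",
]

GABAERGIC, MIXED, GLUTAMATERGIC = "GABAergic", "mixed", "glutamatergic"
OTHER_REGION = "scattered/other"

# Mean percentage of total subcortical retrogradely labelled cells per input
# region, per genotype, from the reference tract-tracing dataset (n = 3
# animals per genotype). Used as the generating profile for synthetic count
# tables and in worked examples. None = no labelled cells reported.
REFERENCE_REGION_MEANS: dict[str, dict[str, float | None]] = {
    # region: {"vGLUT2": pct, "vGAT": pct}
    "MnPO": {"vGLUT2": 4.35, "vGAT": None},
    "SUM": {"vGLUT2": 4.92, "vGAT": None},
    "PSTh": {"vGLUT2": 3.60, "vGAT": None},
    "PPTg": {"vGLUT2": 5.1, "vGAT": None},
    "MPL": {"vGLUT2": 8.44, "vGAT": None},
    "LPB": {"vGLUT2": 14.49, "vGAT": None},
    "BNST": {"vGLUT2": None, "vGAT": 10.95},
    "LH": {"vGLUT2": None, "vGAT": 12.53},
    "DM": {"vGLUT2": None, "vGAT": 4.70},
    "TRN": {"vGLUT2": None, "vGAT": 9.53},
    "ZI": {"vGLUT2": None, "vGAT": 7.54},
    "DR": {"vGLUT2": None, "vGAT": 6.04},
    "Ant-med amy": {"vGLUT2": 5.57, "vGAT": 3.79},
    "POA": {"vGLUT2": 8.85, "vGAT": 3.54},
    "PAG": {"vGLUT2": 16.13, "vGAT": 8.58},
    "DpMe": {"vGLUT2": 6.30, "vGAT": 11.43},
}


def _require_columns(table: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")


def normalize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-animal region fractions as percentages of the animal's total.

    Rows flagged ``excluded`` (cells attributed to tracer spread into
    neighbouring structures) are dropped from both numerator and
    denominator before normalization. Returns a long DataFrame with columns
    region, animal, genotype, pct.
    """
    _require_columns(table, ("region", "animal", "genotype", "count"))
    t = table.copy()
    if "excluded" in t.columns:
        t = t[~t["excluded"].fillna(False).astype(bool)]
    if (t["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if t.duplicated(subset=["region", "animal", "genotype"]).any():
        raise ValueError("(region, animal, genotype) rows must be unique")
    totals = t.groupby("animal")["count"].sum()
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"animal(s) with zero total cells: {list(zero.index)}")
    t = t.assign(pct=100.0 * t["count"] / t["animal"].map(totals))
    return t[["region", "animal", "genotype", "pct"]].reset_index(drop=True)


def summarize_regions(
    fractions: pd.DataFrame,
    min_report_pct: float = 3.0,
    ratio_low: float = 0.2,
    ratio_high: float = 5.0,
) -> pd.DataFrame:
    """Mean +/- SEM fraction per region and genotype, with phenotype calls.

    Per genotype, a region whose mean fraction falls below
    ``min_report_pct`` is pooled into the "scattered/other" remainder (the
    reporting floor for individually described input regions). SEM uses the
    n-1 standard deviation across animals. Regions retained for at least
    one genotype get a phenotype call from :func:`classify_region` on the
    pair of mean fractions (absent genotype = 0).
    """
    _require_columns(fractions, ("region", "animal", "genotype", "pct"))
    stats = (
        fractions.groupby(["region", "genotype"])["pct"]
        .agg(mean_pct="mean", sd="std", n="count")
        .reset_index()
    )
    stats["sem_pct"] = stats["sd"] / np.sqrt(stats["n"])
    stats = stats.drop(columns="sd")

    rows = []
    for genotype, sub in stats.groupby("genotype"):
        listed = sub[(sub["mean_pct"] >= min_report_pct) & (sub["region"] != OTHER_REGION)]
        pooled = sub[(sub["mean_pct"] < min_report_pct) | (sub["region"] == OTHER_REGION)]
        for _, r in listed.iterrows():
            rows.append(dict(r, pooled=False))
        if len(pooled):
            rows.append(
                {
                    "region": OTHER_REGION,
                    "genotype": genotype,
                    "mean_pct": pooled["mean_pct"].sum(),
                    "sem_pct": np.nan,
                    "n": int(pooled["n"].max()),
                    "pooled": True,
                }
            )
    out = pd.DataFrame(rows)

    calls = []
    for _, r in out.iterrows():
        if r["region"] == OTHER_REGION:
            calls.append((np.nan, ""))
            continue
        sel = out[(out["region"] == r["region"]) & ~out["pooled"]]
        vglut2 = float(sel.loc[sel["genotype"] == "vGLUT2", "mean_pct"].sum())
        vgat = float(sel.loc[sel["genotype"] == "vGAT", "mean_pct"].sum())
        ratio = np.inf if vgat == 0 else vglut2 / vgat
        calls.append((ratio, classify_region(vglut2, vgat, ratio_low, ratio_high)))
    out["ratio"] = [c[0] for c in calls]
    out["phenotype"] = [c[1] for c in calls]
    return out.reset_index(drop=True)


def classify_region(
    vglut2_frac: float, vgat_frac: float, low: float = 0.2, high: float = 5.0
) -> str:
    """Phenotype call from the glutamatergic/GABAergic fraction ratio.

    The ratio r = vglut2_frac / vgat_frac is compared with the closed band
    [low, high]: below it the region is GABAergic (>= 1/low times more
    vGAT+ cells), inside it mixed, above it glutamatergic. A zero
    denominator (or numerator) maps to the corresponding extreme; a region
    with no cells of either type is not a classifiable input.
    """
    if vglut2_frac < 0 or vgat_frac < 0:
        raise ValueError("fractions must be non-negative")
    if vglut2_frac == 0 and vgat_frac == 0:
        raise ValueError("both fractions zero: region is not an input")
    if vgat_frac == 0:
        return GLUTAMATERGIC
    r = vglut2_frac / vgat_frac
    if r < low:
        return GABAERGIC
    if r <= high:
        return MIXED
    return GLUTAMATERGIC


def coverage_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Listed-region coverage and scattered remainder per genotype.

    remainder = 100 - sum of listed (non-pooled) region means; with the
    reference profile this reproduces the listed/scattered split of the
    labelled-cell population.
    """
    rows = []
    for genotype, sub in summary.groupby("genotype"):
        listed = sub[~sub["pooled"]]["mean_pct"].sum()
        rows.append(
            {
                "genotype": genotype,
                "listed_pct": listed,
                "remainder_pct": 100.0 - listed,
            }
        )
    return pd.DataFrame(rows)


def double_label_fraction(n_double: int, n_total: int) -> float:
    """Percentage of double-labelled cells, to two decimals (e.g. colocalization
    of a virally expressed reporter with an immunostained marker)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_double <= n_total:
        raise ValueError("need 0 <= n_double <= n_total")
    return round(100.0 * n_double / n_total, 2)


def reference_fraction_profile() -> dict[str, dict[str, float]]:
    """Generating fractions (0-1) per genotype from the reference means,
    suitable for :func:`axonquant.simulate.generate_count_table`."""
    out: dict[str, dict[str, float]] = {"vGLUT2": {}, "vGAT": {}}
    for region, by_geno in REFERENCE_REGION_MEANS.items():
        for genotype, pct in by_geno.items():
            if pct is not None:
                out[genotype][region] = pct / 100.0
    return out
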