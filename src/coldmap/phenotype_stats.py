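"""Descriptive statistics, subspecies contrasts and correlation matrices for
the four percent-scale cold-tolerance measures."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import MEASURES


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, CV% = 100 * SD / mean (undefined for mean 0)."""
    if mean == 0:
        return float("nan")
    return 100.0 * sd / mean


def star_code(p: float) -> str:
    """Significance stars: '**' at p < 0.01, '*' at p < 0.05, else ''."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize(pheno: pd.DataFrame, measures=MEASURES) -> pd.DataFrame:
    """Per-(measure, subspecies) mean, range, sample SD (n-1) and CV%.

    Missing values are excluded per measure.  A group with every value
    missing raises; a zero mean yields a missing CV with a warning.
    """
    rows = []
    for measure in measures:
        for subsp, grp in pheno.groupby("subspecies", observed=True):
            vals = grp[measure].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                raise ValueError(f"all values missing for {measure} in {subsp}")
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            cv = cv_percent(mean, sd)
            if mean == 0:
                warnings.warn(f"CV undefined (zero mean) for {measure} in {subsp}")
            rows.append(
                {
                    "measure": measure,
                    "subspecies": subsp,
                    "n": int(vals.size),
                    "mean": mean,
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "sd": sd,
                    "cv": cv,
                }
            )
    return pd.DataFrame(rows)


def subspecies_contrast(pheno: pd.DataFrame, measure: str) -> dict:
    """Welch two-sample t-test between the two subspecies for one measure.

    Returns ``{"t", "p", "stars", "n1", "n2"}``.  Welch's unequal-variance
    form is used because the subspecies SDs differ substantially.
    """
    groups = {
        s: g[measure].dropna().to_numpy(dtype=float)
        for s, g in pheno.groupby("subspecies", observed=True)
    }
    if len(groups) < 2:
        raise ValueError("subspecies contrast requires both subspecies present")
    (n1_name, a), (n2_name, b) = sorted(groups.items())
    if np.array_equal(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "measure": measure,
        "t": float(t),
        "p": float(p),
        "stars": star_code(float(p)),
        "n1": int(a.size),
        "n2": int(b.size),
        "groups": (n1_name, n2_name),
    }


def correlation_matrix(
    pheno: pd.DataFrame, subspecies: str, measures=MEASURES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations among measures in one subspecies.

    Returns ``(r, stars)`` as square DataFrames; stars mark p < 0.01 as in
    the usual published correlation tables.  Zero-variance measures yield
    missing correlations with a warning.
    """
    sub = pheno.loc[pheno["subspecies"] == subspecies, list(measures)]
    r = pd.DataFrame(np.eye(len(measures)), index=measures, columns=measures)
    stars_df = pd.DataFrame("", index=measures, columns=measures)
    for i, mi in enumerate(measures):
        for j, mj in enumerate(measures):
            if j <= i:
                continue
            pair = sub[[mi, mj]].dropna()
            if len(pair) < 3:
                raise ValueError(f"<3 complete pairs for {mi} vs {mj} in {subspecies}")
            x, y = pair[mi].to_numpy(float), pair[mj].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"zero variance for {mi} or {mj} in {subspecies}")
                rij, pij = float("nan"), float("nan")
            else:
                rij, pij = stats.pearsonr(x, y)
            r.loc[mi, mj] = r.loc[mj, mi] = float(rij)
            code = "**" if pij == pij and pij < 0.01 else ""
            stars_df.loc[mi, mj] = stars_df.loc[mj, mi] = code
    return r, stars_df
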