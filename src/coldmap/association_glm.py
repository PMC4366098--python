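"""Per-marker fixed-effect GLM association scan with sequential significance
adjustment and QTL calling.

Each marker is tested within one subspecies by a one-way fixed-effects ANOVA
of the phenotype on genotype class (allele label):

    SS_model = sum_i n_i (xbar_i - xbar)²,   SS_E = sum_ij (x_ij - xbar_i)²,
    F = [SS_model/(k-1)] / [SS_E/(N-k)],     R² = SS_model / SS_total.

R² is reported as the marker's contribution to phenotypic variation (CPV).
The per-marker error mean square MS_E and the class means are retained for
the downstream relative-genotypic-effect statistic.

Multiple testing across a (subspecies, measure) scan uses a step-down rule:
p-values are visited in ascending order and the j-th is rejected iff it does
not exceed alpha * (1-alpha)^R, where R is the number of hypotheses already
rejected; the walk stops at the first failure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MEASURES, SUBSPECIES

logger = logging.getLogger(__name__)

#: QTL-name tag per measure, patterned on the qLT<measure><chrom>-<ordinal> convention.
MEASURE_TAGS: dict[str, str] = {
    "SSvR": "LTSSvR",
    "SStR_NL": "LTSStRNL",
    "SStR_CW": "LTSStRCW",
    "RSStR_CW": "LTRSStRCW",
}


@dataclass
class AssociationRecord:
    marker: str
    measure: str
    subspecies: str
    k: int  # genotype classes tested
    n: int  # accessions used (after class-size filtering)
    f_stat: float
    p_value: float
    r_squared: float  # CPV as a fraction in [0, 1]
    ms_error: float
    class_labels: tuple[str, ...]
    class_sizes: tuple[int, ...]
    class_means: tuple[float, ...]
    group_mean: float  # subspecies mean over the accessions used


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker": r.marker,
                "measure": r.measure,
                "subspecies": r.subspecies,
                "k": r.k,
                "n": r.n,
                "F": r.f_stat,
                "p": r.p_value,
                "cpv_percent": 100.0 * r.r_squared,
                "ms_error": r.ms_error,
            }
            for r in records
        ],
        columns=["marker", "measure", "subspecies", "k", "n", "F", "p", "cpv_percent", "ms_error"],
    )


def fit_marker_glm(
    panel: pd.DataFrame,
    pheno: pd.DataFrame,
    marker: str,
    measure: str,
    subspecies: str,
    min_class_size: int = 5,
    covariates: pd.DataFrame | None = None,
) -> AssociationRecord | None:
    """One-way ANOVA of ``measure`` on the genotype classes of ``marker``.

    Accessions of the given subspecies with a non-missing genotype and
    phenotype enter the fit; genotype classes with fewer than
    ``min_class_size`` members are dropped (not merged) beforehand, and the
    subspecies mean is recomputed over the accessions actually fitted.
    Returns None (logged) when fewer than two eligible classes remain.

    With ``covariates`` (accession-indexed numeric DataFrame, e.g. STRUCTURE
    Q columns) the marker is tested by the partial F of the genotype-class
    dummies added to the covariate-only model.
    """
    sub = pheno[pheno["subspecies"] == subspecies]
    geno = panel.loc[panel.index.intersection(sub.index), marker]
    df = pd.DataFrame({"g": geno, "y": sub.loc[geno.index, measure]}).dropna()
    counts = df["g"].value_counts()
    keep = counts[counts >= min_class_size].index
    df = df[df["g"].isin(keep)]
    if df["g"].nunique() < 2:
        logger.info("fit_marker_glm: %s/%s/%s skipped (<2 eligible classes)",
                    marker, measure, subspecies)
        return None

    labels = sorted(df["g"].unique())
    y = df["y"].to_numpy(dtype=float)
    n = y.size
    k = len(labels)
    class_means, class_sizes = [], []
    ss_e = 0.0
    grand = float(y.mean())
    ss_model = 0.0
    for lab in labels:
        yi = df.loc[df["g"] == lab, "y"].to_numpy(dtype=float)
        class_sizes.append(int(yi.size))
        mi = float(yi.mean())
        class_means.append(mi)
        ss_e += float(((yi - mi) ** 2).sum())
        ss_model += yi.size * (mi - grand) ** 2
    ss_total = ss_model + ss_e

    if covariates is not None:
        f_stat, p_value, ms_error = _partial_f(df, covariates)
        r_squared = ss_model / ss_total if ss_total > 0 else 0.0
    else:
        ms_error = ss_e / (n - k) if n > k else 0.0
        if ss_total == 0:
            f_stat, p_value, r_squared = 0.0, 1.0, 0.0
        elif ss_e == 0:
            warnings.warn(f"zero error SS at {marker}/{measure}/{subspecies}; p set to 0")
            f_stat, p_value, r_squared = float("inf"), 0.0, 1.0
        else:
            f_stat = (ss_model / (k - 1)) / (ss_e / (n - k))
            p_value = float(stats.f.sf(f_stat, k - 1, n - k))
            r_squared = ss_model / ss_total

    return AssociationRecord(
        marker=marker,
        measure=measure,
        subspecies=subspecies,
        k=k,
        n=n,
        f_stat=float(f_stat),
        p_value=float(p_value),
        r_squared=float(r_squared),
        ms_error=float(ms_error),
        class_labels=tuple(labels),
        class_sizes=tuple(class_sizes),
        class_means=tuple(class_means),
        group_mean=grand,
    )


def _partial_f(df: pd.DataFrame, covariates: pd.DataFrame) -> tuple[float, float, float]:
    """Partial F-test of genotype-class dummies added to covariates."""
    q = covariates.loc[df.index].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    n = y.size
    dummies = pd.get_dummies(df["g"], drop_first=True).to_numpy(dtype=float)
    k = dummies.shape[1] + 1
    x_r = np.column_stack([np.ones(n), q])
    x_f = np.column_stack([x_r, dummies])
    sse_r = _sse(x_r, y)
    sse_f = _sse(x_f, y)
    df2 = n - x_f.shape[1]
    ms_error = sse_f / df2
    if ms_error == 0:
        return float("inf"), 0.0, 0.0
    f_stat = ((sse_r - sse_f) / (k - 1)) / ms_error
    return float(f_stat), float(stats.f.sf(f_stat, k - 1, df2)), float(ms_error)


def _sse(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def scan_markers(
    panel: pd.DataFrame,
    pheno: pd.DataFrame,
    measures: Sequence[str] = MEASURES,
    subspecies: Sequence[str] = SUBSPECIES,
    min_class_size: int = 5,
    covariates: pd.DataFrame | None = None,
) -> list[AssociationRecord]:
    """Fit every marker for every requested (measure, subspecies) pair."""
    records = []
    for subsp in subspecies:
        for measure in measures:
            for marker in panel.columns:
                rec = fit_marker_glm(
                    panel, pheno, marker, measure, subsp,
                    min_class_size=min_class_size, covariates=covariates,
                )
                if rec is not None:
                    records.append(rec)
    return records


@dataclass
class SequentialResult:
    rejected: list[str]  # marker names, in rejection (ascending-p) order
    thresholds: dict[str, float] = field(default_factory=dict)  # threshold each p faced


def sequential_threshold(r: int, alpha: float = 0.05) -> float:
    """Significance level faced after r rejections: alpha * (1-alpha)^r."""
    return alpha * (1.0 - alpha) ** r


def sequential_adjust(
    pvalues: Mapping[str, float] | Sequence[tuple[str, float]],
    alpha: float = 0.05,
) -> SequentialResult:
    """Step-down sequential adjustment over one (subspecies, measure) scan.

    P-values are visited in ascending order (ties broken by name); the next
    one is rejected iff p <= alpha*(1-alpha)^R with R rejections so far, and
    the walk stops at the first failure.  Every hypothesis is assigned the
    threshold it faced (hypotheses past the stop face the final threshold).
    """
    items = list(pvalues.items()) if isinstance(pvalues, Mapping) else list(pvalues)
    for _, p in items:
        if not 0.0 <= p <= 1.0:
            raise ValueError("p-values must lie in [0, 1]")
    items.sort(key=lambda kv: (kv[1], kv[0]))
    result = SequentialResult(rejected=[])
    r = 0
    stopped = False
    for name, p in items:
        thr = sequential_threshold(r, alpha)
        result.thresholds[name] = thr
        if not stopped and p <= thr:
            result.rejected.append(name)
            r += 1
        else:
            stopped = True
    return result


def call_qtls(
    records: Sequence[AssociationRecord],
    marker_map: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the sequential adjustment per (subspecies, measure) scan and name
    the surviving markers as QTLs.

    Names follow q<tag><chrom>-<ordinal>, the ordinal running along each
    chromosome in position order within a measure; a marker significant for
    the same measure in both subspecies keeps one name.  Markers absent from
    the map are called without a chromosome (warning logged).
    """
    mm = marker_map.set_index("marker")
    by_scan: dict[tuple[str, str], list[AssociationRecord]] = {}
    for rec in records:
        by_scan.setdefault((rec.subspecies, rec.measure), []).append(rec)

    rejected: dict[tuple[str, str], SequentialResult] = {}
    for key, recs in by_scan.items():
        rejected[key] = sequential_adjust({r.marker: r.p_value for r in recs}, alpha)

    # Name QTLs per measure over the union of subspecies hits.
    names: dict[tuple[str, str], str] = {}
    measures = sorted({m for _, m in by_scan})
    for measure in measures:
        hits = sorted(
            {r for (s, m), res in rejected.items() if m == measure for r in res.rejected}
        )
        def sort_key(marker: str):
            if marker in mm.index:
                return (0, str(mm.loc[marker, "chrom"]), int(mm.loc[marker, "pos_bp"]))
            return (1, "", 0)
        ordinal: dict[str, int] = {}
        for marker in sorted(hits, key=sort_key):
            if marker in mm.index:
                chrom = str(mm.loc[marker, "chrom"])
            else:
                logger.warning("call_qtls: marker %s missing from map", marker)
                chrom = "NA"
            ordinal[chrom] = ordinal.get(chrom, 0) + 1
            names[(measure, marker)] = f"q{MEASURE_TAGS.get(measure, measure)}{chrom}-{ordinal[chrom]}"

    rows = []
    for (subsp, measure), res in sorted(rejected.items()):
        recs = {r.marker: r for r in by_scan[(subsp, measure)]}
        for marker in res.rejected:
            rec = recs[marker]
            chrom = str(mm.loc[marker, "chrom"]) if marker in mm.index else ""
            rows.append(
                {
                    "qtl": names[(measure, marker)],
                    "marker": marker,
                    "chrom": chrom,
                    "measure": measure,
                    "subspecies": subsp,
                    "p": rec.p_value,
                    "cpv_percent": 100.0 * rec.r_squared,
                    "ms_error": rec.ms_error,
                    "threshold": res.thresholds[marker],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["qtl", "marker", "chrom", "measure", "subspecies", "p",
                 "cpv_percent", "ms_error", "threshold"],
    )
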