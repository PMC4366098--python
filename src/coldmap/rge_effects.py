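"""Relative genotypic effects (RGE) and the z-classification of
cold-tolerant (positive) and cold-sensitive (negative) genotypes.

For genotype class i of a marker tested within subspecies s,

    RGE_si    = (xbar_si - xbar_s) / xbar_s
    MS_RGE_si = (MS_E / n_i) / xbar_s²
    z         = RGE_si / sqrt(MS_RGE_si)

where xbar_si is the class mean, xbar_s the subspecies mean over the
accessions in the fit, and MS_E the error mean square of the per-marker
ANOVA.  MS_E comes from a large sample relative to any single class, so z is
referred to the standard normal.  A class is called positive when z is
significantly greater than zero (cold-tolerant allele) and negative when
significantly smaller (cold-sensitive allele); RGE is scale-free, so a value
of -0.60 reads as a 60% reduction in the measure relative to the subspecies
mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .association_glm import AssociationRecord


@dataclass
class GenotypeEffect:
    genotype: str  # allele label, marker_size
    marker: str
    measure: str
    subspecies: str
    n_class: int
    class_mean: float
    group_mean: float
    rge: float
    ms_rge: float
    z: float
    p: float
    label: str = "neutral"  # positive | negative | neutral


def compute_rge(record: AssociationRecord) -> list[GenotypeEffect]:
    """RGE, its variance, and the z statistic for every genotype class of one
    association record.

    Raises when the subspecies mean is zero (the relative effect is then
    undefined for the whole (measure, subspecies) combination).
    """
    if record.group_mean == 0:
        raise ValueError(
            f"subspecies mean is zero for {record.measure}/{record.subspecies}; "
            "relative effects undefined"
        )
    effects = []
    for lab, n_i, mean_i in zip(
        record.class_labels, record.class_sizes, record.class_means
    ):
        rge = (mean_i - record.group_mean) / record.group_mean
        ms_rge = (record.ms_error / n_i) / record.group_mean**2
        if ms_rge > 0:
            z = rge / math.sqrt(ms_rge)
        else:
            z = 0.0 if rge == 0 else math.copysign(math.inf, rge)
        p = 2.0 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
        effects.append(
            GenotypeEffect(
                genotype=lab,
                marker=record.marker,
                measure=record.measure,
                subspecies=record.subspecies,
                n_class=n_i,
                class_mean=mean_i,
                group_mean=record.group_mean,
                rge=rge,
                ms_rge=ms_rge,
                z=float(z),
                p=float(p),
            )
        )
    return effects


def classify_genotypes(
    effects: Sequence[GenotypeEffect], alpha: float = 0.05
) -> list[GenotypeEffect]:
    """Label each effect positive (p < alpha, RGE > 0), negative (p < alpha,
    RGE < 0) or neutral, in place; returns the same list."""
    for e in effects:
        if e.p < alpha and e.rge > 0:
            e.label = "positive"
        elif e.p < alpha and e.rge < 0:
            e.label = "negative"
        else:
            e.label = "neutral"
    return list(effects)


def classification_counts(effects: Sequence[GenotypeEffect]) -> pd.DataFrame:
    """Per-subspecies counts of positive/negative/neutral genotype calls."""
    df = effects_to_frame(effects)
    return (
        df.groupby(["subspecies", "label"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )


def effect_asymmetry_summary(effects: Sequence[GenotypeEffect]) -> pd.DataFrame:
    """Mean and max |RGE| of the positive vs negative classes per subspecies.

    An absent class within a subspecies yields a row with n=0 and missing
    summaries, so asymmetric scans remain visible rather than erroring.
    """
    df = effects_to_frame(effects)
    rows = []
    for subsp in sorted(df["subspecies"].unique()):
        for label in ("positive", "negative"):
            vals = df.loc[
                (df["subspecies"] == subsp) & (df["label"] == label), "rge"
            ].abs()
            rows.append(
                {
                    "subspecies": subsp,
                    "label": label,
                    "n": int(vals.size),
                    "mean_abs_rge": float(vals.mean()) if vals.size else float("nan"),
                    "max_abs_rge": float(vals.max()) if vals.size else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["subspecies", "label", "n", "mean_abs_rge", "max_abs_rge"])


def effects_to_frame(effects: Sequence[GenotypeEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genotype": e.genotype,
                "marker": e.marker,
                "measure": e.measure,
                "subspecies": e.subspecies,
                "n_class": e.n_class,
                "class_mean": e.class_mean,
                "group_mean": e.group_mean,
                "rge": e.rge,
                "ms_rge": e.ms_rge,
                "z": e.z,
                "p": e.p,
                "label": e.label,
            }
            for e in effects
        ],
        columns=["genotype", "marker", "measure", "subspecies", "n_class",
                 "class_mean", "group_mean", "rge", "ms_rge", "z", "p", "label"],
    )


def qtl_effects(
    records: Sequence[AssociationRecord],
    qtl_calls: pd.DataFrame,
    alpha: float = 0.05,
    all_markers: bool = False,
) -> list[GenotypeEffect]:
    """Classified effects for every genotype class of every called QTL.

    By default only markers surviving the sequential adjustment (rows of
    ``qtl_calls``) contribute; ``all_markers=True`` computes effects for
    every association record (exploratory use).
    """
    if all_markers:
        selected = list(records)
    else:
        called = {
            (row.marker, row.measure, row.subspecies)
            for row in qtl_calls.itertuples()
        }
        selected = [
            r for r in records if (r.marker, r.measure, r.subspecies) in called
        ]
    effects: list[GenotypeEffect] = []
    for rec in selected:
        effects.extend(compute_rge(rec))
    return classify_genotypes(effects, alpha)
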