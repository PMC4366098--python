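"""Breeding-oriented screens built on the classified genotype effects:
positive-genotype pyramiding counts, phenotype-by-count summaries,
strong-negative-genotype flags, and top-accession genotype tables.

Genotype identity is always the full allele label (marker + fragment size);
a different allele at the same marker never counts as carrying the genotype.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .rge_effects import GenotypeEffect, effects_to_frame

logger = logging.getLogger(__name__)


def _label_set(
    effects: Sequence[GenotypeEffect], subspecies: str, measure: str, label: str
) -> list[tuple[str, str, float]]:
    """(marker, genotype, rge) triples of one class discovered in one subspecies."""
    return [
        (e.marker, e.genotype, e.rge)
        for e in effects
        if e.subspecies == subspecies and e.measure == measure and e.label == label
    ]


def count_positive_genotypes(
    panel: pd.DataFrame,
    pheno: pd.DataFrame,
    effects: Sequence[GenotypeEffect],
    reference_subspecies: str,
    measure: str,
) -> pd.DataFrame:
    """Pyramiding profile: for every accession (both subspecies), the number
    of positive genotypes from the reference subspecies' discovery set that
    it carries, plus any carried negative genotypes with their RGE.

    A missing genotype call at a marker contributes 0 to the count.
    """
    positives = _label_set(effects, reference_subspecies, measure, "positive")
    negatives = _label_set(effects, reference_subspecies, measure, "negative")
    if not positives:
        warnings.warn(
            f"no positive genotypes for {measure} discovered in {reference_subspecies}; "
            "all counts are 0"
        )
    count = np.zeros(len(panel), dtype=int)
    for marker, genotype, _ in positives:
        count += (panel[marker] == genotype).to_numpy()
    neg_carried = []
    for acc in panel.index:
        carried = [
            f"{genotype}({rge:+.3f})"
            for marker, genotype, rge in negatives
            if panel.at[acc, marker] == genotype
        ]
        neg_carried.append(";".join(carried))
    return pd.DataFrame(
        {
            "accession": panel.index,
            "subspecies": pheno.loc[panel.index, "subspecies"].to_numpy(),
            "measure": measure,
            "reference_subspecies": reference_subspecies,
            "value": pheno.loc[panel.index, measure].to_numpy(dtype=float),
            "positive_count": count,
            "negative_genotypes": neg_carried,
        }
    ).set_index("accession")


def phenotype_by_count(
    profiles: pd.DataFrame,
    subspecies: str,
    min_class_size: int = 3,
) -> pd.DataFrame:
    """Mean/SD of the measure by positive-genotype count within one
    subspecies, merging count classes with fewer than ``min_class_size``
    accessions into the nearest populated class so summaries stay stable."""
    sub = profiles[profiles["subspecies"] == subspecies].copy()
    counts = sub["positive_count"].value_counts().sort_index()
    merged = {}
    kept = counts[counts >= min_class_size].index.to_numpy()
    for c in counts.index:
        if c in kept or kept.size == 0:
            merged[c] = c
        else:
            merged[c] = int(kept[np.argmin(np.abs(kept - c))])
    sub["count_class"] = sub["positive_count"].map(merged)
    out = (
        sub.groupby("count_class")["value"]
        .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return out


def flag_strong_negatives(
    panel: pd.DataFrame,
    effects: Sequence[GenotypeEffect],
    threshold_rge: float = 0.5,
) -> pd.DataFrame:
    """Accessions carrying any negative genotype with RGE <= -threshold_rge,
    listing the offending genotype, its measure/subspecies of discovery and
    its RGE."""
    strong = [
        e
        for e in effects
        if e.label == "negative" and e.rge <= -threshold_rge
    ]
    rows = []
    for e in strong:
        carriers = panel.index[(panel[e.marker] == e.genotype).to_numpy()]
        for acc in carriers:
            rows.append(
                {
                    "accession": acc,
                    "genotype": e.genotype,
                    "measure": e.measure,
                    "subspecies": e.subspecies,
                    "rge": e.rge,
                }
            )
    return pd.DataFrame(rows, columns=["accession", "genotype", "measure", "subspecies", "rge"])


def top_accessions(
    pheno: pd.DataFrame,
    panel: pd.DataFrame,
    effects: Sequence[GenotypeEffect],
    measure: str,
    subspecies: str,
    k: int = 5,
    strong_threshold: float = 0.5,
) -> pd.DataFrame:
    """Top-k accessions of one subspecies by a measure, with presence/absence
    of every positive and negative genotype discovered for that
    (measure, subspecies).

    Ranking is by measure value descending, ties broken by accession id
    ascending.  Adds summary booleans: ``has_positive`` (carries at least one
    positive genotype) and ``has_strong_negative`` (carries a negative
    genotype with RGE <= -strong_threshold).
    """
    sub = pheno[(pheno["subspecies"] == subspecies) & pheno[measure].notna()]
    if len(sub) < k:
        warnings.warn(
            f"only {len(sub)} accessions available for {measure}/{subspecies}; "
            f"top table truncated from k={k}"
        )
        k = len(sub)
    ranked = sub.reset_index().sort_values(
        by=[measure, "accession"], ascending=[False, True]
    )["accession"].tolist()[:k]

    positives = _label_set(effects, subspecies, measure, "positive")
    negatives = _label_set(effects, subspecies, measure, "negative")
    rows = []
    for rank, acc in enumerate(ranked, start=1):
        row = {
            "rank": rank,
            "accession": acc,
            "value": float(pheno.at[acc, measure]),
        }
        has_pos = False
        has_strong_neg = False
        for marker, genotype, _ in positives:
            present = bool(panel.at[acc, marker] == genotype)
            row[f"pos:{genotype}"] = int(present)
            has_pos = has_pos or present
        for marker, genotype, rge in negatives:
            present = bool(panel.at[acc, marker] == genotype)
            row[f"neg:{genotype}"] = int(present)
            if present and rge <= -strong_threshold:
                has_strong_neg = True
        row["has_positive"] = has_pos
        row["has_strong_negative"] = has_strong_neg
        rows.append(row)
    return pd.DataFrame(rows)
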