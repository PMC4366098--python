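"""Shared constants and plain-CSV readers/writers for the pipeline's tabular formats.

All tables travel as headered CSV: the genotype panel has accessions as rows
and markers as columns (cells are allele labels like ``RM5496_136``, empty =
missing); the marker map has columns ``marker, chrom, pos_bp`` (1-based bp);
the phenotype table has ``accession, subspecies`` plus the four percent-scale
cold-tolerance measures.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

#: The four cold-tolerance measures, in canonical column order.
#: SSvR — seedling survival rate under low temperature at germination (%);
#: SStR_NL — seed setting rate under natural low temperature at booting (%);
#: SStR_CW — seed setting rate under cold-water irrigation at booting (%);
#: RSStR_CW — seed setting under cold water relative to normal conditions (%).
MEASURES: tuple[str, ...] = ("SSvR", "SStR_NL", "SStR_CW", "RSStR_CW")

#: Subspecies labels used throughout; panels are split on this column.
SUBSPECIES: tuple[str, str] = ("indica", "japonica")

#: Decimal places used when serializing percent values (keeps reruns byte-stable).
FLOAT_FORMAT = "%.4f"


def write_genotypes(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index_label="accession", na_rep="")


def read_genotypes(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path, index_col="accession", dtype=str, keep_default_na=False)
    # object dtype with float NaN for missing keeps elementwise == comparisons boolean
    return panel.astype(object).mask(panel == "")


def write_marker_map(marker_map: pd.DataFrame, path: str | Path) -> None:
    marker_map.to_csv(path, index=False)


def read_marker_map(path: str | Path) -> pd.DataFrame:
    mm = pd.read_csv(path, dtype={"marker": str, "chrom": str, "pos_bp": int})
    missing = {"marker", "chrom", "pos_bp"} - set(mm.columns)
    if missing:
        raise ValueError(f"marker map lacks required columns: {sorted(missing)}")
    return mm


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, index_label="accession", float_format=FLOAT_FORMAT)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    pheno = pd.read_csv(path, index_col="accession")
    missing = {"subspecies", *MEASURES} - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype table lacks required columns: {sorted(missing)}")
    return pheno
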