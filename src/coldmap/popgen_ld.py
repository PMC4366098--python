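"""Pairwise multi-allelic linkage disequilibrium, LD-by-distance binning, and
the Evanno delta-K helper for externally supplied STRUCTURE LnP(D) runs.

Accessions are fully homozygous inbreds, so each accession contributes one
known haplotype and two-locus haplotype frequencies are obtained by direct
counting — no EM phasing is needed.  For a pair of multi-allelic markers the
reported r² is the frequency-weighted average over ordered allele pairs,

    r² = sum_ab  p_a p_b * D_ab² / (p_a (1-p_a) p_b (1-p_b)),

the convention used by standard association-mapping toolkits; it reduces
exactly to the classical biallelic r² when both markers carry two alleles.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Distance bin edges in kb; bins are half-open [lo, hi).
LD_BIN_EDGES_KB: tuple[float, ...] = (0.0, 50.0, 150.0, 500.0, 1000.0, float("inf"))


def _bin_label(lo: float, hi: float) -> str:
    return f"[{lo:g},{hi:g})kb" if np.isfinite(hi) else f">={lo:g}kb"


LD_BIN_LABELS: tuple[str, ...] = tuple(
    _bin_label(lo, hi) for lo, hi in itertools.pairwise(LD_BIN_EDGES_KB)
)


def pair_r2(g1: np.ndarray, g2: np.ndarray) -> tuple[float, int] | None:
    """Multi-allelic r² between two aligned genotype-label vectors.

    Missing entries are dropped pairwise; returns ``(r2, n)`` or None when
    fewer than 2 complete haplotypes remain or either marker is monomorphic
    within the complete cases.
    """
    g1 = np.asarray(g1, dtype=object)
    g2 = np.asarray(g2, dtype=object)
    keep = ~(pd.isna(g1) | pd.isna(g2))
    g1, g2 = g1[keep], g2[keep]
    n = g1.size
    if n < 2:
        return None
    a1, i1 = np.unique(g1.astype(str), return_inverse=True)
    a2, i2 = np.unique(g2.astype(str), return_inverse=True)
    if a1.size < 2 or a2.size < 2:
        return None
    joint = np.zeros((a1.size, a2.size))
    np.add.at(joint, (i1, i2), 1.0)
    joint /= n
    p1 = joint.sum(axis=1)
    p2 = joint.sum(axis=0)
    d = joint - np.outer(p1, p2)
    denom = np.outer(p1 * (1.0 - p1), p2 * (1.0 - p2))
    r2_ab = d**2 / denom
    r2 = float(np.sum(np.outer(p1, p2) * r2_ab))
    return r2, int(n)


def pairwise_r2(
    panel: pd.DataFrame,
    marker_map: pd.DataFrame,
    scope: list[str] | pd.Index | None = None,
) -> pd.DataFrame:
    """All pairwise LD records for the markers in ``marker_map``.

    ``scope`` optionally restricts to a subset of accessions (e.g. one
    subspecies).  Monomorphic-in-scope pairs are skipped and counted in the
    log.  Returns columns: marker1, marker2, same_chrom, dist_bp, r2, n.
    """
    sub = panel if scope is None else panel.loc[scope]
    mm = marker_map.set_index("marker")
    markers = [m for m in mm.index if m in sub.columns]
    cols = {m: sub[m].to_numpy(dtype=object) for m in markers}
    rows = []
    skipped = 0
    for m1, m2 in itertools.combinations(markers, 2):
        res = pair_r2(cols[m1], cols[m2])
        if res is None:
            skipped += 1
            continue
        r2, n = res
        same = mm.loc[m1, "chrom"] == mm.loc[m2, "chrom"]
        dist = abs(int(mm.loc[m1, "pos_bp"]) - int(mm.loc[m2, "pos_bp"])) if same else np.nan
        rows.append(
            {
                "marker1": m1,
                "marker2": m2,
                "same_chrom": bool(same),
                "dist_bp": dist,
                "r2": r2,
                "n": n,
            }
        )
    if skipped:
        logger.info("pairwise_r2: skipped %d monomorphic/undersized pairs", skipped)
    return pd.DataFrame(
        rows, columns=["marker1", "marker2", "same_chrom", "dist_bp", "r2", "n"]
    )


def bin_ld_by_distance(records: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of r² in half-open physical-distance bins.

    Intra-chromosomal pairs are binned by bp distance; inter-chromosomal
    pairs are excluded from the bins but contribute to the trailing
    genome-wide summary row (which averages every pair).
    """
    rows = []
    intra = records[records["same_chrom"]]
    dist_kb = intra["dist_bp"].to_numpy(float) / 1000.0
    for (lo, hi), label in zip(itertools.pairwise(LD_BIN_EDGES_KB), LD_BIN_LABELS):
        vals = intra.loc[(dist_kb >= lo) & (dist_kb < hi), "r2"].to_numpy(float)
        rows.append(
            {
                "bin": label,
                "n": int(vals.size),
                "mean_r2": float(vals.mean()) if vals.size else np.nan,
                "sd_r2": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
            }
        )
    all_r2 = records["r2"].to_numpy(float)
    rows.append(
        {
            "bin": "genome-wide",
            "n": int(all_r2.size),
            "mean_r2": float(all_r2.mean()) if all_r2.size else np.nan,
            "sd_r2": float(all_r2.std(ddof=1)) if all_r2.size > 1 else np.nan,
        }
    )
    return pd.DataFrame(rows, columns=["bin", "n", "mean_r2", "sd_r2"])


def evanno_delta_k(table: pd.DataFrame) -> pd.DataFrame:
    """Evanno's delta-K from a (K, rep, lnpd) table of STRUCTURE runs.

    delta-K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / SD_K, where the
    means are over replicates and SD_K is the n-1 replicate SD of L(K).
    Defined only for interior K with both neighbours present; a zero SD
    yields a missing delta-K with a warning in the log.
    """
    required = {"K", "rep", "lnpd"}
    if not required <= set(table.columns):
        raise ValueError(f"LnP(D) table needs columns {sorted(required)}")
    grp = table.groupby("K")["lnpd"]
    means = grp.mean()
    sds = grp.std(ddof=1)
    ks = sorted(means.index)
    rows = []
    for k in ks:
        if (k - 1) not in means.index or (k + 1) not in means.index:
            continue
        num = abs(means[k + 1] - 2.0 * means[k] + means[k - 1])
        sd = sds[k]
        if not np.isfinite(sd) or sd == 0:
            logger.warning("evanno_delta_k: zero/undefined replicate SD at K=%d", k)
            dk = np.nan
        else:
            dk = num / sd
        rows.append(
            {"K": int(k), "delta_k": float(dk), "mean_lnpd": float(means[k]), "sd_lnpd": float(sd)}
        )
    return pd.DataFrame(rows, columns=["K", "delta_k", "mean_lnpd", "sd_lnpd"])
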