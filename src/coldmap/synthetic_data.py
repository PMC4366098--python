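"""Simulation of SSR genotype panels and cold-tolerance phenotypes.

The generator emulates a structured inbred rice diversity panel: two diverged
subpopulations (indica / japonica) genotyped at multi-allelic SSR markers,
with optional linkage disequilibrium between physically close markers and
planted allele effects ("QTLs") on four percent-scale cold-tolerance
measures.  Accessions are fully homozygous, so each genotype cell is a single
allele label of the form ``<marker>_<fragment-size>``.

Model sketch
------------
* Per marker, a base allele-frequency vector is drawn from a flat Dirichlet;
  each subpopulation then draws its own frequencies from
  ``Dirichlet(divergence * base)``.  Small ``divergence`` concentrates mass at
  the simplex vertices, producing near-fixed, subpopulation-private alleles.
* Within a chromosome, a marker lying within ``ld_block_span`` bp of its
  predecessor copies each accession's allele index from the predecessor with
  probability ``1 - ld_mutation_rate``, inducing LD that decays with the
  number of intervening markers (hence, stochastically, with distance).
* Phenotype = subpopulation baseline + planted allele effects + Gaussian
  noise, clamped to [0, 100].  RSStR_CW is derived as
  ``100 * SStR_CW / (normal-condition seed set)`` so the two booting-stage
  measures are strongly correlated, as observed in real panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MEASURES, SUBSPECIES

# Approximate rice chromosome lengths (bp), chromosomes 1-12.
RICE_CHROM_LENGTHS: tuple[int, ...] = (
    43_270_000, 35_940_000, 36_410_000, 35_500_000, 29_960_000, 31_250_000,
    29_700_000, 28_440_000, 23_010_000, 23_210_000, 29_020_000, 27_530_000,
)

# Observed subspecies means (%) for each measure in the 174-accession
# reference panel; used as simulator baselines.
DEFAULT_BASELINE_MEANS: dict[str, dict[str, float]] = {
    "indica": {"SSvR": 23.39, "SStR_NL": 18.88, "SStR_CW": 14.71, "RSStR_CW": 14.57},
    "japonica": {"SSvR": 79.11, "SStR_NL": 29.89, "SStR_CW": 16.87, "RSStR_CW": 25.79},
}

# Residual SDs (%). For the three directly simulated measures these follow the
# observed per-subspecies SDs; RSStR_CW inherits most of its variance through
# the ratio to normal-condition seed set, so only a small residual is added.
DEFAULT_NOISE_SD: dict[str, dict[str, float]] = {
    "SSvR": {"indica": 18.03, "japonica": 28.67},
    "SStR_NL": {"indica": 21.33, "japonica": 26.41},
    "SStR_CW": {"indica": 21.24, "japonica": 19.54},
    "RSStR_CW": {"indica": 4.0, "japonica": 4.0},
}


@dataclass(frozen=True)
class QTLSpec:
    """A planted allele effect: ``effect`` percent points added to ``measure``
    for accessions of ``scope`` ('indica', 'japonica' or 'both') carrying
    allele ``allele_index`` at marker ``marker_index``."""

    marker_index: int
    allele_index: int
    measure: str
    effect: float
    scope: str = "both"


@dataclass
class SimulationConfig:
    n_accessions: int = 174
    subpop_proportions: Sequence[float] = (109 / 174, 65 / 174)
    subpop_names: Sequence[str] = SUBSPECIES
    n_markers: int = 273
    alleles_per_marker: int | Sequence[int] = 4
    base_allele_conc: float = 1.0
    divergence: float = 1.0
    ld_block_span: int = 100_000
    ld_mutation_rate: float = 0.1
    chrom_lengths: Sequence[int] = RICE_CHROM_LENGTHS
    qtl_spec: Sequence[QTLSpec] = ()
    baseline_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_BASELINE_MEANS
    )
    noise_sd: Mapping[str, Mapping[str, float] | float] = field(
        default_factory=lambda: DEFAULT_NOISE_SD
    )
    normal_sd: float = 8.0  # SD of normal-condition seed set feeding RSStR_CW
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.subpop_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("subpop_proportions must sum to 1")
        if (props <= 0).any():
            raise ValueError("subpop_proportions must be positive")
        if len(self.subpop_names) != len(props):
            raise ValueError("subpop_names and subpop_proportions length mismatch")
        if self.n_accessions <= 0 or self.n_markers <= 0:
            raise ValueError("counts must be positive")
        for k in self._allele_counts():
            if k < 2:
                raise ValueError("alleles_per_marker must be >= 2 for every marker")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.divergence <= 0:
            raise ValueError("divergence must be positive")
        if self.base_allele_conc <= 0:
            raise ValueError("base_allele_conc must be positive")
        for q in self.qtl_spec:
            if not math.isfinite(q.effect):
                raise ValueError("QTL effect sizes must be finite")
            if q.measure not in MEASURES:
                raise ValueError(f"unknown measure in qtl_spec: {q.measure}")
            if q.scope not in (*self.subpop_names, "both"):
                raise ValueError(f"unknown scope in qtl_spec: {q.scope}")

    def _allele_counts(self) -> np.ndarray:
        if isinstance(self.alleles_per_marker, int):
            return np.full(self.n_markers, self.alleles_per_marker)
        counts = np.asarray(self.alleles_per_marker, dtype=int)
        if counts.size != self.n_markers:
            raise ValueError("per-marker allele counts must match n_markers")
        return counts

    def subpop_sizes(self) -> list[int]:
        """Largest-remainder apportionment of accessions to subpopulations."""
        props = np.asarray(self.subpop_proportions, dtype=float)
        raw = props * self.n_accessions
        sizes = np.floor(raw).astype(int)
        for i in np.argsort(-(raw - sizes))[: self.n_accessions - sizes.sum()]:
            sizes[i] += 1
        return sizes.tolist()

    def noise_sd_for(self, measure: str, subpop: str) -> float:
        sd = self.noise_sd[measure]
        return float(sd[subpop]) if isinstance(sd, Mapping) else float(sd)


@dataclass(frozen=True)
class RealizedQTL:
    marker: str
    allele_label: str
    measure: str
    effect: float
    scope: str


@dataclass
class GroundTruth:
    """Everything needed to score parameter recovery against the simulation."""

    subpop: pd.Series  # accession -> subpopulation label
    qtls: list[RealizedQTL]
    allele_freqs: dict[str, dict[str, np.ndarray]]  # marker -> subpop -> freqs
    allele_labels: dict[str, list[str]]  # marker -> label per allele index


def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    raw = weights / weights.sum() * total
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: total - counts.sum()]:
        counts[i] += 1
    return counts


def _build_marker_map(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    lengths = np.asarray(config.chrom_lengths, dtype=float)
    per_chrom = _apportion(lengths, config.n_markers)
    rows = []
    idx = 0
    for c, (length, cnt) in enumerate(zip(config.chrom_lengths, per_chrom), start=1):
        pos = np.sort(rng.integers(1, int(length) + 1, size=int(cnt)))
        for p in pos:
            idx += 1
            rows.append({"marker": f"RM{idx:04d}", "chrom": str(c), "pos_bp": int(p)})
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos_bp"])


def simulate_genotypes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a homozygous multi-allelic SSR panel with population structure.

    Returns ``(panel, marker_map, truth)`` where ``panel`` is an
    accessions x markers DataFrame of allele labels (NA = missing).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    marker_map = _build_marker_map(config, rng)
    n = config.n_accessions
    m = config.n_markers
    allele_counts = config._allele_counts()

    sizes = config.subpop_sizes()
    subpop_labels = np.repeat(list(config.subpop_names), sizes)
    accessions = [f"ACC{i + 1:04d}" for i in range(n)]
    subpop = pd.Series(subpop_labels, index=pd.Index(accessions, name="accession"))
    blocks = {}
    start = 0
    for name, size in zip(config.subpop_names, sizes):
        blocks[name] = slice(start, start + size)
        start += size

    # Subpopulation allele frequencies per marker.
    freqs: dict[str, dict[str, np.ndarray]] = {}
    labels: dict[str, list[str]] = {}
    for j, row in enumerate(marker_map.itertuples()):
        k = int(allele_counts[j])
        base = rng.dirichlet(np.full(k, config.base_allele_conc))
        freqs[row.marker] = {
            name: rng.dirichlet(config.divergence * k * base)
            for name in config.subpop_names
        }
        labels[row.marker] = [f"{row.marker}_{100 + 4 * a}" for a in range(k)]

    # Allele-index matrix; neighbour copy-with-mutation induces LD.
    alleles = np.empty((n, m), dtype=np.int64)
    prev_chrom, prev_pos, prev_j = None, None, None
    for j, row in enumerate(marker_map.itertuples()):
        k = int(allele_counts[j])
        fresh = np.empty(n, dtype=np.int64)
        for name in config.subpop_names:
            sl = blocks[name]
            fresh[sl] = rng.choice(k, size=sl.stop - sl.start, p=freqs[row.marker][name])
        linked = (
            prev_chrom == row.chrom
            and row.pos_bp - prev_pos <= config.ld_block_span
        )
        if linked:
            copy = rng.random(n) >= config.ld_mutation_rate
            alleles[:, j] = np.where(copy, alleles[:, prev_j] % k, fresh)
        else:
            alleles[:, j] = fresh
        prev_chrom, prev_pos, prev_j = row.chrom, row.pos_bp, j

    cells = np.empty((n, m), dtype=object)
    for j, marker in enumerate(marker_map["marker"]):
        lab = np.asarray(labels[marker], dtype=object)
        cells[:, j] = lab[alleles[:, j]]
    if config.missing_rate > 0:
        cells[rng.random((n, m)) < config.missing_rate] = None
    panel = pd.DataFrame(
        cells, index=subpop.index, columns=marker_map["marker"].tolist()
    )

    realized = []
    for q in config.qtl_spec:
        marker = marker_map["marker"].iloc[q.marker_index]
        if not 0 <= q.allele_index < allele_counts[q.marker_index]:
            raise ValueError(
                f"qtl_spec references allele {q.allele_index} absent at {marker}"
            )
        realized.append(
            RealizedQTL(marker, labels[marker][q.allele_index], q.measure, q.effect, q.scope)
        )
    truth = GroundTruth(subpop=subpop, qtls=realized, allele_freqs=freqs, allele_labels=labels)
    return panel, marker_map, truth


def _effect_vector(
    panel: pd.DataFrame, truth: GroundTruth, measure: str
) -> np.ndarray:
    """Summed planted effects on ``measure`` for each accession."""
    eff = np.zeros(len(panel))
    for q in truth.qtls:
        if q.measure != measure:
            continue
        carriers = (panel[q.marker] == q.allele_label).to_numpy()
        if q.scope != "both":
            carriers &= (truth.subpop == q.scope).to_numpy()
        eff[carriers] += q.effect
    return eff


def simulate_phenotypes(
    panel: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the four cold-tolerance measures for every accession.

    SSvR, SStR_NL and SStR_CW are baseline + planted effects + noise, clamped
    to [0, 100].  RSStR_CW is 100 * SStR_CW / N where N is a per-accession
    normal-condition seed setting rate whose subpopulation mean is implied by
    the SStR_CW and RSStR_CW baselines; this couples the two cold-water
    measures the way repeated measurements of the same panicles are coupled.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    missing = set(panel.index) - set(truth.subpop.index)
    if missing:
        raise ValueError(
            f"accessions missing a subpopulation assignment: {sorted(missing)[:5]}"
        )
    subpop = truth.subpop.loc[panel.index]
    n = len(panel)

    values: dict[str, np.ndarray] = {}
    for measure in ("SSvR", "SStR_NL", "SStR_CW"):
        base = np.array([config.baseline_means[s][measure] for s in subpop])
        sd = np.array([config.noise_sd_for(measure, s) for s in subpop])
        val = base + _effect_vector(panel, truth, measure) + rng.normal(0.0, 1.0, n) * sd
        values[measure] = np.clip(val, 0.0, 100.0)

    # Normal-condition seed set: mean implied by the two baseline means so that
    # the noise-free ratio reproduces the RSStR_CW baseline exactly.
    normal_mean = np.array(
        [
            100.0 * config.baseline_means[s]["SStR_CW"] / config.baseline_means[s]["RSStR_CW"]
            for s in subpop
        ]
    )
    normal = normal_mean + rng.normal(0.0, 1.0, n) * config.normal_sd
    normal = np.clip(normal, 20.0, 130.0)
    sd_r = np.array([config.noise_sd_for("RSStR_CW", s) for s in subpop])
    rsstr = (
        100.0 * values["SStR_CW"] / normal
        + _effect_vector(panel, truth, "RSStR_CW")
        + rng.normal(0.0, 1.0, n) * sd_r
    )
    values["RSStR_CW"] = np.clip(rsstr, 0.0, 100.0)

    pheno = pd.DataFrame({"subspecies": subpop.to_numpy()}, index=panel.index)
    for measure in MEASURES:
        pheno[measure] = values[measure]
    return pheno


def simulate(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Run both simulation stages under a single seed.

    Returns ``(panel, marker_map, pheno, truth)``.
    """
    children = np.random.SeedSequence(config.seed).spawn(2)
    g_rng = np.random.default_rng(children[0])
    p_rng = np.random.default_rng(children[1])
    panel, marker_map, truth = simulate_genotypes(config, rng=g_rng)
    pheno = simulate_phenotypes(panel, truth, config, rng=p_rng)
    return panel, marker_map, pheno, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Sidecar CSV of planted effects (one row per realized QTL)."""
    pd.DataFrame(
        [
            {
                "marker": q.marker,
                "allele_label": q.allele_label,
                "measure": q.measure,
                "effect": q.effect,
                "scope": q.scope,
            }
            for q in truth.qtls
        ],
        columns=["marker", "allele_label", "measure", "effect", "scope"],
    ).to_csv(path, index=False)
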