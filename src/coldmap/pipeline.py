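"""End-to-end orchestration: simulate -> stats -> ld -> assoc -> rge ->
screen, driven by one YAML config and one reproducibility seed.

Every stage writes plain CSV (percent values at 4 decimals so reruns are
byte-stable) and the run ends with a JSON manifest recording parameters,
input hashes and per-stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io
from .association_glm import call_qtls, records_to_frame, scan_markers
from .phenotype_stats import correlation_matrix, subspecies_contrast, summarize
from .popgen_ld import bin_ld_by_distance, pairwise_r2
from .rge_effects import (
    classification_counts,
    effect_asymmetry_summary,
    effects_to_frame,
    qtl_effects,
)
from .screening import (
    count_positive_genotypes,
    flag_strong_negatives,
    phenotype_by_count,
    top_accessions,
)
from .synthetic_data import QTLSpec, SimulationConfig, simulate, write_ground_truth

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "coldmap_out"
    seed: int = 0
    alpha: float = 0.05
    min_class_size: int = 5
    threshold_rge: float = 0.5
    top_k: int = 5
    # either paths to existing inputs ...
    genotypes: str | None = None
    phenotypes: str | None = None
    marker_map: str | None = None
    # ... or a simulate block (dict of SimulationConfig overrides)
    simulate: dict[str, Any] | None = None
    stages: tuple[str, ...] = ("simulate", "stats", "ld", "assoc", "rge", "screen")

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulation_config(config: PipelineConfig) -> SimulationConfig:
    overrides = dict(config.simulate or {})
    qtls = [
        QTLSpec(**q) if isinstance(q, dict) else q
        for q in overrides.pop("qtl_spec", [])
    ]
    overrides.setdefault("seed", config.seed)
    return SimulationConfig(qtl_spec=tuple(qtls), **overrides)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the configured stages in dependency order.

    Returns the manifest (also written to ``<out_dir>/manifest.json``).  A
    stage failure aborts the run with the stage named; outputs of completed
    stages are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "alpha": config.alpha,
        "min_class_size": config.min_class_size,
        "threshold_rge": config.threshold_rge,
        "top_k": config.top_k,
        "stages": {},
    }
    ff = io.FLOAT_FORMAT

    stage = "setup"
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            sim_cfg = _simulation_config(config)
            panel, marker_map, pheno, truth = simulate(sim_cfg)
            io.write_genotypes(panel, out / "genotypes.csv")
            io.write_marker_map(marker_map, out / "marker_map.csv")
            io.write_phenotypes(pheno, out / "phenotypes.csv")
            write_ground_truth(truth, out / "ground_truth.csv")
            manifest["stages"]["simulate"] = {
                "outputs": ["genotypes.csv", "marker_map.csv", "phenotypes.csv",
                            "ground_truth.csv"],
                "n_accessions": sim_cfg.n_accessions,
                "n_markers": sim_cfg.n_markers,
            }
        else:
            stage = "load"
            if not (config.genotypes and config.phenotypes and config.marker_map):
                raise ValueError(
                    "genotypes, phenotypes and marker_map paths are required "
                    "when the simulate stage is disabled"
                )
            panel = io.read_genotypes(config.genotypes)
            pheno = io.read_phenotypes(config.phenotypes)
            marker_map = io.read_marker_map(config.marker_map)
            manifest["inputs"] = {
                p: _sha256(Path(p))
                for p in (config.genotypes, config.phenotypes, config.marker_map)
            }

        if "stats" in config.stages:
            stage = "stats"
            summarize(pheno).to_csv(out / "phenotype_summary.csv", index=False,
                                    float_format=ff)
            contrasts = pd.DataFrame(
                [subspecies_contrast(pheno, m) for m in io.MEASURES]
            ).drop(columns=["groups"])
            contrasts.to_csv(out / "subspecies_contrasts.csv", index=False,
                             float_format=ff)
            for subsp in io.SUBSPECIES:
                r, stars = correlation_matrix(pheno, subsp)
                r.round(4).to_csv(out / f"correlations_{subsp}.csv")
            manifest["stages"]["stats"] = {
                "outputs": ["phenotype_summary.csv", "subspecies_contrasts.csv",
                            "correlations_indica.csv", "correlations_japonica.csv"],
            }

        if "ld" in config.stages:
            stage = "ld"
            records = pairwise_r2(panel, marker_map)
            records.to_csv(out / "ld_pairs.csv", index=False, float_format="%.6f")
            bin_ld_by_distance(records).to_csv(out / "ld_bins.csv", index=False,
                                               float_format="%.6f")
            manifest["stages"]["ld"] = {
                "outputs": ["ld_pairs.csv", "ld_bins.csv"],
                "n_pairs": int(len(records)),
            }

        records = None
        calls = None
        if "assoc" in config.stages:
            stage = "assoc"
            records = scan_markers(
                panel, pheno, min_class_size=config.min_class_size
            )
            records_to_frame(records).to_csv(out / "association_scan.csv",
                                             index=False, float_format="%.6g")
            calls = call_qtls(records, marker_map, alpha=config.alpha)
            calls.to_csv(out / "qtl_calls.csv", index=False, float_format="%.6g")
            manifest["stages"]["assoc"] = {
                "outputs": ["association_scan.csv", "qtl_calls.csv"],
                "n_records": len(records),
                "n_qtl_calls": int(len(calls)),
            }

        effects = None
        if "rge" in config.stages:
            stage = "rge"
            if records is None or calls is None:
                raise ValueError("rge stage requires the assoc stage")
            effects = qtl_effects(records, calls, alpha=config.alpha)
            effects_to_frame(effects).to_csv(out / "genotype_effects.csv",
                                             index=False, float_format="%.6g")
            classification_counts(effects).to_csv(
                out / "genotype_class_counts.csv", index=False
            )
            effect_asymmetry_summary(effects).to_csv(
                out / "effect_asymmetry.csv", index=False, float_format=ff
            )
            manifest["stages"]["rge"] = {
                "outputs": ["genotype_effects.csv", "genotype_class_counts.csv",
                            "effect_asymmetry.csv"],
                "n_effects": len(effects),
            }

        if "screen" in config.stages:
            stage = "screen"
            if effects is None:
                raise ValueError("screen stage requires the rge stage")
            profiles_frames = []
            by_count_frames = []
            top_frames = []
            for subsp in io.SUBSPECIES:
                for measure in io.MEASURES:
                    prof = count_positive_genotypes(
                        panel, pheno, effects, subsp, measure
                    )
                    profiles_frames.append(prof.reset_index())
                    for target in io.SUBSPECIES:
                        pbc = phenotype_by_count(prof, target)
                        pbc.insert(0, "reference_subspecies", subsp)
                        pbc.insert(1, "subspecies", target)
                        pbc.insert(2, "measure", measure)
                        by_count_frames.append(pbc)
                    top = top_accessions(
                        pheno, panel, effects, measure, subsp,
                        k=config.top_k, strong_threshold=config.threshold_rge,
                    )
                    top.insert(0, "measure", measure)
                    top.insert(1, "subspecies", subsp)
                    top_frames.append(top)
            pd.concat(profiles_frames, ignore_index=True).to_csv(
                out / "pyramiding_profiles.csv", index=False, float_format=ff
            )
            pd.concat(by_count_frames, ignore_index=True).to_csv(
                out / "phenotype_by_count.csv", index=False, float_format=ff
            )
            pd.concat(top_frames, ignore_index=True).to_csv(
                out / "top_accessions.csv", index=False, float_format=ff
            )
            flags = flag_strong_negatives(panel, effects, config.threshold_rge)
            flags.to_csv(out / "strong_negative_flags.csv", index=False,
                         float_format=ff)
            manifest["stages"]["screen"] = {
                "outputs": ["pyramiding_profiles.csv", "phenotype_by_count.csv",
                            "top_accessions.csv", "strong_negative_flags.csv"],
                "n_flags": int(len(flags)),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    for stage_info in manifest["stages"].values():
        stage_info["output_sha256"] = {
            name: _sha256(out / name) for name in stage_info["outputs"]
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
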