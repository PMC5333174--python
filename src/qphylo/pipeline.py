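"""End-to-end orchestration: simulate/ingest -> filter -> tree + QC -> date
-> map / predict, with plain-file intermediates and a seed-recording manifest.

Every stage reads and writes ordinary text formats (TSV/VCF/Newick/JSON/CSV)
so each step is independently inspectable and re-entrant: rerunning a stage
from its stored inputs reproduces its outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as qio
from .dating import MU_DEFAULT, date_all_clades
from .filtering import FilterConfig, build_matrix, mask_str_regions
from .geomap import build_surface
from .parsimony import qc_report
from .simulate import (
    SimulationConfig,
    drop_mutations,
    simulate_genealogy,
    simulate_observations,
    simulate_reference,
)

logger = logging.getLogger("qphylo")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    outdir: str = "qphylo_run"
    stages: tuple[str, ...] = ("simulate", "filter", "tree", "date")
    seed: int = 0
    # simulation
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    genealogy_mode: str = "yule"
    # ingestion (used instead of simulation when given)
    observations_tsv: Optional[str] = None
    observations_vcf: Optional[str] = None
    reference_fasta: Optional[str] = None
    # filtering
    filter: FilterConfig = field(default_factory=FilterConfig)
    # tree search
    outgroup: Optional[str] = None
    search_mode: str = "heuristic"
    n_restarts: int = 10
    n_bootstrap: int = 0
    # dating
    mu: float = MU_DEFAULT
    dating_subset: Optional[Sequence[str]] = None
    dating_length: Optional[float] = None
    # mapping
    geo_csv: Optional[str] = None
    map_radius: float = 1500.0
    map_power: float = 3.0
    map_resolution: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        blob = yaml.safe_load(Path(str(path)).read_text()) or {}
        sim = SimulationConfig(**blob.pop("sim", {}))
        filt_kw = blob.pop("filter", {})
        if "whitelist" in filt_kw:
            filt_kw["whitelist"] = frozenset(filt_kw["whitelist"])
        preset = filt_kw.pop("preset", "relaxed")
        filt = (
            FilterConfig.stringent(**filt_kw)
            if preset == "stringent"
            else FilterConfig.relaxed(**filt_kw)
        )
        stages = tuple(blob.pop("stages", ("simulate", "filter", "tree", "date")))
        return cls(sim=sim, filter=filt, stages=stages, **blob)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "artifacts": {},
        "thresholds": {
            "min_depth": config.filter.min_depth,
            "min_base_quality": config.filter.min_base_quality,
            "min_mapping_quality": config.filter.min_mapping_quality,
            "max_minor_fraction": config.filter.max_minor_fraction,
            "entropy_min": config.filter.entropy_min,
            "min_call_rate": config.filter.min_call_rate,
            "mu": config.mu,
        },
    }

    def record(name: str, path: Path):
        manifest["artifacts"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    obs = ref = truth = matrix = annotated = None

    try:
        if "simulate" in config.stages:
            stage = "simulate"
            logger.info("simulating genealogy and observations")
            truth = simulate_genealogy(config.sim, mode=config.genealogy_mode)
            truth = drop_mutations(truth, config.sim)
            ref = simulate_reference(
                config.sim.region_length, config.sim.str_tracts, config.sim.seed
            )
            obs = simulate_observations(truth, ref, config.sim)
            (outdir / "truth.nwk").write_text(
                truth.to_newick(annotate=True) + "\n"
            )
            record("truth_tree", outdir / "truth.nwk")
            qio.write_fasta(ref, outdir / "reference.fasta")
            record("reference", outdir / "reference.fasta")
            qio.write_observations_tsv(obs, outdir / "observations.tsv")
            record("observations", outdir / "observations.tsv")

        if obs is None and (config.observations_tsv or config.observations_vcf):
            stage = "ingest"
            if config.observations_tsv:
                obs = qio.read_observations_tsv(config.observations_tsv)
            else:
                obs = qio.read_observations_vcf(config.observations_vcf)
            if config.reference_fasta:
                ref = qio.read_fasta(config.reference_fasta)

        if "filter" in config.stages:
            stage = "filter"
            if obs is None:
                raise ValueError("no observations: enable simulate or supply input")
            logger.info("building variant matrix")
            matrix = build_matrix(obs, ref, config.filter)
            qio.write_matrix_vcf(matrix, outdir / "matrix.vcf")
            record("matrix_vcf", outdir / "matrix.vcf")
            qio.write_alignment(matrix, outdir / "alignment.txt")
            record("alignment", outdir / "alignment.txt")
            qio.write_sites_table(matrix, outdir / "sites.tsv")
            record("sites", outdir / "sites.tsv")
            if ref is not None:
                qio.write_bed(
                    mask_str_regions(ref, config.filter), outdir / "mask.bed"
                )
                record("mask_bed", outdir / "mask.bed")
            manifest["matrix"] = {
                "n_samples": matrix.n_samples,
                "n_positions": matrix.n_positions,
                "region_length": matrix.region_length,
            }

        if "tree" in config.stages:
            stage = "tree"
            if matrix is None:
                raise ValueError("tree stage needs the filter stage")
            if matrix.is_empty():
                raise ValueError("matrix is empty after filtering")
            logger.info("parsimony search (%s)", config.search_mode)
            annotated, qc = qc_report(
                matrix,
                outgroup=config.outgroup,
                seed=config.seed,
                n_bootstrap=config.n_bootstrap,
                search_kwargs={
                    "mode": config.search_mode,
                    "n_restarts": config.n_restarts,
                },
            )
            (outdir / "tree.nwk").write_text(
                annotated.to_newick(lengths="mutations", annotate=True) + "\n"
            )
            record("tree", outdir / "tree.nwk")
            (outdir / "qc.json").write_text(json.dumps(qc.to_dict(), indent=1))
            record("qc", outdir / "qc.json")
            manifest["qc"] = qc.to_dict()

        if "date" in config.stages:
            stage = "date"
            if annotated is None:
                raise ValueError("date stage needs the tree stage")
            L = config.dating_length or (matrix.region_length if matrix else None)
            table = date_all_clades(
                annotated,
                subset=config.dating_subset,
                mu=config.mu,
                length_bp=L,
            )
            table.to_csv(outdir / "dating.tsv", sep="\t", index=False)
            record("dating", outdir / "dating.tsv")

        if "map" in config.stages:
            stage = "map"
            if not config.geo_csv:
                raise ValueError("map stage needs geo_csv")
            samples = qio.read_geo_csv(config.geo_csv)
            surface = build_surface(
                samples,
                radius=config.map_radius,
                power=config.map_power,
                resolution=config.map_resolution,
            )
            surface.to_frame().to_csv(outdir / "surface.csv", index=False)
            record("surface", outdir / "surface.csv")
            manifest["map"] = surface.meta
    except StageError:
        raise
    except Exception as exc:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise StageError(stage, exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
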