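"""Pipeline orchestration: simulate -> spectra -> fit/select, with manifest.

A single JSON-able configuration drives the stages; every output directory
receives a ``manifest.json`` recording the configuration hash, the seeds,
and a SHA-256 checksum per artifact, so reruns with an identical
configuration are verifiably bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .demography import DemographicModelSpec
from .fitting import FitSettings, model_selection
from .spectra import afs_from_genotypes, read_genotypes_tsv, read_sfs, write_genotypes_tsv, write_sfs
from .synthetic_data import SimulationConfig, simulate_snp_genotypes

__all__ = ["PipelineConfig", "DependencyError", "run_pipeline"]

log = logging.getLogger("divmig")

_STAGE_ORDER = ("simulate", "afs", "fit")


class PipelineError(ValueError):
    """Raised for invalid pipeline configurations."""


class DependencyError(PipelineError):
    """A stage's upstream input is missing; names the offending stage."""


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    ``stages`` toggles pipeline steps (executed in dependency order);
    ``model`` holds the simulation scenario (model_id plus parameters);
    ``fit_models`` lists candidate models for the selection stage.
    External inputs may replace upstream stages (``genotypes_path`` for
    ``afs``, ``sfs_path`` for ``fit``).
    """

    out_dir: str | Path
    stages: list[str] = field(default_factory=lambda: ["simulate", "afs", "fit"])
    seed: int = 0
    model: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)
    fit_models: list[str] = field(default_factory=lambda: ["SI"])
    fit: dict = field(default_factory=dict)
    genotypes_path: str | None = None
    sfs_path: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGE_ORDER)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        for path_attr in ("genotypes_path", "sfs_path"):
            value = getattr(self, path_attr)
            if value is not None and not Path(value).exists():
                raise PipelineError(f"{path_attr} does not exist: {value}")

    def canonical(self) -> str:
        payload = {
            "out_dir": str(self.out_dir),
            "stages": self.stages,
            "seed": self.seed,
            "model": self.model,
            "sim": self.sim,
            "fit_models": self.fit_models,
            "fit": self.fit,
            "genotypes_path": self.genotypes_path,
            "sfs_path": self.sfs_path,
        }
        return json.dumps(payload, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stages = [s for s in _STAGE_ORDER if s in config.stages]

    genotypes = None
    sfs = None

    if "simulate" in stages:
        if not config.model:
            raise DependencyError("simulate: no model specified in config")
        spec = DemographicModelSpec(**config.model)
        sim_cfg = SimulationConfig(model_spec=spec, seed=config.seed, **config.sim)
        log.info("simulate: model=%s sites=%d seed=%d",
                 spec.model_id, sim_cfg.num_snp_sites, config.seed)
        genotypes, truth = simulate_snp_genotypes(sim_cfg)
        geno_path = out_dir / "genotypes.tsv"
        write_genotypes_tsv(genotypes, geno_path)
        truth_path = out_dir / "truth.json"
        truth.to_json(truth_path)
        outputs["genotypes"] = geno_path
        outputs["truth"] = truth_path

    if "afs" in stages:
        if genotypes is None:
            if config.genotypes_path is None:
                raise DependencyError(
                    "afs: requires the simulate stage or a genotypes_path input"
                )
            genotypes = read_genotypes_tsv(config.genotypes_path)
        log.info("afs: %d individuals x %d sites",
                 genotypes.n_individuals, genotypes.n_sites)
        unfolded = afs_from_genotypes(genotypes)
        sfs = unfolded.fold()
        unfolded_path = out_dir / "afs_unfolded.fs"
        folded_path = out_dir / "afs_folded.fs"
        write_sfs(unfolded, unfolded_path)
        write_sfs(sfs, folded_path)
        outputs["afs_unfolded"] = unfolded_path
        outputs["afs_folded"] = folded_path

    if "fit" in stages:
        if sfs is None:
            if config.sfs_path is None:
                raise DependencyError(
                    "fit: requires the afs stage or an sfs_path input"
                )
            sfs = read_sfs(config.sfs_path)
        settings = FitSettings(seed=config.seed, **config.fit)
        log.info("fit: models=%s runs=%d iters=%d",
                 config.fit_models, settings.n_runs, settings.n_iters)
        table = model_selection(sfs, config.fit_models, settings=settings)
        table_path = out_dir / "model_selection.tsv"
        table.to_tsv(table_path)
        outputs["model_selection"] = table_path

    manifest = {
        "tool": "divmig",
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": json.loads(config.canonical()),
        "seed": config.seed,
        "stages": stages,
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                    for name, p in sorted(outputs.items())},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
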