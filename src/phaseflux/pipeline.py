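"""End-to-end pipeline: simulate -> parameterize -> FBA/FVA -> dynamics ->
nutritional-MOMA -> covariation, with a reproducibility manifest.

All stage artifacts are plain text (TSV/CSV/JSON).  The manifest records the
package version, the seed, the configuration and a SHA-256 checksum per file,
so a rerun with the same config and seed is byte-identical for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

from . import __version__
from .covariation import export_gene_lists, run_covariation
from .dynamics import (
    activity_summary,
    classify_all_transitions,
    pathway_activity,
    transition_summary,
    write_transition_reports,
)
from .fba import minimal_media_screen, run_phase_fba, run_phase_fva
from .model import read_model, write_model
from .moma import compare_methods, run_moma_chain
from .parameterization import GrowthCurve, parameterize
from .synth import SyntheticScenario, make_growth_curve, make_toy_model

log = logging.getLogger("phaseflux")

__all__ = ["PipelineConfig", "run_all"]


class ConfigError(Exception):
    pass


@dataclass
class PipelineConfig:
    out_dir: str = "phaseflux_out"
    model_path: str | None = None  # None -> generate the toy model
    model_dialect: str | None = None
    curve_path: str | None = None  # None -> simulate the synthetic curve
    seed: int = 0
    n_amino_acids: int = 6
    activity_tol: float = 1e-9
    change_tol: float = 1e-6
    fva_fraction: float = 1.0
    moma_metric: str = "euclidean"
    covariation_threshold: float = 0.7
    uptake_scaling: str = "normalize"
    target_mass_flux: float = 1.0

    def validate(self) -> "PipelineConfig":
        if self.activity_tol <= 0 or self.change_tol <= 0:
            raise ConfigError("tolerances must be positive")
        if not (-1.0 < self.covariation_threshold < 1.0):
            raise ConfigError("covariation threshold must lie in (-1, 1)")
        if not (0.0 < self.fva_fraction <= 1.0):
            raise ConfigError("FVA optimality fraction must lie in (0, 1]")
        if self.model_path and not Path(self.model_path).exists():
            raise ConfigError(f"model file not found: {self.model_path}")
        if self.curve_path and not Path(self.curve_path).exists():
            raise ConfigError(f"growth-curve file not found: {self.curve_path}")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; return (and write) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def emit(path: Path) -> Path:
        artifacts.append(path)
        return path

    # -- stage 1: inputs ----------------------------------------------------
    log.info("stage simulate: preparing model and growth curve")
    if config.model_path:
        model = read_model(config.model_path, config.model_dialect)
    else:
        model = make_toy_model(config.n_amino_acids, seed=config.seed)
        emit(write_model(model, out / "toy_model.json"))
    if config.curve_path:
        curve = GrowthCurve.read(config.curve_path)
    else:
        scenario = SyntheticScenario(
            n_amino_acids=config.n_amino_acids, seed=config.seed
        )
        curve = make_growth_curve(scenario)
        curve.write(out / "growth_curve.csv")
        emit(out / "growth_curve.csv")
        emit(out / "growth_curve.meta.json")

    # -- stage 2: parameterization ------------------------------------------
    log.info("stage parameterize: %d phases in curve", curve.n_phases)
    params = parameterize(
        curve, scaling=config.uptake_scaling, target_mass_flux=config.target_mass_flux
    )
    params.write_tsv(out / "phase_parameterization.tsv")
    emit(out / "phase_parameterization.tsv")
    log.info("modelled phases: %s", params.phases)

    # -- stage 3: FBA + media screen -----------------------------------------
    log.info("stage fba: %d phases", len(params.phases))
    fba = run_phase_fba(model, params)
    fba.write_tsv(out / "fba_fluxes.tsv")
    emit(out / "fba_fluxes.tsv")
    screen = minimal_media_screen(model, params.amino_acids)
    screen.to_csv(out / "media_screen.tsv", sep="\t", index=False,
                  float_format="%.10g")
    emit(out / "media_screen.tsv")

    # -- stage 4: FVA ---------------------------------------------------------
    log.info("stage fva")
    fva = run_phase_fva(model, params, optimality_fraction=config.fva_fraction,
                        tol=config.activity_tol)
    fva.write_tsv(out / "fva.tsv")
    emit(out / "fva.tsv")

    # -- stage 5: transition dynamics ----------------------------------------
    log.info("stage dynamics")
    reports = classify_all_transitions(
        fba, tol=config.activity_tol, change_tol=config.change_tol
    )
    write_transition_reports(reports, out / "transitions.json")
    emit(out / "transitions.json")
    summary = transition_summary(reports)
    act = activity_summary(fba, tol=config.activity_tol)
    summary.to_csv(out / "transition_summary.tsv", sep="\t")
    emit(out / "transition_summary.tsv")
    pathway_activity(fba, model, tol=config.activity_tol).to_csv(
        out / "pathway_activity.tsv", sep="\t"
    )
    emit(out / "pathway_activity.tsv")

    # -- stage 6: nutritional-MOMA -------------------------------------------
    log.info("stage nmoma (%s metric)", config.moma_metric)
    chain = run_moma_chain(model, params, fba_fluxes=fba, metric=config.moma_metric)
    chain.fluxes.write_tsv(out / "nmoma_fluxes.tsv")
    emit(out / "nmoma_fluxes.tsv")
    chain.distances.rename("distance").to_csv(out / "nmoma_distances.tsv", sep="\t")
    emit(out / "nmoma_distances.tsv")
    comparison = compare_methods(fba, chain.fluxes, model, tol=config.activity_tol)
    comparison["per_phase"].to_csv(out / "method_comparison.tsv", sep="\t")
    emit(out / "method_comparison.tsv")
    comparison["per_subsystem"].to_csv(
        out / "method_comparison_subsystems.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    emit(out / "method_comparison_subsystems.tsv")

    # -- stage 7: covariation --------------------------------------------------
    log.info("stage covary (threshold %s)", config.covariation_threshold)
    cov = run_covariation(fba, model, threshold=config.covariation_threshold)
    cov.correlation.to_csv(out / "correlation.tsv", sep="\t", float_format="%.10g")
    emit(out / "correlation.tsv")
    cov.diffs.to_csv(out / "diff_vectors.tsv", sep="\t", float_format="%.10g")
    emit(out / "diff_vectors.tsv")
    (out / "clusters.json").write_text(
        json.dumps([sorted(c) for c in cov.clusters], indent=1) + "\n"
    )
    emit(out / "clusters.json")
    if cov.gene_sets:
        for p in export_gene_lists(cov.gene_sets, out / "gene_lists"):
            emit(p)

    manifest = {
        "package": "phaseflux",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "modelled_phases": params.phases,
        "mean_active_reactions": act.mean_active,
        "n_clusters": len(cov.clusters),
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in artifacts
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    log.info("wrote %d artifacts to %s", len(artifacts), out)
    return manifest
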