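"""End-to-end orchestration with seeded reproducibility and a run manifest.

The pipeline runs prep → bias correction/background → per-species MaxEnt
fit with cross-validation → projection onto the seven period × SSP
scenarios → habitat metrics, either from real input files (occurrence
CSV, bathymetry grid, a covariate manifest per scenario) or from a
synthetic virtual-species block that generates the whole input set
first. Every stage reads and writes serialised intermediates under the
output directory, so stages can be run separately and compose to the
same bytes as a single run.

All randomness derives from one global seed: each (stage, species) pair
gets a sub-seed from a keyed BLAKE2 hash of the seed and a tag, so
per-species results are stable when the species set changes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import bias as bias_mod
from . import synthetic as syn
from .envstack import (ALL_KEYS, CURRENT, FUTURE_KEYS, EnvStack, ScenarioKey,
                       load_env_stack, select_variables_vif)
from .grids import GridSpec, RasterGrid
from .habitat import (SuitabilityRaster, area_summary, classify_habitat_change,
                      habitat_summary_table, project_scenario, richness_and_delta,
                      suitable_area)
from .maxent import MaxEntModel, build_hinge_basis, cross_validate, fit_maxent
from .occurrences import StudyWindow, clean_occurrences, read_occurrences

logger = logging.getLogger(__name__)

_CSV_FLOAT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offender."""


def stable_seed(global_seed: int, *tags: str) -> int:
    """Deterministic sub-seed below 2**31 for a (seed, tag...) pair."""
    key = f"{global_seed}|" + "|".join(tags)
    digest = hashlib.blake2b(key.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


# ----------------------------------------------------------------------
# Configuration
# ----------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Virtual-species generation block."""

    grid: dict = field(default_factory=lambda: {
        "n_rows": 80, "n_cols": 80,
        "lat_min": 58.0, "lat_max": 76.0, "lon_min": -40.0, "lon_max": 10.0,
    })
    n_covariates: int = 4
    smoothness: float = 6.0
    correlation: float = 0.3  # constant off-diagonal of the target matrix
    n_species: int = 5
    n_presences: int = 400
    optima_range: tuple[float, float] = (-1.5, 1.5)
    niche_sd_range: tuple[float, float] = (0.6, 1.2)
    contamination: dict = field(default_factory=lambda: {
        "pelagic_rate": 0.05, "out_of_box_rate": 0.05,
        "out_of_period_rate": 0.05, "shallow_rate": 0.05,
    })
    effort: dict = field(default_factory=lambda: {
        "n_hotspots": 3, "hotspot_sd_cells": 10.0, "baseline": 0.2,
    })
    # additive covariate offsets of the most severe long-term scenario,
    # scaled down by SSP severity and period factors below
    base_offsets: dict = field(default_factory=lambda: {"cov1": 0.8})
    severity: dict = field(default_factory=lambda: {
        "SSP1-1.9": 0.4, "SSP2-4.5": 0.7, "SSP5-8.5": 1.0,
    })
    period_factor: dict = field(default_factory=lambda: {
        "2050-2060": 0.6, "2090-2100": 1.0,
    })


@dataclass
class InputPaths:
    """Real-data inputs: all paths relative to the config file's directory."""

    occurrences: str
    bathymetry: str
    env_manifest: dict  # scenario label -> {covariate -> path}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "sdm_out"
    window: StudyWindow = field(default_factory=StudyWindow)
    min_records: int = 200
    benthic_tolerance: float = 0.05
    vif_threshold: float = 5.0
    threshold: float = 0.70
    bandwidth_km: float = 100.0
    epsilon_factor: float = 0.01
    n_background: int = 50_000
    multiplier: float = 2.0
    knots_per_covariate: int = 30
    k_folds: int = 3
    synthetic: SyntheticConfig | None = None
    inputs: InputPaths | None = None

    def __post_init__(self) -> None:
        if self.synthetic is None and self.inputs is None:
            raise ValueError(
                "config must provide either a synthetic block or input paths"
            )

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "PipelineConfig":
        doc = dict(doc)
        if "window" in doc:
            doc["window"] = StudyWindow(**doc["window"])
        if doc.get("synthetic") is not None:
            sy = dict(doc["synthetic"])
            for tup in ("optima_range", "niche_sd_range"):
                if tup in sy:
                    sy[tup] = tuple(sy[tup])
            doc["synthetic"] = SyntheticConfig(**sy)
        if doc.get("inputs") is not None:
            doc["inputs"] = InputPaths(**doc["inputs"])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_canonical_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(type(o).__name__)
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=enc)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_CSV_FLOAT)


# ----------------------------------------------------------------------
# Stages
# ----------------------------------------------------------------------

def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"{stage}: missing upstream artefact {path} "
            f"(run the {produced_by!r} stage first)"
        )
    return path


def stage_simulate(config: PipelineConfig) -> dict:
    """Generate a complete synthetic input set runnable by ``prep``."""
    if config.synthetic is None:
        raise PipelineError("simulate: config has no synthetic block")
    sy = config.synthetic
    out = Path(config.outdir) / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    grid = GridSpec(**sy.grid)
    n = sy.n_covariates
    corr = np.full((n, n), float(sy.correlation))
    np.fill_diagonal(corr, 1.0)
    stack, bathy = syn.generate_env_stack(
        grid, n, target_correlation=corr, smoothness=sy.smoothness,
        seed=stable_seed(config.seed, "env"),
    )
    effort = syn.generate_effort_bias(
        grid, seed=stable_seed(config.seed, "effort"), **sy.effort,
    )
    rng = np.random.default_rng(stable_seed(config.seed, "species"))
    species = []
    for i in range(sy.n_species):
        optima = {c: float(rng.uniform(*sy.optima_range)) for c in stack.names}
        tol = {c: float(rng.uniform(*sy.niche_sd_range)) for c in stack.names}
        species.append(syn.VirtualSpeciesSpec(f"species_{i + 1:02d}", optima, tol))
    contamination = syn.ContaminationSpec(**sy.contamination)
    occ_parts, truth_parts = [], []
    for sp in species:
        occ, truth = syn.sample_occurrences(
            sp, stack, bathy, effort, n=sy.n_presences,
            contamination=contamination,
            year_range=(config.window.year_min, config.window.year_max),
            window=config.window,
            seed=stable_seed(config.seed, "occ", sp.species_id),
        )
        occ["record_id"] = [f"{sp.species_id}:{i}" for i in occ["record_id"]]
        truth["record_id"] = occ["record_id"].to_numpy()
        occ_parts.append(occ)
        truth_parts.append(truth)
    occurrences = pd.concat(occ_parts, ignore_index=True)
    truth = pd.concat(truth_parts, ignore_index=True)
    _write_csv(occurrences, out / "occurrences.csv")
    _write_csv(truth, out / "truth.csv")
    bathy.write_ascii(out / "bathymetry.asc")

    manifest: dict[str, dict[str, str]] = {}
    truth_area_rows = []
    env_dir = out / "env"
    env_dir.mkdir(exist_ok=True)
    for key in ALL_KEYS:
        if key.is_current:
            scen_stack, truth_df = stack, None
        else:
            offsets = {
                c: v * sy.severity[key.ssp] * sy.period_factor[key.period]
                for c, v in sy.base_offsets.items()
            }
            scen_stack, truth_df = syn.apply_scenario_shift(
                stack, syn.ScenarioShift(offsets=offsets),
                species=species, threshold=config.threshold, scenario=key,
            )
        manifest[key.label] = {}
        for cov in scen_stack.names:
            path = env_dir / f"{key.label}__{cov}.asc"
            scen_stack[cov].write_ascii(path)
            manifest[key.label][cov] = str(path.relative_to(out))
        if truth_df is None:
            for sp in species:
                truth_area_rows.append({
                    "species": sp.species_id, "scenario": key.label,
                    "true_area_km2": syn.true_suitable_area_km2(
                        sp, stack, config.threshold),
                })
        else:
            for _, r in truth_df.iterrows():
                truth_area_rows.append({
                    "species": r["species"], "scenario": key.label,
                    "true_area_km2": r["area_after_km2"],
                })
    (out / "env_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    _write_csv(pd.DataFrame(truth_area_rows), out / "species_truth_areas.csv")
    niche_rows = [
        {"species": sp.species_id,
         **{f"mu_{c}": sp.optima[c] for c in sorted(sp.optima)},
         **{f"sigma_{c}": sp.tolerances[c] for c in sorted(sp.tolerances)}}
        for sp in species
    ]
    _write_csv(pd.DataFrame(niche_rows), out / "species_niches.csv")
    logger.info("simulate: wrote %d records for %d species", len(occurrences),
                len(species))
    return {"n_records": len(occurrences), "n_species": len(species)}


def _input_paths(config: PipelineConfig) -> tuple[Path, Path, dict]:
    """Resolve occurrence/bathymetry/env paths for prep and later stages."""
    if config.inputs is not None:
        manifest = config.inputs.env_manifest
        return Path(config.inputs.occurrences), Path(config.inputs.bathymetry), {
            label: {cov: Path(p) for cov, p in entry.items()}
            for label, entry in manifest.items()
        }
    base = Path(config.outdir) / "inputs"
    _require(base / "occurrences.csv", "prep", "simulate")
    manifest_doc = yaml.safe_load(
        _require(base / "env_manifest.yaml", "prep", "simulate").read_text())
    manifest = {
        label: {cov: base / p for cov, p in entry.items()}
        for label, entry in manifest_doc.items()
    }
    return base / "occurrences.csv", base / "bathymetry.asc", manifest


def _load_scenario(config: PipelineConfig, key: ScenarioKey) -> EnvStack:
    _, _, manifest = _input_paths(config)
    if key.label not in manifest:
        raise PipelineError(f"no environmental layers for scenario {key.label}")
    return load_env_stack(
        {cov: str(p) for cov, p in sorted(manifest[key.label].items())}, key)


def stage_prep(config: PipelineConfig) -> dict:
    """Read, filter and audit occurrence records."""
    occ_path, bathy_path, _ = _input_paths(config)
    records = read_occurrences(occ_path)
    bathy = RasterGrid.read_ascii(bathy_path)
    result = clean_occurrences(
        records, bathy, window=config.window,
        tolerance=config.benthic_tolerance, min_records=config.min_records,
    )
    if not result.species_table["included"].any():
        raise PipelineError(
            "prep: filter_min_records left no species with at least "
            f"{config.min_records} records"
        )
    out = Path(config.outdir) / "prep"
    _write_csv(result.records, out / "cleaned.csv")
    _write_csv(result.species_table, out / "species_table.csv")
    _write_csv(result.audit, out / "audit.csv")
    counts = result.audit["rule_failed"].value_counts().to_dict()
    return {
        "n_in": len(records),
        "n_out": len(result.records),
        "n_species_included": int(result.species_table["included"].sum()),
        "removed_by_rule": {k: int(v) for k, v in sorted(counts.items())},
    }


def stage_background(config: PipelineConfig) -> dict:
    """VIF screening, pooled-effort KDE, and background sampling."""
    out = Path(config.outdir)
    cleaned = pd.read_csv(_require(out / "prep" / "cleaned.csv",
                                   "background", "prep"))
    stack = _load_scenario(config, CURRENT)
    from .envstack import extract_covariates
    table = extract_covariates(cleaned["lon"].to_numpy(),
                               cleaned["lat"].to_numpy(), stack)
    vif = select_variables_vif(table, threshold=config.vif_threshold)
    surface_raw = bias_mod.build_effort_surface(
        cleaned["lon"].to_numpy(), cleaned["lat"].to_numpy(), stack.grid,
        bias_mod.KdeConfig(bandwidth_km=config.bandwidth_km,
                           epsilon_factor=config.epsilon_factor),
    )
    surface = bias_mod.normalize_with_floor(surface_raw, config.epsilon_factor)
    background = bias_mod.sample_background(
        surface, n=config.n_background,
        seed=stable_seed(config.seed, "background"),
    )
    bg_dir = out / "background"
    bg_dir.mkdir(parents=True, exist_ok=True)
    surface.raster.write_ascii(bg_dir / "effort.asc")
    _write_csv(background[["lon", "lat"]], bg_dir / "background.csv")
    (bg_dir / "vif.json").write_text(json.dumps({
        "retained": vif.retained,
        "dropped": [[name, v] for name, v in vif.dropped],
        "vif": {k: (None if not np.isfinite(v) else float(v))
                for k, v in vif.vif.items()},
        "threshold": config.vif_threshold,
    }, sort_keys=True, indent=1))
    return {"retained_covariates": vif.retained,
            "n_background": len(background)}


def _retained_covariates(config: PipelineConfig) -> list[str]:
    path = _require(Path(config.outdir) / "background" / "vif.json",
                    "fit", "background")
    return list(json.loads(path.read_text())["retained"])


def stage_fit(config: PipelineConfig) -> dict:
    """Per-species hinge-MaxEnt fit with k-fold cross-validated AUC."""
    out = Path(config.outdir)
    cleaned = pd.read_csv(_require(out / "prep" / "cleaned.csv", "fit", "prep"))
    background = pd.read_csv(_require(out / "background" / "background.csv",
                                      "fit", "background"))
    retained = _retained_covariates(config)
    stack = _load_scenario(config, CURRENT)
    stack = EnvStack({c: stack[c] for c in retained}, CURRENT)
    model_dir = out / "fit" / "models"
    model_dir.mkdir(parents=True, exist_ok=True)
    cv_rows = []
    for species, group in cleaned.groupby("species", sort=True):
        try:
            training = bias_mod.assemble_training(
                group["lon"].to_numpy(), group["lat"].to_numpy(),
                background, stack)
            basis = build_hinge_basis(training.features,
                                      config.knots_per_covariate)
            cv = cross_validate(
                training, basis=basis, multiplier=config.multiplier,
                k=config.k_folds,
                seed=stable_seed(config.seed, "cv", str(species)),
            )
            model = fit_maxent(training, basis=basis,
                               multiplier=config.multiplier)
        except Exception as exc:
            raise PipelineError(f"fit: species {species!r} failed: {exc}") from exc
        model.to_json(model_dir / f"{_slug(str(species))}.json")
        cv_rows.append({
            "species": species, "mean_auc": cv.mean_auc,
            **{f"fold{i + 1}_auc": a for i, a in enumerate(cv.fold_auc)},
        })
    cv_df = pd.DataFrame(cv_rows)
    _write_csv(cv_df, out / "fit" / "cv.csv")
    return {"n_models": len(cv_rows),
            "mean_cv_auc": float(cv_df["mean_auc"].mean())}


def stage_project(config: PipelineConfig) -> dict:
    """Project every fitted model onto all 7 scenario stacks."""
    out = Path(config.outdir)
    model_dir = _require(out / "fit" / "models", "project", "fit")
    model_paths = sorted(model_dir.glob("*.json"))
    if not model_paths:
        raise PipelineError("project: no fitted models found; run 'fit' first")
    proj_dir = out / "project"
    proj_dir.mkdir(parents=True, exist_ok=True)
    n = 0
    for key in ALL_KEYS:
        stack = _load_scenario(config, key)
        for mp in model_paths:
            model = MaxEntModel.from_json(mp)
            sr = project_scenario(model, stack, species=mp.stem)
            sr.raster.write_ascii(proj_dir / f"{mp.stem}__{key.label}.asc")
            n += 1
    return {"n_rasters": n}


def stage_metrics(config: PipelineConfig) -> dict:
    """Thresholded areas, summaries, loser flags, richness and deltas."""
    out = Path(config.outdir)
    proj_dir = _require(out / "project", "metrics", "project")
    rasters: dict[str, dict[ScenarioKey, SuitabilityRaster]] = {}
    for path in sorted(proj_dir.glob("*.asc")):
        species, _, label = path.stem.rpartition("__")
        key = ScenarioKey.from_label(label)
        rasters.setdefault(species, {})[key] = SuitabilityRaster(
            RasterGrid.read_ascii(path), species, key)
    if not rasters:
        raise PipelineError("metrics: no projections found; run 'project' first")
    met_dir = out / "metrics"
    met_dir.mkdir(parents=True, exist_ok=True)
    areas = {
        sp: {key: suitable_area(sr, config.threshold)
             for key, sr in by_scen.items()}
        for sp, by_scen in rasters.items()
    }
    _write_csv(habitat_summary_table(areas), met_dir / "habitat_areas.csv")
    summary_rows = []
    for key in ALL_KEYS:
        stats = area_summary([areas[sp][key] for sp in areas])
        summary_rows.append({"scenario": key.label, **stats})
    _write_csv(pd.DataFrame(summary_rows), met_dir / "area_summary.csv")
    loser_rows = []
    for sp in sorted(areas):
        flags = classify_habitat_change(areas[sp])
        loser_rows.append({"species": sp, **flags})
    losers = pd.DataFrame(loser_rows)
    _write_csv(losers, met_dir / "losers.csv")
    present = [rasters[sp][CURRENT] for sp in sorted(rasters)]
    for key in FUTURE_KEYS:
        future = [rasters[sp][key] for sp in sorted(rasters)]
        rp, rf, delta = richness_and_delta(present, future, config.threshold)
        rf.write_ascii(met_dir / f"richness_{key.label}.asc")
        delta.write_ascii(met_dir / f"delta_{key.label}.asc")
    rp, _, _ = richness_and_delta(present, present, config.threshold)
    rp.write_ascii(met_dir / "richness_current.asc")
    return {
        "n_species": len(areas),
        "consistent_losers": int(losers["consistent_loser"].sum()),
        "majority_losers": int(losers["majority_loser"].sum()),
        "mean_current_area_km2": float(np.mean(
            [areas[sp][CURRENT] for sp in areas])),
    }


STAGES = {
    "simulate": stage_simulate,
    "prep": stage_prep,
    "background": stage_background,
    "fit": stage_fit,
    "project": stage_project,
    "metrics": stage_metrics,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order and write ``manifest.json``.

    Returns the manifest as a dict. Reruns with an identical config and
    seed reproduce identical outputs (timestamps aside).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "stages": {},
        "timestamps": {"started": time.strftime("%Y-%m-%dT%H:%M:%S")},
    }
    order = ["simulate", "prep", "background", "fit", "project", "metrics"]
    if config.synthetic is None:
        order.remove("simulate")
    stage_dirs = {"simulate": "inputs", "prep": "prep",
                  "background": "background", "fit": "fit",
                  "project": "project", "metrics": "metrics"}
    for name in order:
        logger.info("pipeline: running stage %s", name)
        try:
            info = STAGES[name](config)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"{name}: {exc}") from exc
        stage_dir = out / stage_dirs[name]
        files = sorted(str(p.relative_to(out))
                       for p in stage_dir.rglob("*") if p.is_file())
        manifest["stages"][name] = {"info": info, "files": files}
    if "fit" in manifest["stages"]:
        cv = pd.read_csv(out / "fit" / "cv.csv")
        manifest["per_species_mean_auc"] = {
            str(r["species"]): float(r["mean_auc"]) for _, r in cv.iterrows()
        }
    if "prep" in manifest["stages"]:
        manifest["filter_removed_by_rule"] = (
            manifest["stages"]["prep"]["info"]["removed_by_rule"])
    manifest["timestamps"]["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
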