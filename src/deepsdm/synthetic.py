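"""Virtual-species test-bed: correlated environmental fields, Gaussian
niches, biased occurrence sampling, and scenario shifts with known truth.

The generator builds smooth correlated random fields standing in for
gridded ocean covariates, a smooth positive bathymetry, and virtual
species whose true habitat suitability is a product-Gaussian function of
the covariates. Occurrences are drawn with sampling effort bias and can
be contaminated with records that each violate exactly one cleaning rule
(non-benthic depth, outside the study box, outside the study period, or
shallower than the deep-sea cutoff), together with a truth table saying
which records are clean. Scenario shifts perturb covariates additively
and/or multiplicatively, with the true change in suitable habitat area
computed by direct evaluation on both stacks, so projection code can be
checked against an analytic ground truth.

All randomness flows through a single integer seed; identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .envstack import CURRENT, EnvStack, ScenarioKey
from .grids import GridSpec, RasterGrid, cell_areas
from .occurrences import StudyWindow


@dataclass(frozen=True)
class VirtualSpeciesSpec:
    """A virtual species with a known product-Gaussian niche.

    Suitability is ``s(x) = exp(-sum_j (x_j - mu_j)^2 / (2 sigma_j^2))``
    over the covariates named in ``optima``; it equals 1 exactly where
    every covariate sits at its optimum.
    """

    species_id: str
    optima: Mapping[str, float]
    tolerances: Mapping[str, float]
    prevalence_target: float = 0.1

    def __post_init__(self) -> None:
        if set(self.optima) != set(self.tolerances):
            raise ValueError("optima and tolerances must name the same covariates")
        if any(s <= 0 for s in self.tolerances.values()):
            raise ValueError("niche tolerances must be positive")
        if not (0.0 < self.prevalence_target < 1.0):
            raise ValueError("prevalence_target must lie in (0, 1)")


@dataclass(frozen=True)
class ContaminationSpec:
    """Per-rule contamination rates for sampled occurrence records.

    Each record is assigned at most one violated rule; the rates are the
    marginal probabilities of each rule and must sum to less than 1.
    """

    pelagic_rate: float = 0.0
    out_of_box_rate: float = 0.0
    out_of_period_rate: float = 0.0
    shallow_rate: float = 0.0

    def __post_init__(self) -> None:
        rates = (self.pelagic_rate, self.out_of_box_rate,
                 self.out_of_period_rate, self.shallow_rate)
        if any(not (0.0 <= r < 1.0) for r in rates):
            raise ValueError("contamination rates must lie in [0, 1)")
        if sum(rates) >= 1.0:
            raise ValueError("contamination rates must sum to less than 1")


@dataclass(frozen=True)
class ScenarioShift:
    """Per-covariate additive offsets and scale factors.

    ``new = value * scale + offset``; omitted covariates are untouched,
    so an empty shift reproduces the input stack exactly.
    """

    offsets: Mapping[str, float] = field(default_factory=dict)
    scales: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = list(self.offsets.values()) + list(self.scales.values())
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("shift offsets and scales must be finite")


# ----------------------------------------------------------------------
# Environmental fields
# ----------------------------------------------------------------------

def _smooth_standard_field(rng: np.random.Generator, shape: tuple[int, int],
                           smoothness: float) -> np.ndarray:
    """Low-pass-filtered white noise, standardised to mean 0, sd 1."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=smoothness,
                                mode="reflect")
    return (z - z.mean()) / z.std()


def generate_env_stack(grid: GridSpec, n_covariates: int,
                       target_correlation: np.ndarray | None = None,
                       smoothness: float = 5.0, seed: int = 0,
                       covariate_names: Sequence[str] | None = None,
                       bathy_mean: float = 1200.0, bathy_sd: float = 500.0,
                       bathy_min: float = 250.0,
                       ) -> tuple[EnvStack, RasterGrid]:
    """Generate smooth correlated covariate fields plus a bathymetry grid.

    Fields are built by Gaussian-smoothing white noise with the given
    smoothness length (in cells), standardising, then mixing through the
    Cholesky factor of ``target_correlation`` so the cross-covariate
    correlation approximates the target. Bathymetry is an independent
    smooth positive field (metres below surface).
    """
    if smoothness < 1:
        raise ValueError("smoothness must be at least 1 cell")
    if target_correlation is None:
        target_correlation = np.eye(n_covariates)
    C = np.asarray(target_correlation, dtype=float)
    if C.shape != (n_covariates, n_covariates):
        raise ValueError("correlation matrix shape does not match n_covariates")
    if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
        raise ValueError("target correlation must be symmetric with unit diagonal")
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "target correlation matrix is not positive definite"
        ) from exc
    if covariate_names is None:
        covariate_names = [f"cov{j + 1}" for j in range(n_covariates)]
    rng = np.random.default_rng(seed)
    raw = np.stack([
        _smooth_standard_field(rng, grid.shape, smoothness)
        for _ in range(n_covariates)
    ])
    mixed = np.tensordot(L, raw, axes=1)
    # per-field standardisation is affine and leaves correlations intact
    mixed = (mixed - mixed.mean(axis=(1, 2), keepdims=True)) \
        / mixed.std(axis=(1, 2), keepdims=True)
    layers = {
        name: RasterGrid(grid, mixed[j])
        for j, name in enumerate(covariate_names)
    }
    bathy_field = _smooth_standard_field(rng, grid.shape, smoothness)
    bathy = np.maximum(bathy_mean + bathy_sd * bathy_field, bathy_min)
    return EnvStack(layers, CURRENT), RasterGrid(grid, bathy)


def generate_effort_bias(grid: GridSpec, seed: int = 0, n_hotspots: int = 3,
                         hotspot_sd_cells: float = 10.0,
                         baseline: float = 0.2) -> RasterGrid:
    """A plausible sampling-effort field: Gaussian hotspots on a baseline.

    Real survey effort clusters around ports and repeat transects; its
    true spatial form is unknown, so the shape is configurable and this
    default keeps every cell reachable (strictly positive bias).
    """
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols),
                         indexing="ij")
    bias = np.full(grid.shape, float(baseline))
    for _ in range(n_hotspots):
        r0 = rng.uniform(0, grid.n_rows)
        c0 = rng.uniform(0, grid.n_cols)
        bias += np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2)
                       / (2 * hotspot_sd_cells**2))
    return RasterGrid(grid, bias)


# ----------------------------------------------------------------------
# True suitability and occurrence sampling
# ----------------------------------------------------------------------

def true_suitability(species: VirtualSpeciesSpec, stack: EnvStack) -> RasterGrid:
    """Evaluate the species' Gaussian niche on every cell of the stack."""
    missing = [c for c in species.optima if c not in stack]
    if missing:
        raise KeyError(
            f"stack lacks covariates required by {species.species_id}: "
            f"{', '.join(missing)}"
        )
    log_s = np.zeros(stack.grid.shape)
    for cov, mu in species.optima.items():
        sigma = species.tolerances[cov]
        log_s -= (stack[cov].values - mu) ** 2 / (2.0 * sigma**2)
    return RasterGrid(stack.grid, np.exp(log_s))


_RULES = ("pelagic", "out_of_box", "out_of_period", "shallow")


def sample_occurrences(species: VirtualSpeciesSpec, stack: EnvStack,
                       bathymetry: RasterGrid, effort_bias: RasterGrid,
                       n: int,
                       contamination: ContaminationSpec | None = None,
                       year_range: tuple[int, int] = (2000, 2020),
                       window: StudyWindow = StudyWindow(),
                       mismatch_magnitude: tuple[float, float] = (0.20, 0.50),
                       seed: int = 0,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a biased, optionally contaminated occurrence sample.

    Presence cells are drawn with probability proportional to
    ``suitability * effort_bias``, then jittered uniformly within the
    cell. Clean records carry a depth within ±4 % of the local
    bathymetry and a year uniform in ``year_range``. Contaminated
    records violate exactly their designated rule: pelagic records
    mismatch bathymetry by at least 20 % (default), out-of-box records
    fall south of the study window, out-of-period years predate 2000,
    and shallow records have depth well below the 200 m cutoff.

    Returns ``(occurrences, truth)``: a Darwin-Core-like table and a
    sidecar with ``record_id, clean_flag, violated_rule``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    contamination = contamination or ContaminationSpec()
    s = true_suitability(species, stack).values
    w = s * effort_bias.values
    w = np.where(np.isfinite(w), w, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("suitability × effort bias is identically zero")
    rng = np.random.default_rng(seed)
    flat = rng.choice(w.size, size=n, p=(w / total).ravel())
    rows, cols = np.unravel_index(flat, w.shape)
    g = stack.grid
    lat = g.lat_max - (rows + rng.random(n)) * g.dlat
    lon = g.lon_min + (cols + rng.random(n)) * g.dlon
    bathy = bathymetry.values[rows, cols]
    depth = bathy * (1.0 + rng.uniform(-0.04, 0.04, size=n))
    year = rng.integers(year_range[0], year_range[1] + 1, size=n).astype(float)

    rates = np.array([contamination.pelagic_rate, contamination.out_of_box_rate,
                      contamination.out_of_period_rate, contamination.shallow_rate])
    u = rng.random(n)
    edges = np.concatenate([[0.0], np.cumsum(rates)])
    rule_idx = np.full(n, -1)
    for k in range(4):
        rule_idx[(u >= edges[k]) & (u < edges[k + 1])] = k

    lo, hi = mismatch_magnitude
    mag = rng.uniform(lo, hi, size=n)
    sel = rule_idx == 0  # pelagic: depth off the seafloor by >= `lo`
    shallower = bathy * (1.0 - mag) > window.min_depth
    depth[sel & shallower] = (bathy * (1.0 - mag))[sel & shallower]
    depth[sel & ~shallower] = (bathy * (1.0 + mag))[sel & ~shallower]
    sel = rule_idx == 1  # out of box: south of the study window
    lat[sel] = window.lat_min - rng.uniform(1.0, 10.0, size=n)[sel]
    sel = rule_idx == 2  # out of period: strictly before the window
    year[sel] = rng.integers(1950, year_range[0], size=n)[sel].astype(float)
    sel = rule_idx == 3  # shallow: clearly above the deep-sea cutoff
    depth[sel] = rng.uniform(10.0, window.min_depth - 10.0, size=n)[sel]

    record_id = np.arange(n)
    occurrences = pd.DataFrame({
        "record_id": record_id,
        "scientificName": species.species_id,
        "decimalLatitude": lat,
        "decimalLongitude": lon,
        "depth": depth,
        "year": year.astype(int),
    })
    truth = pd.DataFrame({
        "record_id": record_id,
        "clean_flag": rule_idx == -1,
        "violated_rule": [("" if k < 0 else _RULES[k]) for k in rule_idx],
    })
    return occurrences, truth


# ----------------------------------------------------------------------
# Scenario shifts with analytic truth
# ----------------------------------------------------------------------

def true_suitable_area_km2(species: VirtualSpeciesSpec, stack: EnvStack,
                           threshold: float = 0.70) -> float:
    """Spherical area (km²) of cells whose true suitability >= threshold."""
    s = true_suitability(species, stack).values
    area = cell_areas(stack.grid)[:, None]
    valid = stack.valid_mask
    return float(np.sum(area * ((s >= threshold) & valid)))


def apply_scenario_shift(stack: EnvStack, shift: ScenarioShift,
                         species: Sequence[VirtualSpeciesSpec] = (),
                         threshold: float = 0.70,
                         scenario: ScenarioKey | None = None,
                         ) -> tuple[EnvStack, pd.DataFrame]:
    """Apply a covariate shift and report the true habitat-area change.

    Returns the shifted stack (aligned with the input) and a per-species
    truth table with suitable area before/after, both computed by direct
    evaluation of the known niche on every cell.
    """
    unknown = [c for c in set(shift.offsets) | set(shift.scales)
               if c not in stack]
    if unknown:
        raise KeyError(f"shift names covariates absent from the stack: "
                       f"{', '.join(sorted(unknown))}")
    layers = {}
    for name, layer in stack.layers.items():
        scale = shift.scales.get(name, 1.0)
        offset = shift.offsets.get(name, 0.0)
        layers[name] = RasterGrid(layer.grid, layer.values * scale + offset)
    shifted = EnvStack(layers, scenario or stack.scenario)
    records = []
    for sp in species:
        before = true_suitable_area_km2(sp, stack, threshold)
        after = true_suitable_area_km2(sp, shifted, threshold)
        records.append({
            "species": sp.species_id,
            "area_before_km2": before,
            "area_after_km2": after,
            "delta_km2": after - before,
            "relative_change": (after - before) / before if before > 0 else np.nan,
        })
    truth = pd.DataFrame(
        records,
        columns=["species", "area_before_km2", "area_after_km2",
                 "delta_km2", "relative_change"],
    )
    return shifted, truth
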