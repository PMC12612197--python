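"""Scenario projection and habitat analytics.

Fitted models are projected cellwise onto scenario stacks (with
covariate clamping to the training range by default), suitability is
thresholded (>= 0.70 by default) and converted to suitable habitat area
using spherical cell areas, and per-species areas across the seven
scenarios feed richness maps, richness deltas, and habitat-loss
classifications (losing in all six future scenarios, or in at least
five of six; equal area does not count as loss).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .envstack import CURRENT, FUTURE_KEYS, EnvStack, ScenarioKey
from .grids import GridSpec, RasterGrid, cell_areas
from .maxent import MaxEntModel

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.70


@dataclass
class SuitabilityRaster:
    """Per-cell suitability scores for one species under one scenario."""

    raster: RasterGrid
    species: str
    scenario: ScenarioKey

    @property
    def grid(self) -> GridSpec:
        return self.raster.grid


def project_scenario(model: MaxEntModel, stack: EnvStack,
                     species: str = "", clamp: bool = True,
                     transform: str = "cloglog") -> SuitabilityRaster:
    """Score every valid cell of a scenario stack.

    With clamping (default), covariates outside the training [min, max]
    are moved to the nearest bound before hinge evaluation, so
    projections never extrapolate; turning it off is logged. Cells
    masked in any covariate are masked in the output.
    """
    missing = [c for c in model.basis.covariates if c not in stack]
    if missing:
        raise KeyError(
            f"stack lacks model covariates: {', '.join(missing)}"
        )
    if not clamp:
        logger.warning("project_scenario: clamping disabled; hinge features "
                       "may extrapolate beyond the training range")
    table = stack.to_frame()
    scores = model.predict(table[model.basis.covariates], clamp=clamp,
                           transform=transform)
    out = np.full(stack.grid.shape, np.nan).ravel()
    out[table.index.to_numpy()] = scores
    return SuitabilityRaster(
        raster=RasterGrid(stack.grid, out.reshape(stack.grid.shape)),
        species=species, scenario=stack.scenario,
    )


def suitable_area(raster: SuitabilityRaster,
                  threshold: float = DEFAULT_THRESHOLD,
                  inclusive: bool = True) -> float:
    """Total spherical area (km²) of cells at or above the threshold."""
    s = raster.raster.values
    valid = raster.raster.mask
    hit = (s >= threshold) if inclusive else (s > threshold)
    area = cell_areas(raster.grid)[:, None]
    return float(np.sum(area * (hit & valid)))


def area_summary(areas: Sequence[float]) -> dict[str, float]:
    """Mean, min, max and quartiles of per-species areas.

    Quartiles use linear interpolation between order statistics.
    """
    a = np.asarray(list(areas), dtype=float)
    if a.size == 0:
        raise ValueError("area summary needs at least one species")
    return {
        "mean": float(a.mean()),
        "min": float(a.min()),
        "lower_quartile": float(np.percentile(a, 25)),
        "upper_quartile": float(np.percentile(a, 75)),
        "max": float(a.max()),
    }


def classify_habitat_change(areas: Mapping[ScenarioKey, float]) -> dict[str, bool]:
    """Habitat-loss flags from areas across the 7 scenarios.

    ``consistent_loser``: the future area is strictly below the current
    area in all 6 future scenarios; ``majority_loser``: in at least 5 of
    6. Equality is not a loss. Any missing scenario is rejected.
    """
    missing = [k.label for k in (CURRENT,) + FUTURE_KEYS if k not in areas]
    if missing:
        raise ValueError(f"missing scenarios: {', '.join(missing)}")
    current = areas[CURRENT]
    n_losing = sum(1 for k in FUTURE_KEYS if areas[k] < current)
    return {
        "consistent_loser": n_losing == 6,
        "majority_loser": n_losing >= 5,
        "n_losing_scenarios": n_losing,
    }


def habitat_summary_table(areas: Mapping[str, Mapping[ScenarioKey, float]]
                          ) -> pd.DataFrame:
    """Long-form per-species × per-scenario area table."""
    rows = [
        {"species": sp, "scenario": key.label, "area_km2": a}
        for sp, by_scenario in areas.items()
        for key, a in by_scenario.items()
    ]
    return pd.DataFrame(rows, columns=["species", "scenario", "area_km2"])


def richness_map(rasters: Sequence[SuitabilityRaster],
                 threshold: float = DEFAULT_THRESHOLD) -> RasterGrid:
    """Per-cell count of species with suitability >= threshold.

    Cells masked for every species are masked in the output; a cell
    masked for one species simply contributes no count for it.
    """
    if not rasters:
        raise ValueError("richness needs at least one raster")
    grid = rasters[0].grid
    counts = np.zeros(grid.shape)
    any_valid = np.zeros(grid.shape, dtype=bool)
    for r in rasters:
        if r.grid != grid:
            raise ValueError(f"raster for {r.species!r} is misaligned")
        valid = r.raster.mask
        counts += (r.raster.values >= threshold) & valid
        any_valid |= valid
    return RasterGrid(grid, np.where(any_valid, counts, np.nan))


def richness_and_delta(present: Sequence[SuitabilityRaster],
                       future: Sequence[SuitabilityRaster],
                       threshold: float = DEFAULT_THRESHOLD,
                       ) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Richness under both scenarios plus the per-cell difference.

    Returns ``(richness_present, richness_future, delta)`` with
    ``delta = future - present`` wherever both are valid.
    """
    rp = richness_map(present, threshold)
    rf = richness_map(future, threshold)
    if rp.grid != rf.grid:
        raise ValueError("present and future rasters are misaligned")
    delta = rf.values - rp.values
    return rp, rf, RasterGrid(rp.grid, delta)
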