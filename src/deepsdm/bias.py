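"""Target-group sampling-bias correction.

Sampling effort is estimated by a quartic (biweight) kernel density of
the pooled presence points of all modelled species — the target group —
on a geographic grid, using great-circle distances and a 100 km
bandwidth by default. The raw density is floored (never-sampled cells
get a negligible positive value so they remain reachable) and normalised
into a probability surface, from which background points are drawn
multinomially with replacement and jittered uniformly within their cell.
The same background set is shared by every species' model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .envstack import EnvStack, extract_covariates
from .grids import GridSpec, RasterGrid, great_circle_km

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KdeConfig:
    """Effort-surface settings: quartic kernel, bandwidth in km."""

    bandwidth_km: float = 100.0
    epsilon_factor: float = 0.01  # floor = min positive cell × this

    def __post_init__(self) -> None:
        if self.bandwidth_km <= 0:
            raise ValueError("bandwidth must be positive")


def quartic_kernel(distance_km, bandwidth_km: float) -> np.ndarray:
    """Quartic (biweight) kernel density contribution in km⁻².

    ``K(d) = 3/(pi h^2) (1 - (d/h)^2)^2`` for d < h, zero beyond the
    bandwidth; each point's kernel integrates to 1 over the plane.
    """
    if bandwidth_km <= 0:
        raise ValueError("bandwidth must be positive")
    d = np.asarray(distance_km, dtype=float)
    u = d / bandwidth_km
    k = (3.0 / (np.pi * bandwidth_km**2)) * (1.0 - u**2) ** 2
    return np.where(u < 1.0, k, 0.0)


def build_effort_surface(lons, lats, grid: GridSpec,
                         config: KdeConfig = KdeConfig()) -> RasterGrid:
    """Raw sampling-effort density: summed quartic kernels at cell centres.

    Cell value = sum over presence points of the kernel evaluated at the
    great-circle distance from the point to the cell centre. Deterministic
    and invariant to point order.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.size == 0:
        raise ValueError("effort surface needs at least one presence point")
    clat = grid.lat_centers
    clon = grid.lon_centers
    cell_lat = np.repeat(clat, grid.n_cols)
    cell_lon = np.tile(clon, grid.n_rows)
    out = np.zeros(cell_lat.size)
    chunk = max(1, int(2_000_000 // cell_lat.size))
    for start in range(0, lons.size, chunk):
        pl_lat = lats[start:start + chunk, None]
        pl_lon = lons[start:start + chunk, None]
        d = great_circle_km(pl_lat, pl_lon, cell_lat[None, :], cell_lon[None, :])
        out += quartic_kernel(d, config.bandwidth_km).sum(axis=0)
    return RasterGrid(grid, out.reshape(grid.shape))


@dataclass
class EffortSurface:
    """Normalised sampling-effort probability surface.

    Every unmasked cell has strictly positive probability and the grand
    sum is 1 (to 1e-9).
    """

    raster: RasterGrid

    def __post_init__(self) -> None:
        p = self.raster.values
        valid = self.raster.mask
        if not valid.any():
            raise ValueError("effort surface has no valid cells")
        if np.any(p[valid] <= 0):
            raise ValueError("effort surface probabilities must be positive")
        if abs(p[valid].sum() - 1.0) > 1e-9:
            raise ValueError("effort surface probabilities must sum to 1")

    @property
    def grid(self) -> GridSpec:
        return self.raster.grid

    @property
    def probabilities(self) -> np.ndarray:
        return self.raster.values


def normalize_with_floor(raw: RasterGrid,
                         epsilon_factor: float = 0.01) -> EffortSurface:
    """Floor never-sampled cells and normalise to a probability surface.

    Zero-valued unmasked cells receive ``min positive value ×
    epsilon_factor`` (default 1/100) so they keep a small chance of
    selection; all cells are then divided by the grand sum.
    """
    vals = raw.values
    valid = raw.mask
    if np.any(vals[valid] < 0):
        raise ValueError("raw effort surface must be non-negative")
    positive = vals[valid][vals[valid] > 0]
    if positive.size == 0:
        raise ValueError("raw effort surface is identically zero")
    floor = positive.min() * epsilon_factor
    floored = np.where(valid & (vals == 0), floor, vals)
    floored = np.where(valid, floored, np.nan)
    total = np.nansum(floored)
    return EffortSurface(RasterGrid(raw.grid, floored / total))


def sample_background(surface: EffortSurface, n: int = 50_000,
                      seed: int = 0) -> pd.DataFrame:
    """Draw background points from the effort probability surface.

    Cells are drawn i.i.d. with replacement from the cell-probability
    multinomial; each point is then placed uniformly at random within
    its cell. Returns a frame with ``lon, lat, row, col``.
    """
    rng = np.random.default_rng(seed)
    g = surface.grid
    valid = surface.raster.mask.ravel()
    p = surface.probabilities.ravel()[valid]
    flat_ids = np.flatnonzero(valid)
    picks = flat_ids[rng.choice(p.size, size=n, p=p / p.sum())]
    rows, cols = np.unravel_index(picks, g.shape)
    lat = g.lat_max - (rows + rng.random(n)) * g.dlat
    lon = g.lon_min + (cols + rng.random(n)) * g.dlon
    return pd.DataFrame({"lon": lon, "lat": lat, "row": rows, "col": cols})


@dataclass
class TrainingTable:
    """Presence/background rows with extracted covariate columns.

    ``labels`` is 1 for presences, 0 for background; ``features`` holds
    one column per covariate, aligned row-wise with ``labels``.
    """

    features: pd.DataFrame
    labels: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels disagree in length")
        if self.m < 1 or self.b < 1:
            raise ValueError("training needs at least one presence and one "
                             "background row")
        if not np.isfinite(self.features.to_numpy()).all():
            raise ValueError("training covariates must be finite")

    @property
    def m(self) -> int:
        return int(self.labels.sum())

    @property
    def b(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def presence_features(self) -> pd.DataFrame:
        return self.features[self.labels == 1]

    @property
    def background_features(self) -> pd.DataFrame:
        return self.features[self.labels == 0]


def assemble_training(presence_lons, presence_lats,
                      background: pd.DataFrame,
                      stack: EnvStack) -> TrainingTable:
    """Merge one species' presences with the shared background set.

    Covariates are extracted at every point; points on masked cells or
    outside the extent are dropped and counted.
    """
    pres = extract_covariates(presence_lons, presence_lats, stack)
    if len(pres) == 0:
        raise ValueError("no presence records with valid covariates")
    bg = extract_covariates(background["lon"].to_numpy(),
                            background["lat"].to_numpy(), stack)
    n_dropped = pres.attrs["n_dropped"] + bg.attrs["n_dropped"]
    if n_dropped:
        logger.info("assemble_training: dropped %d points on masked cells",
                    n_dropped)
    features = pd.concat([pres, bg], ignore_index=True)
    labels = np.concatenate([np.ones(len(pres), dtype=int),
                             np.zeros(len(bg), dtype=int)])
    return TrainingTable(features=features, labels=labels, n_dropped=n_dropped)
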