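"""Scenario-keyed environmental raster stacks, VIF screening, point extraction.

An :class:`EnvStack` bundles named covariate rasters that share one grid and
one climate scenario. Scenarios are keyed by period (the current baseline
2000–2020 or one of two future decades) crossed with a Shared Socioeconomic
Pathway; seven keys are valid in total.

Predictor screening uses the variance inflation factor
``VIF_j = 1 / (1 - R²_j)``, where R²_j comes from regressing covariate j on
all the others; variables are dropped greedily from the highest VIF until
all fall below a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import GridSpec, RasterGrid

logger = logging.getLogger(__name__)

CURRENT_PERIOD = "2000-2020"
FUTURE_PERIODS = ("2050-2060", "2090-2100")
SSPS = ("SSP1-1.9", "SSP2-4.5", "SSP5-8.5")


@dataclass(frozen=True)
class ScenarioKey:
    """Period × SSP identifier for an environmental stack.

    The current baseline period carries no SSP; each future period must
    carry one of the three pathways, giving 7 valid keys.
    """

    period: str = CURRENT_PERIOD
    ssp: str | None = None

    def __post_init__(self) -> None:
        if self.period == CURRENT_PERIOD:
            if self.ssp is not None:
                raise ValueError("the current period takes no SSP")
        elif self.period in FUTURE_PERIODS:
            if self.ssp not in SSPS:
                raise ValueError(
                    f"future period {self.period!r} requires an SSP from {SSPS}"
                )
        else:
            raise ValueError(f"unknown period {self.period!r}")

    @property
    def is_current(self) -> bool:
        return self.period == CURRENT_PERIOD

    @property
    def label(self) -> str:
        if self.is_current:
            return "current"
        return f"{self.period}_{self.ssp}"

    @classmethod
    def from_label(cls, label: str) -> "ScenarioKey":
        if label == "current":
            return cls()
        period, _, ssp = label.partition("_")
        return cls(period, ssp or None)


CURRENT = ScenarioKey()
FUTURE_KEYS: tuple[ScenarioKey, ...] = tuple(
    ScenarioKey(p, s) for p in FUTURE_PERIODS for s in SSPS
)
ALL_KEYS: tuple[ScenarioKey, ...] = (CURRENT,) + FUTURE_KEYS


class EnvStack:
    """Aligned, named covariate rasters for one scenario.

    All layers must share one :class:`GridSpec`; misalignment is rejected
    rather than silently resampled.
    """

    def __init__(self, layers: Mapping[str, RasterGrid],
                 scenario: ScenarioKey = CURRENT) -> None:
        if not layers:
            raise ValueError("an environmental stack needs at least one layer")
        names = list(layers)
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names in stack")
        self.scenario = scenario
        self.layers: dict[str, RasterGrid] = dict(layers)
        grid = next(iter(self.layers.values())).grid
        for name, layer in self.layers.items():
            if layer.grid != grid:
                raise ValueError(
                    f"layer {name!r} is not aligned with the stack grid "
                    f"({layer.grid.shape} vs {grid.shape})"
                )
        self.grid: GridSpec = grid

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for layer in self.layers.values():
            mask &= layer.mask
        return mask

    def to_frame(self) -> pd.DataFrame:
        """Covariate table over cells valid in all layers.

        The index is the flat cell index (row-major) into the grid.
        """
        mask = self.valid_mask
        flat = np.flatnonzero(mask.ravel())
        data = {
            name: layer.values.ravel()[flat]
            for name, layer in self.layers.items()
        }
        return pd.DataFrame(data, index=flat)


def load_env_stack(paths: Mapping[str, str],
                   scenario: ScenarioKey = CURRENT) -> EnvStack:
    """Load aligned single-band ASCII-grid layers into a stack.

    ``paths`` maps covariate name to file path. Misaligned layers raise,
    naming the offending layer.
    """
    layers = {name: RasterGrid.read_ascii(path) for name, path in paths.items()}
    return EnvStack(layers, scenario)


# ----------------------------------------------------------------------
# Variance inflation factors
# ----------------------------------------------------------------------

#: R² above which a predictor is considered exactly collinear.
_COLLINEAR_R2 = 1.0 - 1e-12


@dataclass
class VifReport:
    """Outcome of VIF computation / iterative selection.

    ``dropped`` lists (variable, VIF at removal) in removal order;
    ``vif`` holds the final per-variable values for the retained set.
    """

    vif: pd.Series
    retained: list[str]
    dropped: list[tuple[str, float]] = field(default_factory=list)


def _vif_values(table: pd.DataFrame) -> pd.Series:
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 variables")
    if n <= p:
        raise ValueError("VIF needs more rows than variables")
    if not np.isfinite(X).all():
        raise ValueError("VIF input must not contain missing values")
    out = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        y = X[:, j]
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0.0:
            out[j] = np.inf  # constant column
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[j] = np.inf if r2 >= _COLLINEAR_R2 else 1.0 / (1.0 - r2)
    return pd.Series(out, index=table.columns, name="vif")


def compute_vif(table: pd.DataFrame) -> VifReport:
    """Per-variable VIF of a points × variables table.

    Equivalent to the diagonal of the inverse correlation matrix; exact
    collinearity is reported as +inf rather than raising.
    """
    vif = _vif_values(table)
    if np.isinf(vif).any():
        logger.warning(
            "exact collinearity detected for: %s",
            ", ".join(vif.index[np.isinf(vif)]),
        )
    return VifReport(vif=vif, retained=list(table.columns))


def select_variables_vif(table: pd.DataFrame, threshold: float = 5.0) -> VifReport:
    """Greedy VIF screening.

    While any VIF exceeds ``threshold``, drop the variable with the
    largest VIF and recompute. Ties on the maximum are broken by
    removing the alphabetically last name, making the outcome invariant
    to column order.
    """
    remaining = table.copy()
    dropped: list[tuple[str, float]] = []
    while remaining.shape[1] >= 2:
        vif = _vif_values(remaining)
        vmax = vif.max()
        if not (vmax > threshold):
            break
        ties = sorted(vif.index[vif == vmax])
        victim = ties[-1]
        dropped.append((victim, float(vmax)))
        logger.info("dropping %s (VIF %.3g > %.3g)", victim, vmax, threshold)
        remaining = remaining.drop(columns=[victim])
    final = (
        _vif_values(remaining)
        if remaining.shape[1] >= 2
        else pd.Series(1.0, index=remaining.columns, name="vif")
    )
    return VifReport(vif=final, retained=list(remaining.columns), dropped=dropped)


def extract_covariates(lons, lats, stack: EnvStack) -> pd.DataFrame:
    """Covariate values at the cell containing each point.

    Points outside the extent, or falling on a cell masked in any layer,
    are dropped and their count logged; surviving rows keep positional
    identity through the returned index.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    rows, cols, inside = stack.grid.rowcol(lats, lons)
    data = np.full((len(lons), len(stack.layers)), np.nan)
    for k, layer in enumerate(stack.layers.values()):
        data[inside, k] = layer.values[rows[inside], cols[inside]]
    keep = inside & np.isfinite(data).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "extract_covariates: dropped %d of %d points "
            "(outside extent or masked cell)", n_dropped, len(lons),
        )
    out = pd.DataFrame(
        data[keep], columns=stack.names, index=np.flatnonzero(keep)
    )
    out.attrs["n_dropped"] = n_dropped
    return out
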