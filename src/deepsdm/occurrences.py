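"""Occurrence reading and cleaning for deep-sea presence records.

Records are filtered to a study window (56–80°N, 45°W–45°E by default),
to the deep sea (recorded depth strictly greater than 200 m), to a
2000–2020 sampling window, and validated as benthic by comparing the
recorded sampling depth against gridded bathymetry: a record whose depth
differs from the seafloor depth by more than 5 % (relative to the
bathymetric depth) is treated as a pelagic catch and removed. Species
with fewer than 200 surviving records are excluded from modelling.

Each filter is a record-wise predicate, so record-level filters commute
and are idempotent; the species-level minimum-record rule is applied last
so that inclusion reflects usable records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import RasterGrid

logger = logging.getLogger(__name__)

#: Darwin-Core-like input columns -> internal names.
COLUMN_MAP = {
    "scientificName": "species",
    "decimalLatitude": "lat",
    "decimalLongitude": "lon",
    "depth": "depth",
    "year": "year",
}
MANDATORY = ("scientificName", "decimalLatitude", "decimalLongitude")


@dataclass(frozen=True)
class StudyWindow:
    """Spatial, bathymetric and temporal bounds of the study region."""

    lat_min: float = 56.0
    lat_max: float = 80.0
    lon_min: float = -45.0
    lon_max: float = 45.0
    min_depth: float = 200.0  # metres; records must be strictly deeper
    year_min: int = 2000
    year_max: int = 2020

    def __post_init__(self) -> None:
        if self.min_depth <= 0:
            raise ValueError("min_depth must be positive")


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Read a delimited occurrence table into the internal schema.

    Returns a frame with columns ``record_id, species, lat, lon, depth,
    year``; missing depth/year stay NaN. Rows with unparseable or
    out-of-range coordinates are dropped row-wise with a logged reason;
    absent mandatory columns raise, naming them.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns: {', '.join(missing)}")
    out = pd.DataFrame()
    if "record_id" in df.columns:
        out["record_id"] = df["record_id"]
    else:
        out["record_id"] = np.arange(len(df))
    out["species"] = df["scientificName"].astype(str)
    out["lat"] = pd.to_numeric(df["decimalLatitude"], errors="coerce")
    out["lon"] = pd.to_numeric(df["decimalLongitude"], errors="coerce")
    for src, dst in (("depth", "depth"), ("year", "year")):
        out[dst] = (
            pd.to_numeric(df[src], errors="coerce")
            if src in df.columns
            else np.nan
        )
    bad = (
        out["lat"].isna() | out["lon"].isna()
        | (out["lat"].abs() > 90.0) | (out["lon"].abs() > 180.0)
        | (out["depth"] < 0)
    )
    if bad.any():
        for rid in out.loc[bad, "record_id"]:
            logger.info("read_occurrences: rejected record %s (invalid coordinates/depth)", rid)
    return out[~bad].reset_index(drop=True)


def _audit(records: pd.DataFrame, failed: pd.Series) -> pd.DataFrame:
    """Build a (record_id, rule_failed) audit for removed records."""
    removed = failed != ""
    return pd.DataFrame(
        {"record_id": records.loc[removed, "record_id"].to_numpy(),
         "rule_failed": failed[removed].to_numpy()}
    )


def filter_window(records: pd.DataFrame,
                  window: StudyWindow = StudyWindow(),
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep records inside the study box, strictly deeper than
    ``min_depth``, with a year inside the study period.

    Records missing depth or year cannot be evaluated and are removed.
    Returns ``(kept, audit)`` where the audit lists each removed
    record's first failed rule.
    """
    failed = pd.Series("", index=records.index, dtype=object)
    in_box = (
        records["lat"].between(window.lat_min, window.lat_max)
        & records["lon"].between(window.lon_min, window.lon_max)
    )
    failed[~in_box] = "window"
    sel = failed == ""
    failed[sel & records["depth"].isna()] = "missing_depth"
    sel = failed == ""
    failed[sel & ~(records["depth"] > window.min_depth)] = "depth"
    sel = failed == ""
    failed[sel & records["year"].isna()] = "missing_year"
    sel = failed == ""
    failed[sel & ~records["year"].between(window.year_min, window.year_max)] = "year"
    kept = records[failed == ""].reset_index(drop=True)
    return kept, _audit(records, failed)


def validate_benthic(records: pd.DataFrame, bathymetry: RasterGrid,
                     tolerance: float = 0.05,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep records whose depth agrees with the seafloor depth.

    A record is benthic when ``|depth - bathy| / bathy <= tolerance``,
    with the bathymetric depth taken from the cell containing the point
    (nearest-cell, no interpolation). Records outside the bathymetry
    extent or on a masked cell, or with missing depth, are removed and
    logged.
    """
    failed = pd.Series("", index=records.index, dtype=object)
    bathy, inside = bathymetry.sample(records["lat"].to_numpy(),
                                      records["lon"].to_numpy())
    no_ref = ~inside | ~np.isfinite(bathy)
    failed[no_ref] = "outside_bathymetry"
    sel = (failed == "") & records["depth"].isna()
    failed[sel] = "missing_depth"
    sel = (failed == "").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        mismatch = np.abs(records["depth"].to_numpy() - bathy) / bathy
    failed[sel & (mismatch > tolerance)] = "benthic_mismatch"
    n_out = int(no_ref.sum())
    if n_out:
        logger.info("validate_benthic: %d records outside bathymetry extent", n_out)
    kept = records[failed == ""].reset_index(drop=True)
    return kept, _audit(records, failed)


def filter_min_records(records: pd.DataFrame, min_records: int = 200,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop species with fewer than ``min_records`` surviving records.

    Returns ``(records restricted to included species, species table)``;
    the table lists every species with its post-filter count and an
    inclusion flag (count >= min_records, threshold inclusive).
    """
    counts = records["species"].value_counts().sort_index()
    table = pd.DataFrame(
        {"species": counts.index,
         "n_records": counts.to_numpy(),
         "included": counts.to_numpy() >= min_records}
    ).reset_index(drop=True)
    included = set(table.loc[table["included"], "species"])
    kept = records[records["species"].isin(included)].reset_index(drop=True)
    return kept, table


@dataclass
class CleanResult:
    """Outcome of the full record-cleaning pass."""

    records: pd.DataFrame
    species_table: pd.DataFrame
    audit: pd.DataFrame


def clean_occurrences(records: pd.DataFrame, bathymetry: RasterGrid,
                      window: StudyWindow = StudyWindow(),
                      tolerance: float = 0.05,
                      min_records: int = 200) -> CleanResult:
    """Window/depth/year filter, benthic validation, then the
    species-level minimum-record rule."""
    kept, audit_w = filter_window(records, window)
    kept, audit_b = validate_benthic(kept, bathymetry, tolerance)
    kept, table = filter_min_records(kept, min_records)
    audit = pd.concat([audit_w, audit_b], ignore_index=True)
    logger.info(
        "clean_occurrences: %d -> %d records, %d/%d species included",
        len(records), len(kept), int(table["included"].sum()), len(table),
    )
    return CleanResult(records=kept, species_table=table, audit=audit)
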