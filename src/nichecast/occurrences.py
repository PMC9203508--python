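"""Occurrence quality control, gridding and the depth/coast habitat filter.

Raw presence-only records from heterogeneous databases come with
unreliable flags, exact duplicates, locational errors (points on land,
far geographic outliers) and weak dating.  Cleaning keeps records dated
1990 or later unconditionally; older or undated records are retained
only along the distribution edge, i.e. within a configurable distance of
a recent record of the same species.  Cleaned records are aggregated to
one presence per occupied 0.1° cell, and candidate habitat is screened
by a hierarchical rule: a cell qualifies when its depth falls inside the
species' observed depth range, or, failing that, when it lies within a
coastal buffer (50 km by default) — so shelf-poor coasts are not
excluded merely for being too deep or too shallow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grids import KM_PER_DEG, EnvGrid


@dataclass(frozen=True)
class CleaningRules:
    """Thresholds for occurrence QC.

    recent_year : records dated >= this year are kept unconditionally.
    edge_distance_km : older/undated records are kept only within this
        distance of a recent record (distribution-edge confirmation).
    outlier_distance_km : records farther than this beyond the 99%
        spatial-density envelope are dropped as geographic outliers.
    round_decimals : coordinate rounding applied before exact-duplicate
        detection (database re-submissions).
    """

    recent_year: int = 1990
    edge_distance_km: float = 100.0
    outlier_distance_km: float = 1000.0
    round_decimals: int = 4


@dataclass
class OccurrenceSet:
    """Presences aggregated to grid cells.

    cells : sorted array of flat cell ids with at least one record.
    provenance : per-cell record count and most recent year.
    """

    species: str
    cells: np.ndarray
    provenance: pd.DataFrame

    def __len__(self) -> int:
        return self.cells.size


@dataclass(frozen=True)
class DepthRange:
    """Observed depth range of a species (m, positive down) plus the
    coastal buffer that rescues shelf-poor cells."""

    min_depth: float
    max_depth: float
    coastal_buffer_km: float = 50.0

    def __post_init__(self):
        if not (0 <= self.min_depth < self.max_depth):
            raise ValueError("need 0 <= min_depth < max_depth")
        if self.coastal_buffer_km < 0:
            raise ValueError("coastal buffer must be non-negative")


def _km_coords(lon, lat, ref_lat: float) -> np.ndarray:
    """Equirectangular projection to km, adequate at sub-regional scale."""
    x = np.asarray(lon) * KM_PER_DEG * np.cos(np.deg2rad(ref_lat))
    y = np.asarray(lat) * KM_PER_DEG
    return np.column_stack([x, y])


def clean_occurrences(
    raw: pd.DataFrame, grid: EnvGrid, rules: CleaningRules = CleaningRules()
) -> pd.DataFrame:
    """Apply the QC cascade; returns the retained rows (original columns).

    Order: unreliable flags → exact duplicates → out-of-domain → on-land
    → geographic outliers → date rule.  The cascade is idempotent.
    """
    if "lon" not in raw.columns or "lat" not in raw.columns:
        raise ValueError("raw occurrence table must have 'lon' and 'lat' columns")
    rec = raw.copy()

    if "flag" in rec.columns:
        rec = rec[rec["flag"] != "unreliable"]

    # exact duplicates after coordinate rounding
    key = pd.DataFrame(
        {
            "lon": rec["lon"].round(rules.round_decimals),
            "lat": rec["lat"].round(rules.round_decimals),
            "year": rec["year"] if "year" in rec.columns else np.nan,
        }
    )
    rec = rec[~key.duplicated(keep="first")]

    # domain and land
    inside = grid.in_domain(rec["lon"].values, rec["lat"].values)
    rec = rec[inside]
    iy, ix = grid.cell_indices(rec["lon"].values, rec["lat"].values)
    marine = grid.marine_mask[iy, ix]
    rec = rec[marine]
    if rec.empty:
        return rec

    # geographic outliers: beyond the 99% density envelope by more than
    # outlier_distance_km
    pts = _km_coords(rec["lon"].values, rec["lat"].values, float(np.mean(grid.lat)))
    centre = np.median(pts, axis=0)
    radii = np.linalg.norm(pts - centre, axis=1)
    envelope = np.quantile(radii, 0.99)
    rec = rec[radii <= envelope + rules.outlier_distance_km]
    if rec.empty:
        return rec

    # date rule: recent records always kept; older/undated only near one
    year = rec["year"] if "year" in rec.columns else pd.Series(np.nan, index=rec.index)
    recent = year >= rules.recent_year
    if recent.all():
        return rec
    if not recent.any():
        return rec[recent]
    pts = _km_coords(rec["lon"].values, rec["lat"].values, float(np.mean(grid.lat)))
    tree = cKDTree(pts[recent.values])
    d, _ = tree.query(pts[~recent.values])
    keep_old = d <= rules.edge_distance_km
    keep = recent.values.copy()
    keep[~recent.values] = keep_old
    return rec[keep]


def grid_occurrences(clean: pd.DataFrame, grid: EnvGrid, species: str | None = None) -> OccurrenceSet:
    """Aggregate cleaned records to one presence per occupied cell."""
    if species is None:
        species = str(clean["species"].iloc[0]) if ("species" in clean.columns and len(clean)) else "unknown"
    if clean.empty:
        import warnings

        warnings.warn("no records to grid; returning an empty occurrence set")
        return OccurrenceSet(
            species, np.array([], dtype=int), pd.DataFrame(columns=["cell_id", "n_records", "last_year"])
        )
    iy, ix = grid.cell_indices(clean["lon"].values, clean["lat"].values)
    cell = grid.flat_id(iy, ix)
    year = clean["year"].values if "year" in clean.columns else np.full(len(clean), np.nan)
    prov = (
        pd.DataFrame({"cell_id": cell, "year": year})
        .groupby("cell_id")
        .agg(n_records=("year", "size"), last_year=("year", "max"))
        .reset_index()
    )
    return OccurrenceSet(species, np.sort(prov["cell_id"].values), prov)


def depth_coast_mask(grid: EnvGrid, depth: DepthRange) -> np.ndarray:
    """Boolean (ny, nx) habitat-candidate mask.

    A marine cell passes iff its depth |bathymetry| lies within the
    species depth range, OR it is within the coastal buffer of the
    coast — the hierarchical depth/coast rule.
    """
    if depth is None:
        raise ValueError("depth range undefined for species")
    bathy = grid.layer("bathymetry")
    marine = bathy < 0
    d = np.abs(bathy)
    in_range = (d >= depth.min_depth) & (d <= depth.max_depth)
    near_coast = grid.layer("dist_coast") <= depth.coastal_buffer_km
    return marine & (in_range | near_coast)


def apply_depth_coast_filter(
    cells: OccurrenceSet | np.ndarray, depth: DepthRange, grid: EnvGrid
) -> np.ndarray:
    """Per-cell pass/fail of the depth/coast rule for the given cells."""
    mask = depth_coast_mask(grid, depth)
    ids = cells.cells if isinstance(cells, OccurrenceSet) else np.asarray(cells)
    iy, ix = grid.unravel(ids)
    return mask[iy, ix]
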