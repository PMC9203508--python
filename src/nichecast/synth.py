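"""Synthetic world generator.

Every downstream stage of the pipeline is exercised against a
self-contained synthetic world whose niche truth is known analytically:

* an environmental grid with the layers the analysis uses (SBT, SBTr,
  SBTvar, SST, SSTr, SSTvar, SSS, Log_PP/PP, bathymetry,
  distance-to-coast) on a regular 0.1° grid, with a coast along the
  eastern edge of the domain;
* a :class:`NicheTruth` — a product of independent Gaussians over the
  three retained predictors (SBT, SBTr, Log_PP) — against which niche
  recovery can be checked analytically;
* presence-only occurrence records sampled proportionally to true
  suitability times a spatial sampling-effort field, contaminated with
  the defects occurrence databases actually show (exact duplicates,
  on-land points, unreliable flags, pre-1990 and undated records);
* emulated general-circulation-model (GCM) fields: observed climatology
  plus a per-GCM smooth bias, per-cell noise and a prescribed per-decade
  warming delta increasing across RCP scenarios, with a "common period"
  field per GCM for delta bias correction;
* Exclusive Economic Zone (EEZ) polygons tiling the marine domain and a
  per-(species, EEZ) catch table.

All outputs are deterministic functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import box, mapping

from .grids import KM_PER_DEG, EnvGrid

#: decade labels used throughout: short-, mid- and long-term horizons
DECADES = ("2030-2039", "2050-2059", "2090-2099")
RCPS = (2.6, 4.5, 8.5)

#: default per-decade warming deltas (°C), monotone across RCPs; the
#: end-of-century RCP8.5 value is the +3.2 °C headline warming level.
DEFAULT_DELTAS: dict[tuple[float, str], float] = {
    (2.6, "2030-2039"): 0.5,
    (2.6, "2050-2059"): 0.8,
    (2.6, "2090-2099"): 1.0,
    (4.5, "2030-2039"): 0.7,
    (4.5, "2050-2059"): 1.2,
    (4.5, "2090-2099"): 2.0,
    (8.5, "2030-2039"): 1.0,
    (8.5, "2050-2059"): 1.8,
    (8.5, "2090-2099"): 3.2,
}

TEMPERATURE_MEANS = ("SBT", "SST")
TEMPERATURE_RANGES = ("SBTr", "SBTvar", "SSTr", "SSTvar")
TEMPERATURE_VARIABLES = TEMPERATURE_MEANS + TEMPERATURE_RANGES

#: fraction of the mean-temperature delta applied to seasonality /
#: variance layers (seasonal amplitude responds much less than the mean)
RANGE_DELTA_SCALE = 0.3


# ----------------------------------------------------------------------
# niche truth
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class NicheTruth:
    """Known realized niche: product of independent Gaussians.

    ``s(x) = max_suitability · Π_v exp(−(x_v − opt_v)² / (2 tol_v²))``
    """

    optima: dict[str, float]
    tolerances: dict[str, float]
    max_suitability: float = 1.0

    def __post_init__(self):
        if set(self.optima) != set(self.tolerances):
            raise ValueError("optima and tolerances must cover the same variables")
        if any(t <= 0 for t in self.tolerances.values()):
            raise ValueError("tolerances must be positive")
        if not (0 < self.max_suitability <= 1):
            raise ValueError("max_suitability must be in (0, 1]")

    @property
    def variables(self) -> list[str]:
        return list(self.optima)

    def suitability(self, env: pd.DataFrame | dict) -> np.ndarray:
        """True suitability in [0, 1] at the given environmental values."""
        s = None
        for v in self.optima:
            x = np.asarray(env[v], dtype=float)
            term = np.exp(-((x - self.optima[v]) ** 2) / (2 * self.tolerances[v] ** 2))
            s = term if s is None else s * term
        return self.max_suitability * s


def default_truth() -> NicheTruth:
    """Default thermal-niche truth, centred inside the default domain's
    environmental range so both flanks of each response are observable."""
    return NicheTruth(
        optima={"SBT": 17.5, "SBTr": 5.0, "Log_PP": -6.7},
        tolerances={"SBT": 2.0, "SBTr": 2.5, "Log_PP": 0.8},
    )


# ----------------------------------------------------------------------
# environment
# ----------------------------------------------------------------------
def _smooth_field(rng: np.random.Generator, shape, sd: float, length: float = 8.0) -> np.ndarray:
    """Zero-mean smooth Gaussian random field with pointwise sd ≈ ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=length, mode="nearest")
    s = raw.std()
    if s == 0:
        return np.zeros(shape)
    return raw * (sd / s)


def make_env_grid(
    domain_bounds: tuple[float, float, float, float] = (-2.0, 8.0, 36.0, 48.0),
    cell_size: float = 0.1,
    seed: int = 0,
) -> EnvGrid:
    """Generate the synthetic contemporary climatology.

    Parameters
    ----------
    domain_bounds : (lon_min, lon_max, lat_min, lat_max) in degrees.
    cell_size : cell edge in degrees; must divide both extents.
    seed : RNG seed; the output is a deterministic function of it.

    The world has land along the (wiggly) eastern coast, bathymetry
    deepening offshore, sea-bottom temperature decreasing poleward,
    a mid-latitude maximum in SBT seasonal range, SBTvar strongly
    correlated with SBTr (as in real bottom-temperature climatologies),
    an eastward salinity gradient and primary production concentrated
    near the coast.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    lon0, lon1, lat0, lat1 = map(float, domain_bounds)
    for extent in (lon1 - lon0, lat1 - lat0):
        n = extent / cell_size
        if abs(n - round(n)) > 1e-9:
            raise ValueError("cell_size must divide the domain extents")
    nx = round((lon1 - lon0) / cell_size)
    ny = round((lat1 - lat0) / cell_size)
    lon = lon0 + cell_size * (np.arange(nx) + 0.5)
    lat = lat0 + cell_size * (np.arange(ny) + 0.5)
    LAT, LON = np.meshgrid(lat, lon, indexing="ij")

    rng = np.random.default_rng(seed)
    width = lon1 - lon0
    height = lat1 - lat0

    # coastline: land occupies the easternmost ~12% of the domain, with a
    # seeded sinusoidal wiggle so the coast is not a straight meridian
    phase = rng.uniform(0, 2 * np.pi)
    coast_lon = lon1 - 0.12 * width + 0.04 * width * np.sin(
        2 * np.pi * (lat - lat0) / height * 2.0 + phase
    )
    land = LON > coast_lon[:, None]

    # bathymetry: shelf sloping away from the coast, then a deep basin;
    # positive on land
    dist_deg = np.maximum(coast_lon[:, None] - LON, 0.0)
    bathy = -(60.0 + 250.0 * dist_deg + 40.0 * dist_deg**3) + _smooth_field(rng, (ny, nx), 40.0)
    bathy = np.maximum(bathy, -5500.0)
    bathy[land] = 150.0
    bathy[~land] = np.minimum(bathy[~land], -5.0)

    # distance to coast (km), 0 on land
    mean_lat = np.deg2rad(lat.mean())
    xs = LON * KM_PER_DEG * np.cos(mean_lat)
    ys = LAT * KM_PER_DEG
    if land.any() and (~land).any():
        tree = cKDTree(np.column_stack([xs[land], ys[land]]))
        d, _ = tree.query(np.column_stack([xs[~land], ys[~land]]))
        dist_coast = np.zeros((ny, nx))
        dist_coast[~land] = d
    else:  # pragma: no cover - degenerate all-sea/all-land domain
        dist_coast = np.zeros((ny, nx))

    # sea-bottom temperature: warm at the equatorward edge, cooling
    # poleward, slightly colder over deep water
    sbt = (
        25.0
        - 1.1 * (LAT - lat0)
        + 4.0e-4 * np.minimum(bathy, 0.0)
        + _smooth_field(rng, (ny, nx), 0.4)
    )
    # seasonal range of SBT: largest over the shallow shelf (the seasonal
    # signal is damped at depth), modulated by a mild mid-latitude maximum
    lat_mid = 0.5 * (lat0 + lat1)
    sbtr = (1.0 + 7.0 * np.exp(np.minimum(bathy, 0.0) / 400.0)) * (
        0.7 + 0.3 * np.exp(-(((LAT - lat_mid) / (0.4 * height)) ** 2))
    ) + _smooth_field(rng, (ny, nx), 0.3)
    sbtr = np.maximum(sbtr, 0.1)
    # monthly variance proxy, strongly correlated with SBTr (r > 0.7)
    sbtvar = 0.8 * sbtr + _smooth_field(rng, (ny, nx), 0.35) + 0.3
    sbtvar = np.maximum(sbtvar, 0.05)

    sst = sbt + 3.0 + 1.5 * np.exp(np.minimum(bathy, 0.0) / 500.0) + _smooth_field(
        rng, (ny, nx), 0.3
    )
    sstr = 1.0 + 0.9 * sbtr + _smooth_field(rng, (ny, nx), 0.3)
    sstr = np.maximum(sstr, 0.1)
    sstvar = 0.8 * sstr + _smooth_field(rng, (ny, nx), 0.3) + 0.2
    sstvar = np.maximum(sstvar, 0.05)

    sss = 36.0 + 0.15 * (LON - lon0) + _smooth_field(rng, (ny, nx), 0.15)

    # log primary production (mol C m^-2 s^-1 scale): coastal enrichment
    log_pp = -7.0 + 0.6 * np.exp(-dist_coast / 300.0) + _smooth_field(rng, (ny, nx), 0.15)

    ds = xr.Dataset(
        {
            name: (("lat", "lon"), arr)
            for name, arr in {
                "SBT": sbt,
                "SBTr": sbtr,
                "SBTvar": sbtvar,
                "SST": sst,
                "SSTr": sstr,
                "SSTvar": sstvar,
                "SSS": sss,
                "Log_PP": log_pp,
                "PP": np.exp(log_pp),
                "bathymetry": bathy,
                "dist_coast": dist_coast,
            }.items()
        },
        coords={"lat": lat, "lon": lon},
    )
    return EnvGrid(ds)


# ----------------------------------------------------------------------
# occurrences
# ----------------------------------------------------------------------
def coastal_effort(grid: EnvGrid, strength: float = 2.0, scale_km: float = 150.0) -> np.ndarray:
    """Spatial sampling-effort field: surveys concentrate near the coast.

    effort = 1 + strength · exp(−distance_to_coast / scale_km), the
    heterogeneous-effort structure presence-only databases exhibit.
    """
    return 1.0 + strength * np.exp(-grid.layer("dist_coast") / scale_km)


def depth_affinity(
    grid: EnvGrid,
    min_depth: float = 150.0,
    max_depth: float = 1000.0,
    coastal_buffer_km: float = 50.0,
    floor: float = 0.02,
) -> np.ndarray:
    """Depth preference of the synthetic demersal species: weight 1
    inside its depth range (or within the coastal buffer), ``floor``
    elsewhere.  Multiplied into the sampling weights so occurrences
    concentrate in plausible demersal habitat."""
    d = np.abs(grid.layer("bathymetry"))
    ok = ((d >= min_depth) & (d <= max_depth)) | (grid.layer("dist_coast") <= coastal_buffer_km)
    return np.where(ok, 1.0, floor)


@dataclass(frozen=True)
class NoiseSpec:
    """Contamination injected into the sampled records so that the
    quality-control stage is exercised at realistic rates.

    The year-class fractions mirror the mix occurrence databases show:
    roughly 73% of records dated ≥ 1990, 11% dated before 1990 and 16%
    undated.
    """

    duplicate_fraction: float = 0.05
    onland_fraction: float = 0.02
    unreliable_fraction: float = 0.05
    pre1990_fraction: float = 0.1079
    undated_fraction: float = 0.1637


def sample_occurrences(
    grid: EnvGrid,
    truth: NicheTruth,
    n: int,
    effort_bias: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    species: str = "synthfish",
) -> pd.DataFrame:
    """Sample raw presence records ∝ true suitability × sampling effort.

    Returns a table with columns species, lon, lat, year (NaN = undated)
    and flag ('ok' or 'unreliable'); includes the contamination described
    by ``noise``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    marine = grid.marine_mask
    env = grid.table(truth.variables, mask=marine)
    s = truth.suitability(env)
    if effort_bias is None:
        effort = np.ones(len(env))
    else:
        effort = np.asarray(effort_bias, dtype=float)
        if effort.shape == marine.shape:
            effort = effort[marine]
        if (effort < 0).any():
            raise ValueError("effort_bias must be non-negative everywhere")
    w = s * effort
    total = w.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero; no cell can be sampled")
    p = w / total

    idx = rng.choice(len(env), size=n, replace=True, p=p)
    cs = grid.cell_size
    lon = env["lon"].values[idx] + rng.uniform(-cs / 2, cs / 2, n) * 0.98
    lat = env["lat"].values[idx] + rng.uniform(-cs / 2, cs / 2, n) * 0.98

    # years: recent / pre-1990 / undated mix
    u = rng.uniform(size=n)
    year = rng.integers(1990, 2018, n).astype(float)
    year[u < noise.pre1990_fraction + noise.undated_fraction] = rng.integers(
        1950, 1990, n
    ).astype(float)[u < noise.pre1990_fraction + noise.undated_fraction]
    year[u < noise.undated_fraction] = np.nan

    flag = np.where(rng.uniform(size=n) < noise.unreliable_fraction, "unreliable", "ok")
    rec = pd.DataFrame(
        {"species": species, "lon": lon, "lat": lat, "year": year, "flag": flag}
    )

    # exact duplicates (database re-submissions)
    n_dup = int(round(noise.duplicate_fraction * n))
    if n_dup:
        dup = rec.iloc[rng.choice(n, n_dup, replace=False)]
        rec = pd.concat([rec, dup], ignore_index=True)

    # on-land locational errors
    n_land = int(round(noise.onland_fraction * n))
    land_iy, land_ix = np.nonzero(~marine)
    if n_land and land_iy.size:
        j = rng.choice(land_iy.size, n_land, replace=True)
        land_rec = pd.DataFrame(
            {
                "species": species,
                "lon": grid.lon[land_ix[j]],
                "lat": grid.lat[land_iy[j]],
                "year": rng.integers(1990, 2018, n_land).astype(float),
                "flag": "ok",
            }
        )
        rec = pd.concat([rec, land_rec], ignore_index=True)
    return rec


# ----------------------------------------------------------------------
# scenarios
# ----------------------------------------------------------------------
@dataclass
class ScenarioSet:
    """Emulated GCM fields for 5 GCMs × 3 RCPs × 3 decades.

    ``fields[(gcm, rcp, decade)]`` maps variable name → (ny, nx) array;
    ``common[gcm]`` holds the common-period field per GCM (observation
    plus that GCM's discrepancy, no warming delta), used for delta bias
    correction.  The same per-(GCM, variable) discrepancy realization
    enters the common-period and every future field.
    """

    fields: dict[tuple[int, float, str], dict[str, np.ndarray]]
    common: dict[int, dict[str, np.ndarray]]
    bias_maps: dict[int, np.ndarray]
    deltas: dict[tuple[float, str], float]
    gcms: tuple[int, ...] = field(default_factory=tuple)

    @property
    def rcps(self) -> tuple[float, ...]:
        return RCPS

    @property
    def decades(self) -> tuple[str, ...]:
        return DECADES


def make_scenarios(
    grid: EnvGrid,
    bias_sd: float = 0.5,
    noise_sd: float = 0.2,
    deltas: dict[tuple[float, str], float] | None = None,
    n_gcms: int = 5,
    seed: int = 0,
) -> ScenarioSet:
    """Emulate GCM scenario fields on the observation grid.

    Temperature-mean layers get ``obs + bias_g + noise_g + delta(rcp,
    decade)``; seasonality/variance layers receive a 0.3-scaled delta;
    Log_PP is perturbed additively in log space (multiplicative on PP)
    and declines mildly with warming; SSS is held constant in time.
    """
    deltas = dict(DEFAULT_DELTAS if deltas is None else deltas)
    for rcp in RCPS:
        for dec in DECADES:
            if (rcp, dec) not in deltas:
                raise ValueError(f"missing delta for RCP{rcp}, decade {dec}")
    for dec in DECADES:
        if not (deltas[(2.6, dec)] <= deltas[(4.5, dec)] <= deltas[(8.5, dec)]):
            raise ValueError(f"deltas must be monotone across RCPs (decade {dec})")

    rng = np.random.default_rng(seed)
    shape = (grid.ny, grid.nx)
    gcms = tuple(range(1, n_gcms + 1))
    common: dict[int, dict[str, np.ndarray]] = {}
    bias_maps: dict[int, np.ndarray] = {}
    disc: dict[tuple[int, str], np.ndarray] = {}

    perturbed = TEMPERATURE_VARIABLES + ("Log_PP",)
    for g in gcms:
        bias = _smooth_field(rng, shape, bias_sd, length=12.0)
        bias_maps[g] = bias
        common[g] = {}
        for v in perturbed:
            scale = 0.2 if v == "Log_PP" else 1.0
            d = scale * bias + rng.normal(0.0, noise_sd * scale, shape)
            disc[(g, v)] = d
            common[g][v] = grid.layer(v) + d
        common[g]["SSS"] = grid.layer("SSS").copy()

    fields: dict[tuple[int, float, str], dict[str, np.ndarray]] = {}
    for g in gcms:
        for rcp in RCPS:
            for dec in DECADES:
                delta = deltas[(rcp, dec)]
                f: dict[str, np.ndarray] = {}
                for v in TEMPERATURE_MEANS:
                    f[v] = grid.layer(v) + disc[(g, v)] + delta
                for v in TEMPERATURE_RANGES:
                    f[v] = grid.layer(v) + disc[(g, v)] + RANGE_DELTA_SCALE * delta
                f["Log_PP"] = grid.layer("Log_PP") + disc[(g, "Log_PP")] - 0.03 * delta
                f["SSS"] = grid.layer("SSS").copy()
                fields[(g, rcp, dec)] = f
    return ScenarioSet(fields=fields, common=common, bias_maps=bias_maps, deltas=deltas, gcms=gcms)


# ----------------------------------------------------------------------
# EEZs and catch
# ----------------------------------------------------------------------
def make_eez_and_catch(
    domain_bounds: tuple[float, float, float, float],
    k: int = 4,
    seed: int = 0,
    species: list[str] | None = None,
):
    """Tile the domain into ``k`` latitude-band EEZ polygons and draw a
    per-(species, EEZ) mean-annual-catch table (t), with some entries
    below the 1000 t display threshold.

    Latitude bands cut the north–south coastal habitat strip into
    pieces, so every zone contains habitat cells — the way real EEZs
    partition a coastline."""
    if k < 2:
        raise ValueError("k must be at least 2")
    lon0, lon1, lat0, lat1 = map(float, domain_bounds)
    edges = np.linspace(lat0, lat1, k + 1)
    polygons = [(f"EEZ{i + 1}", box(lon0, edges[i], lon1, edges[i + 1])) for i in range(k)]

    rng = np.random.default_rng(seed)
    species = species or ["synthfish"]
    rows = []
    for sp in species:
        catches = 10 ** rng.uniform(2.0, 4.5, k)
        if (catches >= 1000).all():  # ensure the display filter is exercised
            catches[rng.integers(k)] = 10 ** rng.uniform(2.0, 2.9)
        for (eez_id, _), c in zip(polygons, catches):
            rows.append({"species": sp, "eez": eez_id, "catch_t": float(c)})
    return polygons, pd.DataFrame(rows)


def polygons_to_geojson(polygons, path) -> None:
    """Write (id, shapely polygon) pairs as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "properties": {"eez": eez_id},
            "geometry": mapping(poly),
        }
        for eez_id, poly in polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def polygons_from_geojson(path):
    """Read EEZ polygons back as (id, shapely geometry) pairs."""
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    return [(f["properties"]["eez"], shape(f["geometry"])) for f in gj["features"]]
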