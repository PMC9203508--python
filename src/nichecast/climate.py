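"""Future-field pre-treatment: regridding, decade averaging, Taylor
statistics and per-cell delta bias correction.

GCM output carries systematic per-cell biases relative to the observed
climatology.  The delta method removes them exactly on a common period:
``corrected_future = gcm_future + (obs_common − gcm_common)`` per cell,
which by construction leaves the simulated change signal
(``gcm_future − gcm_common``) untouched and makes the corrected
common-period field identical to the observations (r = 1, zero centred
RMSD, equal SD).  Temperature-derived variables are corrected
additively; primary production multiplicatively (a ratio in PP space,
equivalently an additive shift in Log_PP, with the ratio clamped to
[0.1, 10] to preserve positivity); salinity is held constant in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .grids import EnvGrid
from .synth import TEMPERATURE_VARIABLES, ScenarioSet

PP_RATIO_CLAMP = (0.1, 10.0)


# ----------------------------------------------------------------------
# regridding
# ----------------------------------------------------------------------
def regrid_bilinear(
    coarse_lon: np.ndarray,
    coarse_lat: np.ndarray,
    field: np.ndarray,
    target: EnvGrid,
) -> np.ndarray:
    """Bilinear interpolation of a coarse (lat, lon) field to the target
    grid's cell centres.  Target points beyond the coarse hull take the
    nearest edge value (no extrapolation); points farther than one
    coarse cell outside the coverage are an error.
    """
    coarse_lon = np.asarray(coarse_lon, dtype=float)
    coarse_lat = np.asarray(coarse_lat, dtype=float)
    dx = np.diff(coarse_lon).max() if coarse_lon.size > 1 else 0.0
    dy = np.diff(coarse_lat).max() if coarse_lat.size > 1 else 0.0
    if (
        target.lon.min() < coarse_lon.min() - dx
        or target.lon.max() > coarse_lon.max() + dx
        or target.lat.min() < coarse_lat.min() - dy
        or target.lat.max() > coarse_lat.max() + dy
    ):
        raise ValueError("target grid lies outside the coarse coverage by more than one cell")
    interp = RegularGridInterpolator(
        (coarse_lat, coarse_lon), np.asarray(field, dtype=float), method="linear"
    )
    # clipping the query coordinates into the coarse range = nearest-edge
    # behaviour for the (at most one-cell-wide) outside margin
    qlat = np.clip(target.lat, coarse_lat.min(), coarse_lat.max())
    qlon = np.clip(target.lon, coarse_lon.min(), coarse_lon.max())
    LAT, LON = np.meshgrid(qlat, qlon, indexing="ij")
    return interp(np.column_stack([LAT.ravel(), LON.ravel()])).reshape(target.ny, target.nx)


def decade_average(yearly_fields: dict[int, np.ndarray], decade: tuple[int, int]) -> np.ndarray:
    """Per-cell arithmetic mean over the ten years of a decade."""
    y0, y1 = decade
    years = range(y0, y1 + 1)
    missing = [y for y in years if y not in yearly_fields]
    if missing:
        raise ValueError(f"missing yearly fields for: {missing}")
    return np.mean([np.asarray(yearly_fields[y], dtype=float) for y in years], axis=0)


# ----------------------------------------------------------------------
# Taylor statistics
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class TaylorStats:
    """Field-agreement summary: Pearson r, centred RMSD (means removed),
    SD difference (model − obs) and mean bias (model − obs)."""

    r: float
    crmsd: float
    sd_diff: float
    bias: float


def taylor_stats(
    model_field: np.ndarray, obs_field: np.ndarray, mask: np.ndarray | None = None
) -> TaylorStats:
    m = np.asarray(model_field, dtype=float)
    o = np.asarray(obs_field, dtype=float)
    if mask is not None:
        m, o = m[mask], o[mask]
    else:
        m, o = m.ravel(), o.ravel()
    valid = np.isfinite(m) & np.isfinite(o)
    m, o = m[valid], o[valid]
    if m.size < 3:
        raise ValueError("need at least 3 common cells for Taylor statistics")
    bias = float(m.mean() - o.mean())
    mc, oc = m - m.mean(), o - o.mean()
    crmsd = float(np.sqrt(np.mean((mc - oc) ** 2)))
    sd_diff = float(m.std() - o.std())
    denom = m.std() * o.std()
    r = float(np.mean(mc * oc) / denom) if denom > 0 else float("nan")
    return TaylorStats(r=r, crmsd=crmsd, sd_diff=sd_diff, bias=bias)


# ----------------------------------------------------------------------
# delta correction
# ----------------------------------------------------------------------
def bias_correct(
    gcm_common: np.ndarray,
    gcm_future: np.ndarray,
    obs_common: np.ndarray,
) -> np.ndarray:
    """Per-cell delta correction (additive):
    ``corrected = gcm_future + (obs_common − gcm_common)``."""
    g0 = np.asarray(gcm_common, dtype=float)
    g1 = np.asarray(gcm_future, dtype=float)
    o = np.asarray(obs_common, dtype=float)
    if not (g0.shape == g1.shape == o.shape):
        raise ValueError("field shapes / masks do not match")
    return g1 + (o - g0)


def bias_correct_pp(
    gcm_common_logpp: np.ndarray,
    gcm_future_logpp: np.ndarray,
    obs_logpp: np.ndarray,
) -> np.ndarray:
    """Multiplicative delta correction for primary production, applied
    as an additive shift in log space with the implied PP ratio clamped
    to [0.1, 10]."""
    shift = np.asarray(obs_logpp, dtype=float) - np.asarray(gcm_common_logpp, dtype=float)
    lo, hi = np.log(PP_RATIO_CLAMP[0]), np.log(PP_RATIO_CLAMP[1])
    return np.asarray(gcm_future_logpp, dtype=float) + np.clip(shift, lo, hi)


def correct_scenarios(scen: ScenarioSet, obs: EnvGrid) -> ScenarioSet:
    """Delta-correct every (GCM, RCP, decade) field against the observed
    climatology: additive for temperature-derived variables,
    multiplicative for PP, and SSS copied unchanged from observations."""
    corrected: dict = {}
    for key, f in scen.fields.items():
        g = key[0]
        out: dict[str, np.ndarray] = {}
        for v in TEMPERATURE_VARIABLES:
            out[v] = bias_correct(scen.common[g][v], f[v], obs.layer(v))
        out["Log_PP"] = bias_correct_pp(scen.common[g]["Log_PP"], f["Log_PP"], obs.layer("Log_PP"))
        out["SSS"] = obs.layer("SSS").copy()
        corrected[key] = out
    corrected_common = {
        g: {v: bias_correct(c[v], c[v], obs.layer(v)) for v in TEMPERATURE_VARIABLES}
        for g, c in scen.common.items()
    }
    return ScenarioSet(
        fields=corrected,
        common=corrected_common,
        bias_maps=scen.bias_maps,
        deltas=scen.deltas,
        gcms=scen.gcms,
    )
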