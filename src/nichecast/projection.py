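"""Ensemble suitability maps, difference maps and range-change summaries.

A *member* is one (algorithm, cross-validation run[, GCM]) prediction on
every valid grid cell; the ensemble map is the unweighted member mean
and the per-cell member standard deviation quantifies inter-simulation
divergence.  Contemporary maps average |retained| × 10 members; future
maps additionally span the 5 GCMs, i.e. 50 members per retained
algorithm.  "Suitable habitat" for area bookkeeping is ESI above a
configurable threshold (0.5 by default, with a 0.3/0.5/0.7 sensitivity
sweep), and areas use latitude-corrected cell sizes in km².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import CVRun, member_sd
from .grids import EnvGrid

AREA_THRESHOLD = 0.5
THRESHOLD_SWEEP = (0.3, 0.5, 0.7)


@dataclass
class SuitabilityMap:
    """Per-cell ensemble-mean ESI and member SD on the valid-cell mask."""

    esi: np.ndarray  # (ny, nx), NaN outside mask
    sd: np.ndarray
    mask: np.ndarray  # bool (ny, nx): marine cells passing depth/coast
    member_count: int
    provenance: dict = field(default_factory=dict)


def _env_table(env: EnvGrid | dict[str, np.ndarray], grid: EnvGrid, variables, mask):
    iy, ix = np.nonzero(mask)
    data = {}
    for v in variables:
        layer = env.layer(v) if isinstance(env, EnvGrid) else env[v]
        data[v] = np.asarray(layer)[iy, ix]
    return pd.DataFrame(data)


def project_ensemble(
    cv_runs: list[CVRun],
    retained: list[str],
    env: EnvGrid | dict[str, np.ndarray] | list,
    grid: EnvGrid,
    mask: np.ndarray,
    provenance: dict | None = None,
) -> SuitabilityMap:
    """Predict every ensemble member on the valid cells and average.

    ``env`` is either a single environment (contemporary: members =
    retained × runs) or a list of environments, one per GCM (future:
    members = retained × runs × GCMs).
    """
    if not retained:
        raise ValueError("no retained algorithms")
    envs = env if isinstance(env, list) else [env]
    variables = None
    members = []
    for e in envs:
        tab = None
        for run in cv_runs:
            for alg in retained:
                model = run.models[alg]
                if variables is None:
                    variables = model.variables
                    missing = [
                        v
                        for v in variables
                        if (v not in (e.variables if isinstance(e, EnvGrid) else e))
                    ]
                    if missing:
                        raise ValueError(f"covariates missing from environment: {missing}")
                if tab is None:
                    tab = _env_table(e, grid, variables, mask)
                members.append(model.predict_esi(tab))
    stack = np.asarray(members)
    mean_flat = stack.mean(axis=0)
    sd_flat = member_sd(stack) if stack.shape[0] > 1 else np.zeros_like(mean_flat)
    esi = np.full(mask.shape, np.nan)
    sd = np.full(mask.shape, np.nan)
    esi[mask] = mean_flat
    sd[mask] = sd_flat
    return SuitabilityMap(
        esi=esi,
        sd=sd,
        mask=mask,
        member_count=stack.shape[0],
        provenance=provenance or {},
    )


def diff_map(future: SuitabilityMap, contemporary: SuitabilityMap) -> np.ndarray:
    """Per-cell future − contemporary ESI, in [−1, 1]."""
    if future.esi.shape != contemporary.esi.shape or not np.array_equal(
        future.mask, contemporary.mask
    ):
        raise ValueError("maps are on mismatched grids/masks")
    return future.esi - contemporary.esi


def suitable_area(smap: SuitabilityMap, grid: EnvGrid, threshold: float = AREA_THRESHOLD) -> float:
    """Total area (km²) of valid cells with ESI ≥ threshold, using
    latitude-corrected cell areas."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    areas = grid.cell_area_km2()
    sel = smap.mask & (smap.esi >= threshold)
    return float(areas[sel].sum())


def range_change(contemporary_area: float, future_area: float) -> float:
    """Signed percentage change in suitable area (negative = loss)."""
    if contemporary_area <= 0:
        raise ValueError("contemporary suitable area is zero; change undefined")
    return 100.0 * (future_area - contemporary_area) / contemporary_area


def esi_centroid(smap: SuitabilityMap, grid: EnvGrid) -> tuple[float, float]:
    """ESI-weighted (lon, lat) centroid of suitability over valid cells."""
    iy, ix = np.nonzero(smap.mask)
    w = smap.esi[iy, ix]
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total suitability")
    return float((grid.lon[ix] * w).sum() / total), float((grid.lat[iy] * w).sum() / total)


def range_change_table(
    contemporary: SuitabilityMap,
    future_maps: dict[tuple[float, str], SuitabilityMap],
    grid: EnvGrid,
    thresholds=THRESHOLD_SWEEP,
    species: str = "synthfish",
) -> pd.DataFrame:
    """Species × RCP × decade matrix of suitable-area change (%) at each
    threshold of the sensitivity sweep."""
    rows = []
    for thr in thresholds:
        base = suitable_area(contemporary, grid, thr)
        for (rcp, decade), smap in future_maps.items():
            fut = suitable_area(smap, grid, thr)
            rows.append(
                {
                    "species": species,
                    "rcp": rcp,
                    "decade": decade,
                    "threshold": thr,
                    "contemporary_km2": base,
                    "future_km2": fut,
                    "change_pct": range_change(base, fut) if base > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
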