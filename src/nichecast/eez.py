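"""Aggregation of suitability to Exclusive Economic Zones.

EEZs are the management units: per-zone ESI is the unweighted mean over
the valid marine cells whose *centres* fall inside the polygon, and the
mean annual catch (t) is attached in log₁₀ for display — zones landing
less than 1000 t/yr are flagged as excluded from display but retained
in the data.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely

from .grids import EnvGrid
from .projection import SuitabilityMap

MIN_CATCH_T = 1000.0


def esi_by_eez(
    smap: SuitabilityMap, grid: EnvGrid, polygons: list[tuple[str, "shapely.Geometry"]]
) -> pd.DataFrame:
    """Mean ESI per EEZ over valid cells with centres inside the polygon.

    A strict point-in-polygon test on cell centres assigns each cell to
    at most one zone of a tiling; zones containing no valid cell get a
    missing value with a warning.
    """
    if not polygons:
        raise ValueError("no EEZ polygons supplied")
    iy, ix = np.nonzero(smap.mask)
    x, y = grid.lon[ix], grid.lat[iy]
    esi = smap.esi[iy, ix]
    rows = []
    for eez_id, poly in polygons:
        inside = shapely.contains_xy(poly, x, y)
        if not inside.any():
            warnings.warn(f"EEZ {eez_id}: no valid cells; ESI undefined")
            rows.append({"eez": eez_id, "mean_esi": np.nan, "n_cells": 0})
        else:
            rows.append(
                {"eez": eez_id, "mean_esi": float(esi[inside].mean()), "n_cells": int(inside.sum())}
            )
    return pd.DataFrame(rows)


def attach_catch(
    summaries: pd.DataFrame,
    catch_table: pd.DataFrame,
    species: str,
    min_catch: float = MIN_CATCH_T,
) -> pd.DataFrame:
    """Join log₁₀ mean annual catch onto per-EEZ summaries.

    Catches below ``min_catch`` are flagged ``below_display_threshold``
    (kept in the data); EEZs with no catch entry get missing values with
    a warning, never zero.
    """
    sub = catch_table[catch_table["species"] == species][["eez", "catch_t"]]
    if (sub["catch_t"] < 0).any():
        raise ValueError("catches must be non-negative")
    out = summaries.merge(sub, on="eez", how="left")
    unmatched = out["catch_t"].isna()
    if unmatched.any():
        warnings.warn(
            f"no catch entry for EEZ(s): {sorted(out.loc[unmatched, 'eez'])}; left missing"
        )
    with np.errstate(divide="ignore"):
        out["log10_catch"] = np.log10(out["catch_t"])
    out["below_display_threshold"] = out["catch_t"] < min_catch
    return out


def plot_eez_bars(summary: pd.DataFrame, future_col: str, contemporary_col: str, ax=None):
    """Fig-5-style bars: per-EEZ future ESI (0–1 bars) with the
    contemporary value as a horizontal line; zones below the catch
    display threshold are dropped."""
    import matplotlib.pyplot as plt

    shown = summary[~summary.get("below_display_threshold", False)]
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * len(shown), 3))
    x = np.arange(len(shown))
    ax.bar(x, shown[future_col], color="tab:orange", label="future")
    for xi, c in zip(x, shown[contemporary_col]):
        ax.hlines(c, xi - 0.4, xi + 0.4, color="black")
    ax.set_xticks(x, shown["eez"], rotation=45)
    ax.set_ylim(0, 1)
    ax.set_ylabel("ESI")
    return ax
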