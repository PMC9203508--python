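"""Regular lat/lon environmental grids.

The whole pipeline works on a single regular grid of square (in degrees)
cells, by default 0.1° × 0.1°, holding named environmental layers
(sea-bottom/surface temperature statistics, salinity, log primary
production, bathymetry, distance-to-coast).  :class:`EnvGrid` is a thin
wrapper around an :class:`xarray.Dataset` that adds the cell bookkeeping
the analysis needs: half-open cell membership, flat cell ids, marine
masks and latitude-corrected cell areas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

# km per degree of latitude (and of longitude at the equator)
KM_PER_DEG = 111.195


class EnvGrid:
    """Stack of named environmental layers on a regular lat/lon grid.

    Parameters
    ----------
    ds : xarray.Dataset
        Dataset with 1-D ``lon`` and ``lat`` coordinates (cell centres,
        evenly spaced) and 2-D ``(lat, lon)`` data variables.
    """

    def __init__(self, ds: xr.Dataset):
        if "lon" not in ds.coords or "lat" not in ds.coords:
            raise ValueError("dataset must carry 'lon' and 'lat' coordinates")
        self.ds = ds
        lon = ds["lon"].values
        lat = ds["lat"].values
        if lon.size > 1:
            steps = np.diff(lon)
            if not np.allclose(steps, steps[0]):
                raise ValueError("lon coordinate is not evenly spaced")
        if lat.size > 1:
            steps = np.diff(lat)
            if not np.allclose(steps, steps[0]):
                raise ValueError("lat coordinate is not evenly spaced")

    # ------------------------------------------------------------------
    # basic geometry
    # ------------------------------------------------------------------
    @property
    def lon(self) -> np.ndarray:
        return self.ds["lon"].values

    @property
    def lat(self) -> np.ndarray:
        return self.ds["lat"].values

    @property
    def nx(self) -> int:
        return self.lon.size

    @property
    def ny(self) -> int:
        return self.lat.size

    @property
    def cell_size(self) -> float:
        lon = self.lon
        return float(lon[1] - lon[0]) if lon.size > 1 else float(self.lat[1] - self.lat[0])

    @property
    def west_edge(self) -> float:
        return float(self.lon[0] - self.cell_size / 2)

    @property
    def south_edge(self) -> float:
        return float(self.lat[0] - self.cell_size / 2)

    @property
    def variables(self) -> list[str]:
        return list(self.ds.data_vars)

    def layer(self, name: str) -> np.ndarray:
        """Return a layer as a ``(ny, nx)`` array."""
        return self.ds[name].values

    def with_layers(self, layers: dict[str, np.ndarray]) -> "EnvGrid":
        """New grid sharing coordinates, with variables replaced/added."""
        ds = self.ds.copy()
        for name, arr in layers.items():
            ds[name] = (("lat", "lon"), np.asarray(arr, dtype=float))
        return EnvGrid(ds)

    # ------------------------------------------------------------------
    # cell bookkeeping
    # ------------------------------------------------------------------
    def cell_indices(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map points to (iy, ix); half-open cells [edge, edge + cell)."""
        cs = self.cell_size
        ix = np.floor((np.asarray(lon) - self.west_edge) / cs).astype(int)
        iy = np.floor((np.asarray(lat) - self.south_edge) / cs).astype(int)
        return iy, ix

    def in_domain(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        iy, ix = self.cell_indices(lon, lat)
        return (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)

    def flat_id(self, iy: np.ndarray, ix: np.ndarray) -> np.ndarray:
        return np.asarray(iy) * self.nx + np.asarray(ix)

    def unravel(self, cell_id: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cell_id = np.asarray(cell_id)
        return cell_id // self.nx, cell_id % self.nx

    def cell_centers(self, cell_id: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        iy, ix = self.unravel(cell_id)
        return self.lon[ix], self.lat[iy]

    @property
    def marine_mask(self) -> np.ndarray:
        """Boolean (ny, nx) mask of sea cells (bathymetry < 0)."""
        return self.layer("bathymetry") < 0

    def cell_area_km2(self) -> np.ndarray:
        """Per-cell area (km²): (111.195·Δ)·(111.195·Δ·cos φ) at cell-centre φ."""
        cs = self.cell_size
        dy = KM_PER_DEG * cs
        dx = KM_PER_DEG * cs * np.cos(np.deg2rad(self.lat))
        return np.broadcast_to((dy * dx)[:, None], (self.ny, self.nx)).copy()

    def table(
        self,
        variables: list[str] | None = None,
        mask: np.ndarray | None = None,
    ) -> pd.DataFrame:
        """Flatten layers to a DataFrame with cell_id, lon, lat and one
        column per variable; optionally restricted to True cells of ``mask``."""
        variables = variables if variables is not None else self.variables
        if mask is None:
            mask = np.ones((self.ny, self.nx), dtype=bool)
        iy, ix = np.nonzero(mask)
        out = pd.DataFrame(
            {
                "cell_id": self.flat_id(iy, ix),
                "lon": self.lon[ix],
                "lat": self.lat[iy],
            }
        )
        for v in variables:
            out[v] = self.layer(v)[iy, ix]
        return out

    # ------------------------------------------------------------------
    # I/O
    # ------------------------------------------------------------------
    def to_netcdf(self, path) -> None:
        """Write as NetCDF (classic format, CF-style cell-centre coords)."""
        ds = self.ds.copy()
        ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
        ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EnvGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls(ds.load())


def write_ascii_grid(path, grid: EnvGrid, layer: str, nodata: float = -9999.0) -> None:
    """Export one layer as an ESRI ASCII grid (plain-text raster)."""
    arr = np.array(grid.layer(layer), dtype=float)
    arr = np.where(np.isfinite(arr), arr, nodata)
    header = (
        f"ncols {grid.nx}\n"
        f"nrows {grid.ny}\n"
        f"xllcorner {grid.west_edge}\n"
        f"yllcorner {grid.south_edge}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grids are stored north-to-south
        np.savetxt(fh, arr[::-1], fmt="%.6g")
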