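"""Environmental space: variable selection, presence thinning,
percentile-trimmed convex hull and pseudo-absence sampling.

Presence-only records over-represent heavily surveyed environments, so
presences are thinned to one observation per cell of a coarse grid in
*environmental* space (0.5 °C for temperature variables, 0.5 psu for
salinity, 0.5 log-units for primary production).  Pseudo-absences are
then drawn from the realized environments of candidate marine cells
lying *outside* the smallest convex hull of the thinned presences after
each variable has been trimmed to its [2.5, 97.5] percentile interval —
so first-record extremes do not inflate the presumed suitable volume.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .grids import EnvGrid
from .occurrences import OccurrenceSet

#: default environmental-filter bin widths
DEFAULT_RESOLUTIONS = {
    "SBT": 0.5,
    "SBTr": 0.5,
    "SBTvar": 0.5,
    "SST": 0.5,
    "SSTr": 0.5,
    "SSTvar": 0.5,
    "SSS": 0.5,
    "Log_PP": 0.5,
}

CORRELATION_THRESHOLD = 0.7


def select_uncorrelated_variables(
    env: pd.DataFrame,
    priority: list[str],
    threshold: float = CORRELATION_THRESHOLD,
) -> list[str]:
    """Greedy correlation pruning in priority order.

    Walk the candidate variables in ``priority`` order and keep one iff
    its absolute Pearson correlation with every already-kept variable is
    <= ``threshold`` (computed at presence cells).  Constant variables
    have undefined correlation and are excluded with a warning.
    """
    if len(priority) < 2:
        raise ValueError("need at least two candidate variables")
    if len(env) < 3:
        raise ValueError("need at least three presence cells to estimate correlations")
    kept: list[str] = []
    for v in priority:
        x = env[v].values.astype(float)
        if np.std(x) == 0:
            warnings.warn(f"variable {v!r} is constant at presences; excluded")
            continue
        ok = True
        for k in kept:
            r = np.corrcoef(x, env[k].values.astype(float))[0, 1]
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            kept.append(v)
    return kept


def environmental_filter(
    presences: OccurrenceSet | pd.DataFrame,
    grid: EnvGrid,
    variables: list[str],
    resolutions: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Thin presences to one per occupied environmental-space bin.

    The selected variables' axes are partitioned into bins of the stated
    widths; within each occupied bin exactly one presence is retained —
    the one with the most recent record year, ties broken by lowest cell
    id, so the pick is deterministic and order-invariant.

    Returns a DataFrame with cell_id, lon, lat, last_year and the
    variable columns of the retained presences.
    """
    res = dict(DEFAULT_RESOLUTIONS if resolutions is None else resolutions)
    for v in variables:
        if res.get(v, 0) <= 0:
            raise ValueError(f"non-positive bin width for {v!r}")

    if isinstance(presences, OccurrenceSet):
        iy, ix = grid.unravel(presences.cells)
        tab = pd.DataFrame(
            {
                "cell_id": presences.cells,
                "lon": grid.lon[ix],
                "lat": grid.lat[iy],
            }
        )
        for v in variables:
            tab[v] = grid.layer(v)[iy, ix]
        prov = presences.provenance.set_index("cell_id")["last_year"]
        tab["last_year"] = prov.reindex(tab["cell_id"]).values
    else:
        tab = presences.copy()
        if "last_year" not in tab.columns:
            tab["last_year"] = np.nan

    missing = tab[variables].isna().any(axis=1)
    if missing.any():
        warnings.warn(f"{int(missing.sum())} presences with missing covariates excluded")
        tab = tab[~missing]

    for v in variables:
        tab[f"_bin_{v}"] = np.floor(tab[v].values / res[v]).astype(int)
    bin_cols = [f"_bin_{v}" for v in variables]
    # deterministic pick: most recent year first (NaN last), then lowest cell id
    tab = tab.sort_values(
        ["last_year", "cell_id"], ascending=[False, True], na_position="last"
    )
    out = tab.drop_duplicates(subset=bin_cols, keep="first")
    out = out.drop(columns=bin_cols).sort_values("cell_id").reset_index(drop=True)
    return out


class TrimmedHull:
    """Convex hull of presence environments after per-variable
    percentile trimming.

    Points falling outside any per-variable [lower, upper] percentile
    interval are discarded; the hull is the convex hull of the
    survivors.  Membership uses facet half-space tests with a small
    tolerance, so boundary points count as inside.  Degenerate
    (lower-dimensional) point sets fall back to an axis-aligned
    bounding-box test with a warning.
    """

    def __init__(
        self,
        points: pd.DataFrame | np.ndarray,
        variables: list[str] | None = None,
        lower: float = 2.5,
        upper: float = 97.5,
        tol: float = 1e-9,
    ):
        if isinstance(points, pd.DataFrame):
            variables = variables or [c for c in points.columns if c not in ("cell_id", "lon", "lat", "last_year")]
            pts = points[variables].values.astype(float)
        else:
            pts = np.asarray(points, dtype=float)
            variables = variables or [f"x{i}" for i in range(pts.shape[1])]
        self.variables = list(variables)
        self.tol = tol
        self.lower, self.upper = lower, upper

        lo = np.percentile(pts, lower, axis=0)
        hi = np.percentile(pts, upper, axis=0)
        keep = ((pts >= lo) & (pts <= hi)).all(axis=1)
        trimmed = pts[keep]
        d = trimmed.shape[1]
        if trimmed.shape[0] < d + 1:
            raise ValueError("not enough points after trimming to build a hull")
        self.points = trimmed
        self.bounds = (trimmed.min(axis=0), trimmed.max(axis=0))
        try:
            self._hull = ConvexHull(trimmed)
        except QhullError:
            warnings.warn("degenerate point set; falling back to bounding-box membership")
            self._hull = None

    @property
    def volume(self) -> float:
        if self._hull is None:
            lo, hi = self.bounds
            return float(np.prod(hi - lo))
        return float(self._hull.volume)

    @property
    def equations(self) -> np.ndarray | None:
        return None if self._hull is None else self._hull.equations

    def contains(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Vectorized membership (boundary counts as inside)."""
        if isinstance(x, pd.DataFrame):
            x = x[self.variables].values
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if self._hull is None:
            lo, hi = self.bounds
            return ((x >= lo - self.tol) & (x <= hi + self.tol)).all(axis=1)
        eq = self._hull.equations  # A x + b <= 0 inside
        return (x @ eq[:, :-1].T + eq[:, -1] <= self.tol).all(axis=1)


class PseudoAbsenceError(ValueError):
    pass


def sample_pseudo_absences(
    hull: TrimmedHull,
    n: int,
    sampling_domain: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``n`` pseudo-absences uniformly without replacement from the
    rows of ``sampling_domain`` (realized environments of candidate
    marine cells) that lie strictly outside the hull."""
    outside = ~hull.contains(sampling_domain)
    pool = sampling_domain[outside]
    if len(pool) < n:
        raise PseudoAbsenceError(
            f"need {n} pseudo-absences but only {len(pool)} candidate points lie "
            f"outside the trimmed hull (short by {n - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(pool), size=n, replace=False)
    return pool.iloc[np.sort(pick)].reset_index(drop=True)


def build_pa_table(
    filtered_presences: pd.DataFrame,
    pseudo_absences: pd.DataFrame,
    variables: list[str],
) -> pd.DataFrame:
    """Assemble the model-ready table: label 1 presences on top of label
    0 pseudo-absences, in exactly equal numbers."""
    if len(filtered_presences) != len(pseudo_absences):
        raise ValueError("presences and pseudo-absences must be equal in number")
    cols = ["cell_id", "lon", "lat"] + list(variables)
    pres = filtered_presences[cols].copy()
    pres.insert(0, "label", 1)
    absn = pseudo_absences[cols].copy()
    absn.insert(0, "label", 0)
    return pd.concat([pres, absn], ignore_index=True)
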