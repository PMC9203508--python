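"""Shared fixtures: a small synthetic world for unit tests and one
full-scale fitted ensemble (the expensive object) shared by the
acceptance checks."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from nichecast import envspace as es
from nichecast import occurrences as occ
from nichecast import synth
from nichecast.ensemble import EnsembleSDM

PRIORITY = ["SBT", "SBTr", "Log_PP", "SBTvar", "SST", "SSTr", "SSTvar", "SSS"]


@pytest.fixture(scope="session")
def small_grid():
    """50×50-cell world (5°×5° at 0.1°)."""
    return synth.make_env_grid((0.0, 5.0, 40.0, 45.0), 0.1, seed=7)


@pytest.fixture(scope="session")
def truth():
    return synth.default_truth()


@pytest.fixture
def toy_table():
    """Linearly separable presence/absence toy problem: presences cold
    (SBT≈15), absences warm (SBT≈25)."""
    rng = np.random.default_rng(42)
    n = 40
    pres = pd.DataFrame(
        {
            "label": 1,
            "SBT": rng.normal(15, 0.7, n),
            "SBTr": rng.normal(5, 0.7, n),
        }
    )
    absn = pd.DataFrame(
        {
            "label": 0,
            "SBT": rng.normal(25, 0.7, n),
            "SBTr": rng.normal(5, 0.7, n),
        }
    )
    return pd.concat([pres, absn], ignore_index=True)


@pytest.fixture(scope="session")
def fitted_world(truth):
    """Full study-condition world: n = 1000 presences over the default
    domain, cleaned, thinned, paired with pseudo-absences, and the
    8-algorithm ensemble fitted with 10×70/30 cross-validation."""
    grid = synth.make_env_grid(seed=1)
    effort = synth.coastal_effort(grid) * synth.depth_affinity(grid)
    raw = synth.sample_occurrences(grid, truth, 1000, effort, seed=2)
    clean = occ.clean_occurrences(raw, grid)
    oset = occ.grid_occurrences(clean, grid)
    depth = occ.DepthRange(150, 1000)
    keep = occ.apply_depth_coast_filter(oset, depth, grid)
    oset = occ.OccurrenceSet(
        oset.species, oset.cells[keep], oset.provenance[oset.provenance.cell_id.isin(oset.cells[keep])]
    )
    iy, ix = grid.unravel(oset.cells)
    env = pd.DataFrame({v: grid.layer(v)[iy, ix] for v in PRIORITY})
    variables = es.select_uncorrelated_variables(env, PRIORITY)
    filtered = es.environmental_filter(oset, grid, variables)
    hull = es.TrimmedHull(filtered, variables)
    mask = occ.depth_coast_mask(grid, depth)
    domain = grid.table(variables, mask=mask)
    pa = es.sample_pseudo_absences(hull, len(filtered), domain, seed=5)
    table = es.build_pa_table(filtered, pa, variables)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = EnsembleSDM(table, variables, seed=11).fit()
    return {
        "grid": grid,
        "truth": truth,
        "raw": raw,
        "occurrences": oset,
        "variables": variables,
        "filtered": filtered,
        "hull": hull,
        "mask": mask,
        "table": table,
        "results": results,
    }


@pytest.fixture(scope="session")
def scenario_world(fitted_world):
    """Corrected GCM scenario fields on the fitted world's grid."""
    from nichecast import climate as clim

    scen = synth.make_scenarios(fitted_world["grid"], seed=3)
    return {"scenarios": scen, "corrected": clim.correct_scenarios(scen, fitted_world["grid"])}
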