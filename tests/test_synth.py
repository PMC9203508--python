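"""Synthetic world generator: geometry, determinism, sampler and
scenario structure."""

import numpy as np
import pytest
from scipy.stats import chisquare

from nichecast import synth
from nichecast.grids import EnvGrid


class TestEnvGrid:
    def test_cell_arithmetic(self):
        g = synth.make_env_grid((0, 10, 30, 40), 0.1, seed=0)
        assert (g.ny, g.nx) == (100, 100)
        assert g.layer("SBT").shape == (100, 100)

    def test_determinism(self, small_grid):
        g2 = synth.make_env_grid((0.0, 5.0, 40.0, 45.0), 0.1, seed=7)
        for v in small_grid.variables:
            np.testing.assert_array_equal(small_grid.layer(v), g2.layer(v))

    def test_sbt_decreases_poleward(self, small_grid):
        sbt = np.where(small_grid.marine_mask, small_grid.layer("SBT"), np.nan)
        south = np.nanmean(sbt[:5])
        north = np.nanmean(sbt[-5:])
        assert south > north

    def test_field_signs(self, small_grid):
        m = small_grid.marine_mask
        assert (small_grid.layer("bathymetry")[m] < 0).all()
        assert (small_grid.layer("dist_coast") >= 0).all()
        assert (small_grid.layer("SBTr")[m] > 0).all()

    def test_sbtr_sbtvar_collinear(self, small_grid):
        m = small_grid.marine_mask
        r = np.corrcoef(small_grid.layer("SBTr")[m], small_grid.layer("SBTvar")[m])[0, 1]
        assert r > 0.7  # exercises the correlation-pruning rule downstream

    def test_bad_cell_size(self):
        with pytest.raises(ValueError):
            synth.make_env_grid((0, 10, 30, 40), -0.1)
        with pytest.raises(ValueError):
            synth.make_env_grid((0, 10, 30, 40), 0.3)

    def test_netcdf_roundtrip(self, small_grid, tmp_path):
        path = tmp_path / "grid.nc"
        small_grid.to_netcdf(path)
        back = EnvGrid.from_netcdf(path)
        np.testing.assert_allclose(back.layer("SBT"), small_grid.layer("SBT"))
        np.testing.assert_allclose(back.lat, small_grid.lat)


class TestNicheTruth:
    def test_bounds_and_monotone_decline(self, truth, small_grid):
        env = small_grid.table(truth.variables, mask=small_grid.marine_mask)
        s = truth.suitability(env)
        assert ((s >= 0) & (s <= 1)).all()
        # transect away from the optimum in a single variable
        sbt = np.linspace(truth.optima["SBT"], truth.optima["SBT"] + 10, 50)
        env1 = {v: np.full(50, truth.optima[v]) for v in truth.variables}
        env1["SBT"] = sbt
        s1 = truth.suitability(env1)
        assert (np.diff(s1) < 0).all()
        assert s1[0] == pytest.approx(1.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            synth.NicheTruth({"SBT": 15}, {"SBT": -1})
        with pytest.raises(ValueError):
            synth.NicheTruth({"SBT": 15}, {"SBTr": 1})


class TestSampler:
    def test_uniform_truth_uniform_effort(self, small_grid):
        """With flat suitability and flat effort, occupancy is uniform
        over marine cells (chi-square GOF on a coarse partition)."""
        flat = synth.NicheTruth(
            {"SBT": 15.0}, {"SBT": 1e6}
        )  # tol → ∞: suitability ≈ 1 everywhere
        rec = synth.sample_occurrences(
            small_grid, flat, 2000, noise=synth.NoiseSpec(0, 0, 0, 0, 0), seed=3
        )
        # partition marine cells into 10 longitude bands, weight by counts
        iy, ix = small_grid.cell_indices(rec["lon"].values, rec["lat"].values)
        band = ix // 5
        counts = np.bincount(band, minlength=10)
        marine_per_band = np.array(
            [small_grid.marine_mask[:, 5 * b : 5 * (b + 1)].sum() for b in range(10)]
        )
        expected = len(rec) * marine_per_band / marine_per_band.sum()
        _, p = chisquare(counts, expected)
        assert p > 0.01

    def test_duplicate_injection(self, small_grid, truth):
        rec = synth.sample_occurrences(
            small_grid, truth, 1000, noise=synth.NoiseSpec(0.1, 0, 0, 0, 0), seed=4
        )
        assert len(rec) == 1100
        assert rec.duplicated(subset=["lon", "lat", "year"]).sum() == 100

    def test_zero_suitability_cells_empty(self, small_grid):
        narrow = synth.NicheTruth({"SBT": 19.0}, {"SBT": 0.5})
        rec = synth.sample_occurrences(
            small_grid, narrow, 500, noise=synth.NoiseSpec(0, 0, 0, 0, 0), seed=5
        )
        iy, ix = small_grid.cell_indices(rec["lon"].values, rec["lat"].values)
        sbt = small_grid.layer("SBT")[iy, ix]
        s = narrow.suitability({"SBT": sbt})
        assert (s > 1e-12).all()

    def test_year_mix(self, small_grid, truth):
        rec = synth.sample_occurrences(small_grid, truth, 4000, seed=6)
        undated = rec["year"].isna().mean()
        pre = (rec["year"] < 1990).mean()
        assert undated == pytest.approx(0.1637, abs=0.03)
        assert pre == pytest.approx(0.1079, abs=0.03)

    def test_all_zero_weights_error(self, small_grid):
        far = synth.NicheTruth({"SBT": 300.0}, {"SBT": 0.1})
        with pytest.raises(ValueError, match="zero"):
            synth.sample_occurrences(small_grid, far, 10, seed=0)


class TestScenarios:
    def test_counts(self, small_grid):
        scen = synth.make_scenarios(small_grid, seed=9)
        assert len(scen.fields) == 45  # 5 GCMs × 3 RCPs × 3 decades
        assert len(scen.common) == 5

    def test_identity_without_perturbation(self, small_grid):
        scen = synth.make_scenarios(small_grid, bias_sd=0.0, noise_sd=0.0, seed=9)
        np.testing.assert_allclose(scen.common[1]["SBT"], small_grid.layer("SBT"))
        zero = {k: 0.0 for k in synth.DEFAULT_DELTAS}
        scen0 = synth.make_scenarios(small_grid, 0.0, 0.0, deltas=zero, seed=9)
        np.testing.assert_allclose(
            scen0.fields[(1, 8.5, "2090-2099")]["SBT"], small_grid.layer("SBT")
        )

    def test_end_of_century_delta(self, small_grid):
        """Domain-mean SBT warming ≈ +3.2 °C under RCP8.5 by the 2090s."""
        scen = synth.make_scenarios(small_grid, bias_sd=0.0, noise_sd=0.0, seed=9)
        d = scen.fields[(1, 8.5, "2090-2099")]["SBT"] - small_grid.layer("SBT")
        assert d[small_grid.marine_mask].mean() == pytest.approx(3.2, abs=1e-9)

    def test_rcp_monotonicity(self, small_grid):
        scen = synth.make_scenarios(small_grid, seed=9)
        m = small_grid.marine_mask
        for g in scen.gcms:
            for dec in synth.DECADES:
                means = [scen.fields[(g, rcp, dec)]["SBT"][m].mean() for rcp in synth.RCPS]
                assert means[0] <= means[1] <= means[2]

    def test_missing_delta_error(self, small_grid):
        bad = dict(synth.DEFAULT_DELTAS)
        bad.pop((4.5, "2050-2059"))
        with pytest.raises(ValueError, match="missing delta"):
            synth.make_scenarios(small_grid, deltas=bad, seed=0)

    def test_sss_constant(self, small_grid):
        scen = synth.make_scenarios(small_grid, seed=9)
        np.testing.assert_array_equal(
            scen.fields[(2, 8.5, "2090-2099")]["SSS"], small_grid.layer("SSS")
        )


class TestEEZ:
    def test_tiling(self, small_grid):
        polys, catch = synth.make_eez_and_catch((0.0, 5.0, 40.0, 45.0), k=4, seed=1)
        assert len(polys) == 4
        for i in range(4):
            for j in range(i + 1, 4):
                assert polys[i][1].intersection(polys[j][1]).area == pytest.approx(0.0)

    def test_marine_coverage(self, small_grid):
        """Every marine cell centre lies in exactly one polygon; the
        union covers ≥ 95% of marine cells."""
        import shapely

        polys, _ = synth.make_eez_and_catch((0.0, 5.0, 40.0, 45.0), k=4, seed=1)
        iy, ix = np.nonzero(small_grid.marine_mask)
        x, y = small_grid.lon[ix], small_grid.lat[iy]
        membership = np.zeros(len(x), dtype=int)
        for _, poly in polys:
            membership += shapely.contains_xy(poly, x, y).astype(int)
        assert membership.max() <= 1
        assert (membership == 1).mean() >= 0.95

    def test_catch_below_threshold_present(self):
        _, catch = synth.make_eez_and_catch((0, 5, 40, 45), k=4, seed=1)
        assert (catch["catch_t"] < 1000).any()

    def test_k_validation(self):
        with pytest.raises(ValueError):
            synth.make_eez_and_catch((0, 5, 40, 45), k=1)

    def test_geojson_roundtrip(self, tmp_path):
        polys, _ = synth.make_eez_and_catch((0, 5, 40, 45), k=3, seed=2)
        synth.polygons_to_geojson(polys, tmp_path / "eez.geojson")
        back = synth.polygons_from_geojson(tmp_path / "eez.geojson")
        assert [pid for pid, _ in back] == [pid for pid, _ in polys]
        assert back[0][1].equals_exact(polys[0][1], 1e-9)
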