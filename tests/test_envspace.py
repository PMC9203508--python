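"""Variable pruning, environmental thinning, trimmed hull and
pseudo-absence sampling."""

import numpy as np
import pandas as pd
import pytest

from nichecast import envspace as es


class TestVariableSelection:
    def make_env(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        return rng, a

    def test_correlated_pair_pruned(self):
        rng, a = self.make_env()
        # r ≈ 0.80, as between the two bottom-temperature variability proxies
        b = 0.8 * a + np.sqrt(1 - 0.8**2) * rng.normal(size=len(a))
        env = pd.DataFrame({"SBTr": a, "SBTvar": b})
        assert abs(np.corrcoef(a, b)[0, 1]) > 0.7
        kept = es.select_uncorrelated_variables(env, ["SBTr", "SBTvar"])
        assert kept == ["SBTr"]  # higher-priority one wins

    def test_uncorrelated_all_kept(self):
        rng, a = self.make_env()
        env = pd.DataFrame({"x": a, "y": rng.normal(size=len(a)), "z": rng.normal(size=len(a))})
        assert es.select_uncorrelated_variables(env, ["x", "y", "z"]) == ["x", "y", "z"]

    def test_three_mutually_correlated_keep_one(self):
        rng, a = self.make_env()
        env = pd.DataFrame(
            {
                "x": a,
                "y": 0.95 * a + 0.05 * rng.normal(size=len(a)),
                "z": 0.95 * a + 0.05 * rng.normal(size=len(a)),
            }
        )
        corr = env.corr().values
        assert (np.abs(corr[np.triu_indices(3, 1)]) > 0.9).all()
        assert es.select_uncorrelated_variables(env, ["x", "y", "z"]) == ["x"]

    def test_constant_variable_excluded_with_warning(self):
        rng, a = self.make_env()
        env = pd.DataFrame({"x": a, "c": np.ones(len(a)), "y": rng.normal(size=len(a))})
        with pytest.warns(UserWarning, match="constant"):
            kept = es.select_uncorrelated_variables(env, ["x", "c", "y"])
        assert kept == ["x", "y"]

    def test_preconditions(self):
        env = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            es.select_uncorrelated_variables(env, ["x"])


class TestEnvironmentalFilter:
    def table(self, sbt, other=None, years=None):
        n = len(sbt)
        return pd.DataFrame(
            {
                "cell_id": np.arange(n),
                "lon": np.zeros(n),
                "lat": np.zeros(n),
                "SBT": sbt,
                "SBTr": other if other is not None else np.full(n, 4.2),
                "last_year": years if years is not None else np.full(n, 2000.0),
            }
        )

    def test_same_bin_collapses(self, small_grid):
        out = es.environmental_filter(self.table([14.1, 14.3]), small_grid, ["SBT", "SBTr"])
        assert len(out) == 1

    def test_distinct_bins_kept(self, small_grid):
        out = es.environmental_filter(self.table([14.1, 14.6, 15.2]), small_grid, ["SBT", "SBTr"])
        assert len(out) == 3

    def test_enumerated_bins(self, small_grid):
        # 10 values in exactly 3 bins of width 0.5: [14.0,14.5), [14.5,15.0), [16.0,16.5)
        sbt = [14.0, 14.1, 14.2, 14.3, 14.49, 14.5, 14.9, 16.0, 16.2, 16.4]
        out = es.environmental_filter(self.table(sbt), small_grid, ["SBT", "SBTr"])
        assert len(out) == 3

    def test_deterministic_pick_most_recent(self, small_grid):
        tab = self.table([14.1, 14.2], years=[1995.0, 2010.0])
        out = es.environmental_filter(tab, small_grid, ["SBT", "SBTr"])
        assert out["last_year"].tolist() == [2010.0]

    def test_tie_broken_by_cell_id(self, small_grid):
        tab = self.table([14.2, 14.1], years=[2000.0, 2000.0])
        out = es.environmental_filter(tab, small_grid, ["SBT", "SBTr"])
        assert out["cell_id"].tolist() == [0]

    def test_idempotent_and_order_invariant(self, small_grid):
        rng = np.random.default_rng(3)
        tab = self.table(rng.uniform(12, 20, 50), other=rng.uniform(2, 8, 50),
                         years=rng.integers(1990, 2018, 50).astype(float))
        tab["cell_id"] = np.arange(50)
        once = es.environmental_filter(tab, small_grid, ["SBT", "SBTr"])
        again = es.environmental_filter(once, small_grid, ["SBT", "SBTr"])
        pd.testing.assert_frame_equal(once, again)
        shuffled = es.environmental_filter(
            tab.sample(frac=1, random_state=7), small_grid, ["SBT", "SBTr"]
        )
        pd.testing.assert_frame_equal(once, shuffled)

    def test_missing_covariate_warns(self, small_grid):
        tab = self.table([14.1, np.nan])
        with pytest.warns(UserWarning, match="missing"):
            out = es.environmental_filter(tab, small_grid, ["SBT", "SBTr"])
        assert len(out) == 1

    def test_bad_resolution(self, small_grid):
        with pytest.raises(ValueError):
            es.environmental_filter(self.table([14.0]), small_grid, ["SBT"], {"SBT": 0.0})


class TestTrimmedHull:
    def test_square_corners(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5]], dtype=float)
        hull = es.TrimmedHull(pts, ["a", "b"], lower=0, upper=100)
        assert hull.volume == pytest.approx(1.0)
        assert hull.contains(np.array([[0.5, 0.5]]))[0]
        assert not hull.contains(np.array([[1.5, 0.5]]))[0]

    def test_outlier_trimmed(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, size=(60, 2))
        with_outlier = np.vstack([pts, [10.0, 10.0]])
        h_clean = es.TrimmedHull(pts, ["a", "b"], lower=0, upper=100)
        h_trim = es.TrimmedHull(with_outlier, ["a", "b"])
        assert not h_trim.contains(np.array([[10.0, 10.0]]))[0]
        assert h_trim.volume < 2 * h_clean.volume  # outlier did not inflate the hull

    def test_trimming_contracts(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(100, 3))
        full = es.TrimmedHull(pts, list("abc"), lower=0, upper=100)
        trimmed = es.TrimmedHull(pts, list("abc"))
        assert trimmed.volume <= full.volume

    def test_boundary_counts_inside(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        hull = es.TrimmedHull(pts, ["a", "b"], lower=0, upper=100)
        assert hull.contains(np.array([[0.0, 0.5]]))[0]

    def test_degenerate_falls_back(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 1, 10)])  # collinear
        with pytest.warns(UserWarning, match="degenerate"):
            hull = es.TrimmedHull(pts, ["a", "b"], lower=0, upper=100)
        assert hull.contains(np.array([[0.5, 0.5]]))[0]
        assert not hull.contains(np.array([[2.0, 2.0]]))[0]

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            es.TrimmedHull(np.array([[0.0, 0.0], [1.0, 1.0]]), ["a", "b"])


class TestPseudoAbsences:
    @pytest.fixture
    def setup(self):
        rng = np.random.default_rng(2)
        pres = rng.normal(0, 1, size=(100, 2))
        hull = es.TrimmedHull(pres, ["a", "b"])
        domain = pd.DataFrame(rng.uniform(-6, 6, size=(2000, 2)), columns=["a", "b"])
        domain.insert(0, "cell_id", np.arange(2000))
        domain.insert(1, "lon", 0.0)
        domain.insert(2, "lat", 0.0)
        return hull, domain

    def test_count_and_outside(self, setup):
        hull, domain = setup
        pa = es.sample_pseudo_absences(hull, 100, domain, seed=0)
        assert len(pa) == 100
        assert not hull.contains(pa[["a", "b"]]).any()

    def test_deterministic(self, setup):
        hull, domain = setup
        a = es.sample_pseudo_absences(hull, 50, domain, seed=3)
        b = es.sample_pseudo_absences(hull, 50, domain, seed=3)
        pd.testing.assert_frame_equal(a, b)
        c = es.sample_pseudo_absences(hull, 50, domain, seed=4)
        assert not a.equals(c)

    def test_shortfall_error_names_count(self, setup):
        hull, domain = setup
        n_out = int((~hull.contains(domain)).sum())
        with pytest.raises(es.PseudoAbsenceError, match="short by"):
            es.sample_pseudo_absences(hull, n_out + 5, domain, seed=0)

    def test_pa_table_balance(self, setup):
        hull, domain = setup
        pres = domain.iloc[:80].copy()
        pa = es.sample_pseudo_absences(hull, 80, domain, seed=1)
        tab = es.build_pa_table(pres, pa, ["a", "b"])
        assert (tab["label"] == 1).sum() == (tab["label"] == 0).sum() == 80
        with pytest.raises(ValueError):
            es.build_pa_table(pres.iloc[:10], pa, ["a", "b"])
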