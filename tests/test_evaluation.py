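"""Cross-validation, Continuous Boyce Index behaviour, response-curve
screening and the selection rule."""

import numpy as np
import pandas as pd
import pytest

from nichecast import synth
from nichecast.evaluation import (
    SelectionError,
    check_response_curves,
    continuous_boyce_index,
    cross_validate,
    member_sd,
    select_algorithms,
)

def thermal_truth():
    """1-D thermal niche spanning the full [0, 1] suitability scale on
    the test grid, so CBI windows across the whole axis are populated."""
    return synth.NicheTruth({"SBT": 17.5}, {"SBT": 2.0})


def cbi_simulation(grid, n=1000, seed=0, transform=None):
    """Presences sampled ∝ true suitability over marine cells; background
    = all marine cells; predictions = (a transform of) true suitability."""
    truth = thermal_truth()
    rng = np.random.default_rng(seed)
    env = grid.table(truth.variables, mask=grid.marine_mask)
    s = truth.suitability(env)
    idx = rng.choice(len(env), size=n, p=s / s.sum())
    pred = transform(s) if transform else s
    return pred[idx], pred


class TestCBI:
    def test_perfect_predictions_high(self, small_grid):
        vals = []
        for seed in range(20):
            p, b = cbi_simulation(small_grid, seed=seed)
            vals.append(continuous_boyce_index(p, b))
        assert min(vals) >= 0.9

    def test_random_null_near_zero(self):
        """Random predictions carry no signal: the replicate-mean CBI is
        near zero (single-seed values scatter more widely because the
        overlapping windows correlate the P/E noise)."""
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals.append(
                continuous_boyce_index(rng.uniform(size=1000), rng.uniform(size=1000))
            )
        assert abs(np.mean(vals)) < 0.3

    def test_reversed_predictions_negative(self, small_grid):
        truth = thermal_truth()
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            env = small_grid.table(truth.variables, mask=small_grid.marine_mask)
            s = truth.suitability(env)
            idx = rng.choice(len(env), size=1000, p=s / s.sum())
            rev = 1.0 - s
            vals.append(continuous_boyce_index(rev[idx], rev))
        assert max(vals) <= -0.9

    def test_monotone_transform_preserves_verdict(self, small_grid):
        """CBI is rank-based in spirit: strictly monotone rescalings of
        the predictions keep a skilful model clearly skilful, and
        reversal flips the sign."""
        p, b = cbi_simulation(small_grid, seed=1)
        for f in (np.sqrt, np.square, lambda x: 0.1 + 0.8 * x):
            assert continuous_boyce_index(f(p), f(b)) >= 0.8
        assert continuous_boyce_index(1 - p, 1 - b) <= -0.8

    def test_constant_background_undefined(self):
        with pytest.warns(UserWarning, match="identical"):
            v = continuous_boyce_index(np.array([0.5, 0.6]), np.full(10, 0.4))
        assert np.isnan(v)

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            continuous_boyce_index(np.array([]), np.array([0.5]))

    def test_bounded(self, small_grid):
        p, b = cbi_simulation(small_grid, seed=2)
        assert -1.0 <= continuous_boyce_index(p, b) <= 1.0


class TestCrossValidation:
    @pytest.fixture
    def table(self):
        rng = np.random.default_rng(0)
        n = 500
        return pd.DataFrame(
            {
                "label": np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)],
                "SBT": np.r_[rng.normal(15, 1, n // 2), rng.normal(22, 1, n // 2)],
                "SBTr": rng.normal(5, 1, n),
            }
        )

    def test_split_sizes(self, table):
        runs = cross_validate(table, ["GLM"], ["SBT", "SBTr"], runs=3, seed=0)
        for r in runs:
            assert len(r.train_idx) == round(0.7 * len(table)) == 350
            assert len(r.eval_idx) == 150

    def test_disjoint_and_exhaustive(self, table):
        runs = cross_validate(table, ["GLM"], ["SBT", "SBTr"], runs=3, seed=0)
        for r in runs:
            assert len(np.intersect1d(r.train_idx, r.eval_idx)) == 0
            assert len(np.union1d(r.train_idx, r.eval_idx)) == len(table)

    def test_runs_differ(self, table):
        runs = cross_validate(table, ["GLM"], ["SBT", "SBTr"], runs=3, seed=0)
        assert not np.array_equal(runs[0].train_idx, runs[1].train_idx)

    def test_too_small_errors(self, table):
        with pytest.raises(ValueError):
            cross_validate(table.iloc[:20], ["GLM"], ["SBT"], seed=0)


@pytest.mark.filterwarnings("ignore")
class TestCurveScreening:
    def _model_from_curve(self, curve_fn):
        class Fake:
            variables = ["SBT"]
            train_X = pd.DataFrame({"SBT": np.linspace(0, 1, 50)})

            def predict_esi(self, X):
                return curve_fn(np.asarray(X["SBT"]))

        return Fake()

    def test_gaussian_curve_passes(self):
        m = self._model_from_curve(lambda x: np.exp(-((x - 0.5) ** 2) / 0.02))
        assert check_response_curves(m) == {"SBT": True}

    def test_bimodal_curve_fails(self):
        def bimodal(x):
            return 0.8 * np.exp(-((x - 0.25) ** 2) / 0.004) + 0.7 * np.exp(
                -((x - 0.75) ** 2) / 0.004
            )

        m = self._model_from_curve(bimodal)
        assert check_response_curves(m) == {"SBT": False}

    def test_monotone_curve_passes(self):
        m = self._model_from_curve(lambda x: x)
        assert check_response_curves(m) == {"SBT": True}

    def test_flat_curve_passes(self):
        m = self._model_from_curve(lambda x: np.full_like(x, 0.4))
        assert check_response_curves(m) == {"SBT": True}

    def test_tiny_wiggles_tolerated(self):
        m = self._model_from_curve(
            lambda x: np.exp(-((x - 0.5) ** 2) / 0.02) + 0.005 * np.sin(40 * x)
        )
        assert check_response_curves(m, tolerance=0.02) == {"SBT": True}


class TestSelection:
    def test_threshold_rule(self):
        rep = select_algorithms(
            {"A": 0.82, "B": 0.45, "C": 0.9}, {"A": True, "B": True, "C": False}
        )
        assert rep.retained == ["A"]  # B under threshold, C bad curves

    def test_empty_retained_is_error(self):
        with pytest.raises(SelectionError):
            select_algorithms({"A": 0.3}, {"A": True})
        with pytest.raises(SelectionError):
            select_algorithms({}, {})

    def test_monotone_in_cbi(self):
        base = {"A": 0.55, "B": 0.7}
        curves = {"A": True, "B": True}
        r1 = select_algorithms(base, curves).retained
        r2 = select_algorithms({"A": 0.75, "B": 0.7}, curves).retained
        assert set(r1) <= set(r2)

    def test_report_frame(self):
        rep = select_algorithms({"A": 0.82, "B": 0.45}, {"A": True, "B": True})
        frame = rep.to_frame()
        assert frame.loc[frame.algorithm == "A", "retained"].item()
        assert not frame.loc[frame.algorithm == "B", "retained"].item()


class TestMemberSD:
    def test_identical_members_zero(self):
        maps = [np.full((4, 4), 0.3)] * 3
        assert member_sd(maps).max() == 0.0

    def test_two_member_closed_form(self):
        sd = member_sd([np.full((2, 2), 0.2), np.full((2, 2), 0.6)])
        np.testing.assert_allclose(sd, 0.2)

    def test_popoviciu_bound(self):
        rng = np.random.default_rng(0)
        maps = rng.uniform(size=(6, 5, 5))
        assert member_sd(maps).max() <= 0.5

    def test_single_member_errors(self):
        with pytest.raises(ValueError):
            member_sd([np.zeros((2, 2))])
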