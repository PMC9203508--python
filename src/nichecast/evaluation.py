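"""Model evaluation and ensemble selection.

Each candidate algorithm is scored by ten random 70/30 train/evaluation
splits of the presence/pseudo-absence table.  Skill is measured with the
Continuous Boyce Index (CBI): suitability space [0, 1] is scanned with
overlapping windows; within each window the predicted-to-expected ratio
P/E compares the share of presence predictions to the share of
background predictions, and CBI is the Spearman rank correlation between
window midpoints and P/E — 1 for a model whose high scores concentrate
presences, 0 for a random ranking, −1 for an inverted one.  An algorithm
joins the ensemble iff its mean CBI over the ten runs exceeds 0.5 *and*
its response curves are ecologically plausible (no multimodal response:
at most one interior local maximum after smoothing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import spearmanr

from .models import ModelFitError, NicheModel, fit_algorithm, response_curve

CBI_THRESHOLD = 0.5
CV_RUNS = 10
TRAIN_FRACTION = 0.7


# ----------------------------------------------------------------------
# Continuous Boyce Index
# ----------------------------------------------------------------------
def continuous_boyce_index(
    pred_presences: np.ndarray,
    pred_background: np.ndarray,
    window: float = 0.1,
    n_windows: int = 101,
) -> float:
    """CBI from presence and background prediction sets.

    Windows of width ``window`` slide across [0, 1] (``n_windows``
    positions); windows where the background (expected) fraction is zero
    are dropped.  Returns NaN with a warning when the background
    predictions are all identical (P/E undefined everywhere).
    """
    p = np.asarray(pred_presences, dtype=float)
    b = np.asarray(pred_background, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both prediction sets must be non-empty")
    if np.ptp(b) == 0:
        warnings.warn("all background predictions identical; CBI undefined")
        return float("nan")
    lows = np.linspace(0.0, 1.0 - window, n_windows)
    mids = lows + window / 2
    pe = np.empty(n_windows)
    keep = np.zeros(n_windows, dtype=bool)
    for i, lo in enumerate(lows):
        hi = lo + window
        pred = ((p >= lo) & (p <= hi)).mean()
        exp = ((b >= lo) & (b <= hi)).mean()
        if exp > 0:
            pe[i] = pred / exp
            keep[i] = True
    if keep.sum() < 3 or np.ptp(pe[keep]) == 0:
        warnings.warn("too few informative windows; CBI undefined")
        return float("nan")
    rho, _ = spearmanr(mids[keep], pe[keep])
    return float(rho)


# ----------------------------------------------------------------------
# cross-validation
# ----------------------------------------------------------------------
@dataclass
class CVRun:
    """One random 70/30 split with its fitted models and hold-out
    predictions."""

    run_id: int
    train_idx: np.ndarray
    eval_idx: np.ndarray
    models: dict[str, NicheModel] = field(default_factory=dict)
    eval_predictions: dict[str, np.ndarray] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


def cross_validate(
    table: pd.DataFrame,
    algorithms: list[str],
    variables: list[str],
    runs: int = CV_RUNS,
    seed: int = 0,
) -> list[CVRun]:
    """Ten (by default) independent random 70/30 splits; per run each
    algorithm is fitted on the training part and predicted on the
    hold-out part.  Algorithms that fail to fit are recorded, not fatal."""
    n = len(table)
    if n < 30:
        raise ValueError("need at least 30 rows for a 70/30 cross-validation")
    n_train = round(TRAIN_FRACTION * n)
    rng = np.random.default_rng(seed)
    out: list[CVRun] = []
    for r in range(runs):
        for _ in range(100):
            perm = rng.permutation(n)
            tr, ev = perm[:n_train], perm[n_train:]
            if (
                table["label"].values[tr].min() != table["label"].values[tr].max()
                and table["label"].values[ev].min() != table["label"].values[ev].max()
            ):
                break
        else:  # pragma: no cover
            raise ValueError("could not draw a split with both classes on each side")
        run = CVRun(run_id=r + 1, train_idx=np.sort(tr), eval_idx=np.sort(ev))
        train = table.iloc[run.train_idx]
        holdout = table.iloc[run.eval_idx]
        for alg in algorithms:
            try:
                m = fit_algorithm(alg, train, variables, seed=(seed * 1000 + r) % (2**31 - 7))
            except ModelFitError as exc:
                run.failures[alg] = str(exc)
                continue
            run.models[alg] = m
            run.eval_predictions[alg] = m.predict_esi(holdout)
        out.append(run)
    return out


def cbi_table(cv_runs: list[CVRun], table: pd.DataFrame) -> pd.DataFrame:
    """Per-(algorithm, run) CBI on the hold-out set: presences = label-1
    hold-out predictions, background = all hold-out predictions."""
    rows = []
    for run in cv_runs:
        y = table["label"].values[run.eval_idx]
        for alg, pred in run.eval_predictions.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cbi = continuous_boyce_index(pred[y == 1], pred)
            rows.append({"algorithm": alg, "run": run.run_id, "cbi": cbi})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# response-curve screening
# ----------------------------------------------------------------------
def check_response_curves(
    model: NicheModel,
    tolerance: float = 0.02,
    n_points: int = 50,
    smooth_window: int = 5,
) -> dict[str, bool]:
    """Plausibility verdict per covariate.

    A curve is plausible iff, after moving-average smoothing, it has at
    most one interior local maximum with prominence above ``tolerance``
    — multimodal responses (the classic spurious case being a bimodal
    response to temperature) fail.  Flat and monotone curves pass.
    """
    verdicts = {}
    for v in model.variables:
        curve = response_curve(model, v, n_points=n_points)["esi"].values
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(curve, pad, mode="edge")
        smoothed = np.convolve(padded, kernel, mode="valid")
        peaks, _ = find_peaks(smoothed, prominence=tolerance)
        verdicts[v] = peaks.size <= 1
    return verdicts


# ----------------------------------------------------------------------
# selection
# ----------------------------------------------------------------------
class SelectionError(RuntimeError):
    """No algorithm satisfies the selection rule; no ensemble possible."""


@dataclass
class SelectionReport:
    """Outcome of ensemble selection: mean CBI per algorithm, curve
    verdicts, and the retained set (CBI > threshold and plausible
    curves)."""

    mean_cbi: dict[str, float]
    curve_pass: dict[str, bool]
    retained: list[str]
    threshold: float = CBI_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "algorithm": list(self.mean_cbi),
                "mean_cbi": [self.mean_cbi[a] for a in self.mean_cbi],
                "curves_ok": [self.curve_pass.get(a, False) for a in self.mean_cbi],
                "retained": [a in self.retained for a in self.mean_cbi],
            }
        )


def select_algorithms(
    mean_cbi: dict[str, float],
    curve_pass: dict[str, bool],
    threshold: float = CBI_THRESHOLD,
) -> SelectionReport:
    """Retain algorithms with mean CBI above threshold and passing
    curves; an empty retained set is a hard error."""
    if not mean_cbi:
        raise SelectionError("no candidate algorithm was evaluated")
    retained = [
        a
        for a, c in mean_cbi.items()
        if np.isfinite(c) and c > threshold and curve_pass.get(a, False)
    ]
    if not retained:
        raise SelectionError(
            f"no algorithm passed selection (CBI > {threshold} with plausible curves)"
        )
    return SelectionReport(mean_cbi=mean_cbi, curve_pass=curve_pass, retained=retained, threshold=threshold)


def member_sd(member_maps: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Per-cell population standard deviation across ensemble members."""
    stack = np.asarray(member_maps, dtype=float)
    if stack.shape[0] < 2:
        raise ValueError("need at least two members")
    if any(m.shape != stack[0].shape for m in stack[1:]):  # pragma: no cover
        raise ValueError("member maps are on mismatched grids")
    return stack.std(axis=0, ddof=0)
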