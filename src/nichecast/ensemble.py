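"""Ensemble species-distribution model, statsmodels-style.

:class:`EnsembleSDM` is the model object: built from a model-ready
presence/pseudo-absence table, its :meth:`~EnsembleSDM.fit` runs the
whole calibration protocol — ten random 70/30 cross-validation splits
per candidate algorithm, Continuous Boyce Index scoring on the hold-out
sets, response-curve screening on full-table fits, and the selection
rule (mean CBI > 0.5 with plausible curves).  The returned
:class:`EnsembleResults` carries the per-run fitted models, the CBI
table, verdicts and retained set, prints a ``summary()`` table, and is
the object projections hang off.

    >>> model = EnsembleSDM.from_dataframe(pa_table, ["SBT", "SBTr", "Log_PP"])
    >>> res = model.fit()
    >>> print(res.summary())
    >>> smap = res.project(grid, mask)          # contemporary map
    >>> future = res.project(grid, mask, env=[fields_per_gcm, ...])
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import (
    CBI_THRESHOLD,
    CV_RUNS,
    CVRun,
    SelectionReport,
    cbi_table,
    check_response_curves,
    cross_validate,
    select_algorithms,
)
from .grids import EnvGrid
from .models import ALGORITHM_IDS, ModelFitError, fit_algorithm
from .projection import SuitabilityMap, project_ensemble


class EnsembleSDM:
    """Ensemble SDM over a fixed candidate-algorithm set.

    Parameters
    ----------
    pa_table : DataFrame with a ``label`` column (1 = presence,
        0 = pseudo-absence) and one column per environmental variable.
    variables : covariates the algorithms see.
    algorithms : candidate algorithm ids (default: all eight).
    cv_runs : number of random 70/30 splits (default 10).
    cbi_threshold : retention threshold on mean CBI (default 0.5).
    seed : master seed for splits and stochastic learners.
    """

    def __init__(
        self,
        pa_table: pd.DataFrame,
        variables: list[str],
        algorithms: tuple[str, ...] = ALGORITHM_IDS,
        cv_runs: int = CV_RUNS,
        cbi_threshold: float = CBI_THRESHOLD,
        curve_tolerance: float = 0.02,
        seed: int = 0,
    ):
        if "label" not in pa_table.columns:
            raise ValueError("pa_table needs a 'label' column")
        self.pa_table = pa_table.reset_index(drop=True)
        self.variables = list(variables)
        self.algorithms = tuple(algorithms)
        self.cv_runs = cv_runs
        self.cbi_threshold = cbi_threshold
        self.curve_tolerance = curve_tolerance
        self.seed = int(seed)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, variables: list[str], **kw) -> "EnsembleSDM":
        return cls(df, variables, **kw)

    def fit(self) -> "EnsembleResults":
        runs = cross_validate(
            self.pa_table, list(self.algorithms), self.variables, runs=self.cv_runs, seed=self.seed
        )
        cbi = cbi_table(runs, self.pa_table)
        mean_cbi = cbi.groupby("algorithm")["cbi"].mean().to_dict()

        # curve screening on full-table fits (the biological object of
        # interest is the algorithm's response, not one split's)
        curve_verdicts: dict[str, dict[str, bool]] = {}
        full_models = {}
        for alg in self.algorithms:
            if alg not in mean_cbi:
                continue
            try:
                m = fit_algorithm(alg, self.pa_table, self.variables, seed=self.seed)
            except ModelFitError:
                curve_verdicts[alg] = {v: False for v in self.variables}
                continue
            full_models[alg] = m
            curve_verdicts[alg] = check_response_curves(m, tolerance=self.curve_tolerance)
        curve_pass = {a: all(v.values()) for a, v in curve_verdicts.items()}
        report = select_algorithms(mean_cbi, curve_pass, threshold=self.cbi_threshold)
        return EnsembleResults(
            model=self,
            cv=runs,
            cbi=cbi,
            curve_verdicts=curve_verdicts,
            selection=report,
            full_models=full_models,
        )


@dataclass
class EnsembleResults:
    """Fitted ensemble: per-run models, CBI table, selection outcome."""

    model: EnsembleSDM
    cv: list[CVRun]
    cbi: pd.DataFrame
    curve_verdicts: dict[str, dict[str, bool]]
    selection: SelectionReport
    full_models: dict

    @property
    def retained(self) -> list[str]:
        return self.selection.retained

    @property
    def mean_cbi(self) -> dict[str, float]:
        return self.selection.mean_cbi

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable selection table."""
        frame = self.selection.to_frame().sort_values("mean_cbi", ascending=False)
        lines = [
            "Ensemble species distribution model",
            "=" * 52,
            f"candidates: {len(self.model.algorithms)}   CV runs: {self.model.cv_runs}   "
            f"rows: {len(self.model.pa_table)}",
            f"variables: {', '.join(self.model.variables)}",
            f"selection: mean CBI > {self.model.cbi_threshold} and plausible response curves",
            "-" * 52,
            frame.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "-" * 52,
            f"retained: {', '.join(self.retained)}",
        ]
        return "\n".join(lines)

    def report_dict(self) -> dict:
        return {
            "mean_cbi": {a: float(c) for a, c in self.mean_cbi.items()},
            "curve_verdicts": self.curve_verdicts,
            "retained": self.retained,
            "cbi_threshold": self.model.cbi_threshold,
        }

    def save_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report_dict(), fh, indent=2)

    # ------------------------------------------------------------------
    def predict(self, env: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Ensemble mean and member SD of ESI at arbitrary points."""
        members = [
            run.models[alg].predict_esi(env) for run in self.cv for alg in self.retained
        ]
        stack = np.asarray(members)
        return stack.mean(axis=0), stack.std(axis=0, ddof=0)

    def project(
        self,
        grid: EnvGrid,
        mask: np.ndarray,
        env: EnvGrid | dict | list | None = None,
        provenance: dict | None = None,
    ) -> SuitabilityMap:
        """Ensemble map on the valid cells of ``grid``.

        ``env=None`` projects the contemporary climatology (members =
        retained × runs); a list of per-GCM field dicts projects a
        future scenario (members = retained × runs × GCMs).
        """
        return project_ensemble(
            self.cv, self.retained, grid if env is None else env, grid, mask, provenance
        )

    def plot_response_curves(self, variable: str, ax=None):
        """Overlay the retained algorithms' response curves for one
        variable (full-table fits)."""
        import matplotlib.pyplot as plt

        from .models import response_curve

        if ax is None:
            _, ax = plt.subplots()
        for alg in self.retained:
            if alg in self.full_models:
                c = response_curve(self.full_models[alg], variable)
                ax.plot(c[variable], c["esi"], label=alg)
        ax.set_xlabel(variable)
        ax.set_ylabel("ESI")
        ax.set_ylim(0, 1)
        ax.legend()
        return ax
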