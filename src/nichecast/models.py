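"""Candidate niche-modelling algorithms.

Eight algorithms compete for a place in the ensemble, all exposing the
same contract: fit on a presence/pseudo-absence table and map any finite
environmental point to an Environmental Suitability Index (ESI) in
[0, 1].

* **NPPEN** (non-parametric probabilistic ecological niche model) is
  implemented from first principles: presence-only, it scores a point by
  the rank of its Mahalanobis distance to the reference presence matrix
  — ESI is the fraction of reference points lying *farther* from the
  niche centroid than the candidate, a permutation-style p-value of
  niche membership.
* GLM (binomial/logit with linear + quadratic terms), GAM (binomial
  GLM on per-variable B-spline bases, df = 4), GBM (gradient boosting,
  2500 trees, depth 3, shrinkage 1e-3), ANN (single hidden layer of 5
  units, best of 3 restarts), RF (500 trees) use statsmodels /
  scikit-learn with frozen, versioned defaults.
* MARS is a compact in-package implementation: forward stepwise
  selection of hinge (piecewise-linear) basis functions with
  second-order interactions, followed by a logistic refit on the
  selected basis so scores live on [0, 1].
* FDA follows its classical formulation — linear discriminant analysis
  on the same adaptively-selected hinge basis — with a logistic squash
  of the discriminant score.

Every fitted model is deterministic given its data and seed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.special import expit
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

ALGORITHM_IDS = ("NPPEN", "GLM", "GAM", "GBM", "ANN", "FDA", "MARS", "RF")

#: frozen default hyper-parameters (explicit, versioned)
DEFAULT_PARAMS: dict[str, dict] = {
    "GAM": {"df": 4},
    "GBM": {"n_estimators": 2500, "max_depth": 3, "learning_rate": 1e-3},
    "ANN": {"hidden_units": 5, "restarts": 3, "max_iter": 1500},
    "RF": {"n_estimators": 500},
    "MARS": {"max_terms": 13, "degree": 2, "n_knots": 12},
    "FDA": {"max_terms": 11, "degree": 1, "n_knots": 12},
    "NPPEN": {"ridge": 1e-8},
}


class ModelFitError(RuntimeError):
    """Raised when an algorithm cannot produce a usable fit (singular
    design, non-convergence, missing class)."""


class NicheModel:
    """Base class: common fitting contract and bookkeeping."""

    name: str = "base"

    def __init__(self, variables: list[str], seed: int = 0):
        self.variables = list(variables)
        self.seed = int(seed)
        self.train_X: pd.DataFrame | None = None

    # -- subclass hooks -------------------------------------------------
    def _fit(self, X: np.ndarray, y: np.ndarray) -> None:  # pragma: no cover
        raise NotImplementedError

    def _predict(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    # -- public contract ------------------------------------------------
    def fit(self, table: pd.DataFrame) -> "NicheModel":
        """Fit on a presence/pseudo-absence table with a ``label`` column."""
        y = table["label"].values.astype(int)
        classes = np.unique(y)
        if not self.presence_only and classes.size < 2:
            raise ModelFitError(f"{self.name}: table contains a single class")
        if self.presence_only and (y == 1).sum() < len(self.variables) + 2:
            raise ModelFitError(f"{self.name}: too few presences")
        X = table[self.variables]
        self.train_X = X[y == 1] if self.presence_only else X
        self._fit(X.values.astype(float), y)
        return self

    def predict_esi(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """ESI in [0, 1] at arbitrary (finite) environmental points."""
        if isinstance(X, pd.DataFrame):
            X = X[self.variables].values
        X = np.asarray(X, dtype=float)
        out = self._predict(X)
        return np.clip(out, 0.0, 1.0)

    presence_only: bool = False


# ----------------------------------------------------------------------
# NPPEN
# ----------------------------------------------------------------------
class NPPEN(NicheModel):
    """Rank-based Mahalanobis p-value of niche membership (presence-only).

    With reference matrix Y (thinned presence environments), centroid μ
    and covariance Σ, the squared Mahalanobis distance of a candidate x
    is D²(x) = (x − μ)ᵀ Σ⁻¹ (x − μ); ESI(x) is the fraction of reference
    points y lying at least as far from the centroid, D²(y) ≥ D²(x) — the
    permutation-test convention, so a reference point itself never scores
    zero.  The index is invariant under any invertible affine transform
    of the environmental axes.
    """

    name = "NPPEN"
    presence_only = True

    def _fit(self, X, y):
        ref = X[y == 1]
        self.mean_ = ref.mean(axis=0)
        cov = np.cov(ref, rowvar=False)
        cov = np.atleast_2d(cov)
        try:
            self.inv_cov_ = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            warnings.warn("singular reference covariance; ridge-regularized inverse used")
            eps = DEFAULT_PARAMS["NPPEN"]["ridge"]
            self.inv_cov_ = np.linalg.inv(cov + eps * np.eye(cov.shape[0]))
        self.cov_ = cov
        self.ref_d2_ = np.sort(self._d2(ref))

    def _d2(self, X):
        c = X - self.mean_
        return np.einsum("ij,jk,ik->i", c, self.inv_cov_, c)

    def _predict(self, X):
        d2 = self._d2(X)
        # fraction of reference distances at least as large as d2(x)
        m = self.ref_d2_.size
        rank = np.searchsorted(self.ref_d2_, d2, side="left")
        return (m - rank) / m


# ----------------------------------------------------------------------
# regression-family learners
# ----------------------------------------------------------------------
class GLM(NicheModel):
    """Binomial GLM (logit link) with linear + quadratic terms."""

    name = "GLM"

    def _design(self, X):
        return np.column_stack([np.ones(len(X)), X, X**2])

    def _fit(self, X, y):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                self.res_ = sm.GLM(y, self._design(X), family=sm.families.Binomial()).fit()
            except Exception as exc:  # singular design, separation blow-up
                raise ModelFitError(f"GLM: {exc}") from exc
        if not np.all(np.isfinite(self.res_.params)):
            raise ModelFitError("GLM: non-finite coefficients")

    def _predict(self, X):
        return self.res_.predict(self._design(X))


class GAM(NicheModel):
    """Binomial GLM on per-variable cubic B-spline bases (df = 4).

    Each covariate gets a cubic B-spline basis with one interior knot at
    its training median (four free columns after dropping one for
    identifiability).  Prediction covariates are clamped to the training
    range (constant extrapolation beyond the observed support).
    """

    name = "GAM"
    _k = 3  # cubic

    def _fit(self, X, y):
        self.knots_ = []
        for col in X.T:
            lo, hi = float(col.min()), float(col.max())
            if hi <= lo:
                hi = lo + 1e-9
            interior = [float(np.median(col))]
            interior = [min(max(t, lo + 1e-12), hi - 1e-12) for t in interior]
            self.knots_.append(np.r_[[lo] * (self._k + 1), interior, [hi] * (self._k + 1)])
        design = self._design(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                self.res_ = sm.GLM(y, design, family=sm.families.Binomial()).fit()
            except Exception as exc:
                raise ModelFitError(f"GAM: {exc}") from exc
        if not np.all(np.isfinite(self.res_.params)):
            raise ModelFitError("GAM: non-finite coefficients")

    def _design(self, X):
        cols = [np.ones(len(X))]
        for i, t in enumerate(self.knots_):
            x = np.clip(X[:, i], t[self._k], t[-self._k - 1])
            basis = BSpline.design_matrix(x, t, self._k).toarray()
            cols.append(basis[:, 1:])  # drop one column: basis sums to 1
        return np.column_stack(cols)

    def _predict(self, X):
        return self.res_.predict(self._design(X))


class GBM(NicheModel):
    name = "GBM"

    def _fit(self, X, y):
        p = DEFAULT_PARAMS["GBM"]
        self.clf_ = GradientBoostingClassifier(
            n_estimators=p["n_estimators"],
            max_depth=p["max_depth"],
            learning_rate=p["learning_rate"],
            random_state=self.seed,
        ).fit(X, y)

    def _predict(self, X):
        return self.clf_.predict_proba(X)[:, 1]


class ANN(NicheModel):
    """Single-hidden-layer perceptron; best of 3 restarts by loss."""

    name = "ANN"

    def _fit(self, X, y):
        p = DEFAULT_PARAMS["ANN"]
        self.mu_, self.sd_ = X.mean(axis=0), X.std(axis=0)
        self.sd_[self.sd_ == 0] = 1.0
        Z = (X - self.mu_) / self.sd_
        best = None
        for k in range(p["restarts"]):
            clf = MLPClassifier(
                hidden_layer_sizes=(p["hidden_units"],),
                max_iter=p["max_iter"],
                random_state=self.seed + k,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(Z, y)
            if best is None or clf.loss_ < best.loss_:
                best = clf
        self.clf_ = best

    def _predict(self, X):
        Z = (X - self.mu_) / self.sd_
        return self.clf_.predict_proba(Z)[:, 1]


class RF(NicheModel):
    name = "RF"

    def _fit(self, X, y):
        self.clf_ = RandomForestClassifier(
            n_estimators=DEFAULT_PARAMS["RF"]["n_estimators"], random_state=self.seed
        ).fit(X, y)

    def _predict(self, X):
        return self.clf_.predict_proba(X)[:, 1]


# ----------------------------------------------------------------------
# hinge-basis machinery shared by MARS and FDA
# ----------------------------------------------------------------------
class _HingeBasis:
    """Forward-stepwise selected products of hinge functions.

    Terms are products of factors max(±(x_v − knot), 0); the empty term
    is the intercept.  Selection greedily adds, at each step, the
    hinge pair (parent term × variable × knot) that most reduces the
    least-squares residual of the running fit.
    """

    def __init__(self, max_terms=13, degree=2, n_knots=12):
        self.max_terms = max_terms
        self.degree = degree
        self.n_knots = n_knots
        self.terms: list[tuple] = [()]  # each term: tuple of (var, sign, knot)

    def _col(self, X, term):
        c = np.ones(len(X))
        for var, sign, knot in term:
            c = c * np.maximum(sign * (X[:, var] - knot), 0.0)
        return c

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.column_stack([self._col(X, t) for t in self.terms])

    @staticmethod
    def _sse(B, y):
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        r = y - B @ coef
        return float(r @ r)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        qs = np.linspace(0.05, 0.95, self.n_knots)
        knots = [np.unique(np.quantile(X[:, j], qs)) for j in range(X.shape[1])]
        B = self.transform(X)
        sse = self._sse(B, y)
        while len(self.terms) + 2 <= self.max_terms:
            best = None
            for parent in self.terms:
                if len(parent) >= self.degree:
                    continue
                used = {v for v, _, _ in parent}
                pcol = self._col(X, parent)
                for j in range(X.shape[1]):
                    if j in used:
                        continue
                    for knot in knots[j]:
                        c1 = pcol * np.maximum(X[:, j] - knot, 0.0)
                        c2 = pcol * np.maximum(knot - X[:, j], 0.0)
                        if c1.std() == 0 and c2.std() == 0:
                            continue
                        cand = np.column_stack([B, c1, c2])
                        s = self._sse(cand, y)
                        if best is None or s < best[0]:
                            best = (s, parent, j, knot)
            if best is None or best[0] > sse - 1e-10:
                break
            sse, parent, j, knot = best
            self.terms.append(parent + ((j, 1, knot),))
            self.terms.append(parent + ((j, -1, knot),))
            B = self.transform(X)
        return self


class MARS(NicheModel):
    """Multivariate adaptive regression splines for classification:
    forward hinge-basis selection, then a logistic refit on the basis so
    the score passes through a logit link onto [0, 1]."""

    name = "MARS"

    def _fit(self, X, y):
        p = DEFAULT_PARAMS["MARS"]
        self.basis_ = _HingeBasis(p["max_terms"], p["degree"], p["n_knots"]).fit(X, y.astype(float))
        B = self.basis_.transform(X)[:, 1:]  # sklearn adds its own intercept
        if B.shape[1] == 0:
            raise ModelFitError("MARS: no basis terms selected")
        self.clf_ = LogisticRegression(C=1e3, max_iter=2000).fit(B, y)

    def _predict(self, X):
        return self.clf_.predict_proba(self.basis_.transform(X)[:, 1:])[:, 1]


class FDA(NicheModel):
    """Flexible discriminant analysis: LDA on an adaptively selected
    hinge basis, discriminant score squashed by a logistic to [0, 1]."""

    name = "FDA"

    def _fit(self, X, y):
        p = DEFAULT_PARAMS["FDA"]
        self.basis_ = _HingeBasis(p["max_terms"], p["degree"], p["n_knots"]).fit(X, y.astype(float))
        B = self.basis_.transform(X)[:, 1:]
        if B.shape[1] == 0:
            raise ModelFitError("FDA: no basis terms selected")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.clf_ = LinearDiscriminantAnalysis().fit(B, y)

    def _predict(self, X):
        score = self.clf_.decision_function(self.basis_.transform(X)[:, 1:])
        return expit(score)


_REGISTRY: dict[str, type[NicheModel]] = {
    "NPPEN": NPPEN,
    "GLM": GLM,
    "GAM": GAM,
    "GBM": GBM,
    "ANN": ANN,
    "FDA": FDA,
    "MARS": MARS,
    "RF": RF,
}


def fit_algorithm(
    algorithm_id: str, table: pd.DataFrame, variables: list[str], seed: int = 0
) -> NicheModel:
    """Fit one algorithm on a presence/pseudo-absence table.

    Raises :class:`ModelFitError` for degenerate inputs (single class,
    too few rows) or failed fits; callers exclude such models from the
    ensemble with a logged reason.
    """
    if algorithm_id not in _REGISTRY:
        raise KeyError(f"unknown algorithm {algorithm_id!r}; choose from {ALGORITHM_IDS}")
    y = table["label"].values
    if np.unique(y).size < 2:
        raise ModelFitError(f"{algorithm_id}: single-class table")
    if min((y == 1).sum(), (y == 0).sum()) < 10:
        raise ModelFitError(f"{algorithm_id}: fewer than 10 rows in a class")
    return _REGISTRY[algorithm_id](variables, seed=seed).fit(table)


def response_curve(
    model: NicheModel,
    variable: str,
    values: np.ndarray | None = None,
    n_points: int = 50,
) -> pd.DataFrame:
    """ESI along one variable, the others held at their training medians."""
    if variable not in model.variables:
        raise ValueError(f"{variable!r} is not a covariate of this model")
    if model.train_X is None:
        raise ValueError("model is not fitted")
    med = model.train_X.median()
    if values is None:
        lo, hi = model.train_X[variable].min(), model.train_X[variable].max()
        values = np.linspace(lo, hi, n_points)
    X = pd.DataFrame({v: np.full(len(values), med[v]) for v in model.variables})
    X[variable] = values
    return pd.DataFrame({variable: values, "esi": model.predict_esi(X)})
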