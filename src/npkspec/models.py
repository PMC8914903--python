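"""Diagnostic regression models for nutrient content.

Three model classes in the statsmodels idiom — construct from data,
``fit()`` returns a results object with estimates, fit statistics,
``predict`` and ``summary()``:

* :class:`UnivariateNutrientModel` — the four classical single-variable
  calibration families: linear y = a + b x, parabolic y = a + b x + c x^2,
  exponential y = a e^(b x) and logarithmic y = a + b ln x;
* :class:`WaveletPLSModel` — partial least squares (PLS1) on the three
  selected wavelet sensitivity coefficients, collapsed to an intercept
  plus one coefficient per predictor;
* :class:`FeedforwardNetModel` — a single-hidden-layer feedforward
  network (10 sigmoid units, linear output) on the same predictors,
  with min–max scaling fitted on the modeling set and deterministic
  training under a fixed seed.

Module-level ``fit_univariate`` / ``fit_pls`` / ``fit_nn`` / ``predict``
are thin functional wrappers over the classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .evaluation import r_squared

__all__ = [
    "FAMILIES",
    "UnivariateNutrientModel",
    "UnivariateResults",
    "WaveletPLSModel",
    "PLSResults",
    "FeedforwardNetModel",
    "NeuralNetResults",
    "fit_univariate",
    "fit_pls",
    "fit_nn",
    "predict",
]

FAMILIES = ("linear", "parabolic", "exponential", "logarithmic")


def _check_finite(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


# ---------------------------------------------------------------------------
# univariate families


class UnivariateNutrientModel:
    """Single-predictor calibration model of one of the four families."""

    def __init__(self, x, y, family: str = "linear",
                 predictor_name: str = "x", response_name: str = "y"):
        if family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
        self.x = _check_finite("x", x)
        self.y = _check_finite("y", y)
        if self.x.size != self.y.size:
            raise ValueError("x and y must have equal length")
        n_par = 3 if family == "parabolic" else 2
        if self.x.size < n_par + 1 and self.x.size != n_par:
            raise ValueError(f"need at least {n_par} samples for a {family} fit")
        if family == "logarithmic" and np.any(self.x <= 0):
            bad = np.flatnonzero(self.x <= 0)
            raise ValueError(
                f"logarithmic model needs x > 0; offending samples {bad.tolist()}"
            )
        if family == "exponential" and np.any(self.y <= 0):
            bad = np.flatnonzero(self.y <= 0)
            raise ValueError(
                f"exponential model needs y > 0; offending samples {bad.tolist()}"
            )
        self.family = family
        self.predictor_name = predictor_name
        self.response_name = response_name

    def fit(self, method: str = "nls") -> "UnivariateResults":
        """Least-squares fit.

        The exponential family is fit by nonlinear least squares
        initialized at the log-linear solution; ``method="log-linear"``
        keeps the initialization itself.
        """
        x, y, family = self.x, self.y, self.family
        if family == "linear":
            b, a = np.polyfit(x, y, 1)
            params = {"a": a, "b": b}
        elif family == "parabolic":
            c, b, a = np.polyfit(x, y, 2)
            params = {"a": a, "b": b, "c": c}
        elif family == "logarithmic":
            b, a = np.polyfit(np.log(x), y, 1)
            params = {"a": a, "b": b}
        else:  # exponential
            b0, loga = np.polyfit(x, np.log(y), 1)
            a0 = np.exp(loga)
            if method == "log-linear":
                params = {"a": a0, "b": b0}
            else:
                try:
                    (a_hat, b_hat), _ = curve_fit(
                        lambda t, a, b: a * np.exp(b * t), x, y,
                        p0=(a0, b0), maxfev=10000,
                    )
                    params = {"a": a_hat, "b": b_hat}
                except RuntimeError:
                    params = {"a": a0, "b": b0}
        params = {k: float(v) for k, v in params.items()}
        res = UnivariateResults(model=self, params=params)
        res.fittedvalues = res.predict(x)
        res.rsquared = r_squared(y, res.fittedvalues)
        return res


@dataclass
class UnivariateResults:
    model: UnivariateNutrientModel
    params: dict[str, float]
    fittedvalues: np.ndarray = field(default=None, repr=False)
    rsquared: float = np.nan

    @property
    def family(self) -> str:
        return self.model.family

    def predict(self, x) -> np.ndarray:
        x = _check_finite("x", x)
        a, b = self.params["a"], self.params["b"]
        if self.family == "linear":
            return a + b * x
        if self.family == "parabolic":
            return a + b * x + self.params["c"] * x**2
        if self.family == "exponential":
            return a * np.exp(b * x)
        if np.any(x <= 0):
            raise ValueError("logarithmic model requires x > 0 at prediction")
        return a + b * np.log(x)

    def equation(self) -> str:
        p, v = self.params, self.model.predictor_name
        if self.family == "linear":
            return f"Y = {p['b']:.4g} * {v} + {p['a']:.4g}"
        if self.family == "parabolic":
            return f"Y = {p['c']:.4g} * {v}^2 + {p['b']:.4g} * {v} + {p['a']:.4g}"
        if self.family == "exponential":
            return f"Y = {p['a']:.4g} * exp({p['b']:.4g} * {v})"
        return f"Y = {p['b']:.4g} * ln({v}) + {p['a']:.4g}"

    def summary(self) -> str:
        lines = [
            f"Univariate {self.family} model: "
            f"{self.model.response_name} ~ {self.model.predictor_name}",
            f"  n = {self.model.x.size}",
            f"  {self.equation()}",
            f"  training R^2 = {self.rsquared:.4f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# partial least squares


class WaveletPLSModel:
    """PLS1 regression on the selected sensitivity coefficients."""

    def __init__(self, X, y, n_components: int = 2,
                 predictor_names: list[str] | None = None,
                 response_name: str = "y"):
        self.X = np.atleast_2d(_check_finite("X", X))
        self.y = _check_finite("y", y)
        n, p = self.X.shape
        if n != self.y.size:
            raise ValueError("X and y disagree on sample count")
        if not 1 <= n_components <= p:
            raise ValueError(f"n_components must be in 1..{p}")
        if n <= n_components:
            raise ValueError("need n > n_components samples")
        rank = np.linalg.matrix_rank(self.X - self.X.mean(axis=0))
        if np.var(self.y) > 0 and n_components > rank:
            raise ValueError(
                f"X has rank {rank}; cannot extract {n_components} components"
            )
        self.n_components = n_components
        self.predictor_names = (
            list(predictor_names) if predictor_names is not None
            else [f"X{i + 1}" for i in range(p)]
        )
        self.response_name = response_name

    def fit(self) -> "PLSResults":
        X, y = self.X, self.y
        if np.var(y) == 0:
            # NIPALS weights are undefined for a constant response.
            coefs = np.zeros(X.shape[1])
            intercept = float(y.mean())
            x_variance = np.zeros(self.n_components)
        else:
            pls = PLSRegression(n_components=self.n_components, scale=False)
            pls.fit(X, y)
            coefs = pls.coef_.ravel().astype(float)
            # collapse the centered form to Y = X @ coefs + intercept
            intercept = float(y.mean() - X.mean(axis=0) @ coefs)
            Xc = X - X.mean(axis=0)
            total = np.sum(Xc**2)
            x_variance = np.array([
                np.sum(np.outer(pls.x_scores_[:, i], pls.x_loadings_[:, i]) ** 2)
                / total
                for i in range(self.n_components)
            ])
        res = PLSResults(
            model=self, intercept=intercept, coefs=coefs,
            x_variance_explained=x_variance,
        )
        res.fittedvalues = res.predict(X)
        res.rsquared = (
            r_squared(y, res.fittedvalues) if np.var(y) > 0 else np.nan
        )
        return res


@dataclass
class PLSResults:
    model: WaveletPLSModel
    intercept: float
    coefs: np.ndarray
    x_variance_explained: np.ndarray
    fittedvalues: np.ndarray = field(default=None, repr=False)
    rsquared: float = np.nan

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(_check_finite("X", X))
        if X.shape[1] != self.coefs.size:
            raise ValueError("predictor count mismatch")
        return self.intercept + X @ self.coefs

    def equation(self) -> str:
        terms = " + ".join(
            f"{c:.4g} * {name}"
            for c, name in zip(self.coefs, self.model.predictor_names)
        )
        return f"Y = {terms} + {self.intercept:.4g}"

    def summary(self) -> str:
        lines = [
            f"PLS regression ({self.model.n_components} components) for "
            f"{self.model.response_name}",
            f"  n = {self.model.y.size}, predictors = "
            f"{self.model.predictor_names}",
            f"  {self.equation()}",
            "  X variance explained per component: "
            + ", ".join(f"{v:.3f}" for v in self.x_variance_explained),
            f"  training R^2 = {self.rsquared:.4f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# feedforward network


class FeedforwardNetModel:
    """Single-hidden-layer feedforward network regression (10 units default)."""

    def __init__(self, X, y, hidden_units: int = 10, activation: str = "logistic",
                 seed: int = 0, max_iter: int = 2000, tol: float = 1e-6,
                 predictor_names: list[str] | None = None,
                 response_name: str = "y"):
        self.X = np.atleast_2d(_check_finite("X", X))
        self.y = _check_finite("y", y)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y disagree on sample count")
        self.hidden_units = hidden_units
        self.activation = activation
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.predictor_names = (
            list(predictor_names) if predictor_names is not None
            else [f"X{i + 1}" for i in range(self.X.shape[1])]
        )
        self.response_name = response_name

    def fit(self) -> "NeuralNetResults":
        X, y = self.X, self.y
        x_min, x_max = X.min(axis=0), X.max(axis=0)
        x_range = np.where(x_max > x_min, x_max - x_min, 1.0)
        y_min, y_max = float(y.min()), float(y.max())
        y_range = (y_max - y_min) if y_max > y_min else 1.0
        net = MLPRegressor(
            hidden_layer_sizes=(self.hidden_units,),
            activation=self.activation,
            solver="lbfgs",
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.seed,
        )
        with warnings.catch_warnings():
            # stopping rule is tol-or-max_iter; hitting max_iter is expected
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            net.fit((X - x_min) / x_range, (y - y_min) / y_range)
        res = NeuralNetResults(
            model=self, net=net,
            x_min=x_min, x_range=x_range, y_min=y_min, y_range=y_range,
        )
        res.fittedvalues = res.predict(X)
        res.rsquared = r_squared(y, res.fittedvalues) if np.var(y) > 0 else np.nan
        return res


@dataclass
class NeuralNetResults:
    model: FeedforwardNetModel
    net: MLPRegressor = field(repr=False)
    x_min: np.ndarray
    x_range: np.ndarray
    y_min: float
    y_range: float
    fittedvalues: np.ndarray = field(default=None, repr=False)
    rsquared: float = np.nan

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(_check_finite("X", X))
        z = (X - self.x_min) / self.x_range
        return self.net.predict(z) * self.y_range + self.y_min

    @property
    def weights(self) -> list[np.ndarray]:
        return self.net.coefs_

    @property
    def biases(self) -> list[np.ndarray]:
        return self.net.intercepts_

    def summary(self) -> str:
        return "\n".join([
            f"Feedforward net ({self.model.hidden_units} hidden "
            f"{self.model.activation} units, linear output) for "
            f"{self.model.response_name}",
            f"  n = {self.model.y.size}, predictors = "
            f"{self.model.predictor_names}, seed = {self.model.seed}",
            f"  training R^2 = {self.rsquared:.4f}",
        ])


# ---------------------------------------------------------------------------
# functional wrappers


def fit_univariate(x, y, family: str = "linear", **kwargs) -> UnivariateResults:
    return UnivariateNutrientModel(x, y, family=family, **kwargs).fit()


def fit_pls(X, y, n_components: int = 2, **kwargs) -> PLSResults:
    return WaveletPLSModel(X, y, n_components=n_components, **kwargs).fit()


def fit_nn(X, y, **kwargs) -> NeuralNetResults:
    return FeedforwardNetModel(X, y, **kwargs).fit()


def predict(results, X) -> np.ndarray:
    """Evaluate any fitted results object on new predictor values."""
    return results.predict(X)
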