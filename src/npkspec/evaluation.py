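"""Model evaluation: R^2, MRE, RMSE, NRMSE and the AHP-weighted score T.

A fitted diagnostic model is judged by its modeling-set coefficient of
determination R^2 and its validation-set mean relative error (MRE, %),
root mean square error (RMSE, content units) and normalized RMSE
(RMSE divided by the mean measured content).  The three criteria are
combined into a single composite score

    T = (1/R^2) * w_R2 + MRE_fraction * w_MRE + NRMSE * w_NRMSE

with fixed expert-elicited (AHP) weights w = (0.4648, 0.2958, 0.2394).
MRE enters the score as a fraction, not a percent.  Lower T is better;
a perfect model scores w_R2 = 0.4648.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AHPWeights",
    "AHP_WEIGHTS",
    "EvaluationReport",
    "r_squared",
    "mre",
    "rmse",
    "nrmse",
    "t_score",
    "relative_improvement",
    "evaluate_model",
]


@dataclass(frozen=True)
class AHPWeights:
    """Fixed composite-score weights for (1/R^2, MRE, NRMSE)."""

    w_r2: float = 0.4648
    w_mre: float = 0.2958
    w_nrmse: float = 0.2394

    def __post_init__(self) -> None:
        if min(self.w_r2, self.w_mre, self.w_nrmse) <= 0:
            raise ValueError("all weights must be positive")
        if abs(self.w_r2 + self.w_mre + self.w_nrmse - 1.0) > 5e-4:
            raise ValueError("weights must sum to 1 (to printed precision)")


AHP_WEIGHTS = AHPWeights()


def _pair(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size != y_hat.size or y.size == 0:
        raise ValueError("y and y_hat must be non-empty and of equal length")
    return y, y_hat


def r_squared(y, y_hat, method: str = "ss") -> float:
    """Coefficient of determination (clipped at 0).

    method="ss" (default): 1 - SS_res/SS_tot; method="corr": squared
    Pearson correlation.  Both coincide for least-squares linear fits.
    """
    y, y_hat = _pair(y, y_hat)
    if y.size < 2 or np.var(y) == 0:
        raise ValueError("R^2 undefined for constant or singleton y")
    if method == "corr":
        c = np.corrcoef(y, y_hat)[0, 1]
        return float(np.nan_to_num(c) ** 2)
    if method != "ss":
        raise ValueError(f"unknown R^2 method {method!r}")
    ss_res = np.sum((y - y_hat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(max(0.0, 1.0 - ss_res / ss_tot))


def mre(y, y_hat) -> float:
    """Mean relative error in percent: 100 * mean(|y - y_hat| / y)."""
    y, y_hat = _pair(y, y_hat)
    if np.any(y <= 0):
        raise ValueError("MRE requires all measured values > 0")
    return float(100.0 * np.mean(np.abs(y - y_hat) / y))


def rmse(y, y_hat) -> float:
    y, y_hat = _pair(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def nrmse(y, y_hat) -> float:
    """RMSE normalized by the mean measured value."""
    y, y_hat = _pair(y, y_hat)
    mean_y = y.mean()
    if mean_y <= 0:
        raise ValueError("NRMSE requires mean(y) > 0")
    return float(rmse(y, y_hat) / mean_y)


def t_score(
    r2: float, mre_percent: float, nrmse_value: float,
    weights: AHPWeights = AHP_WEIGHTS,
) -> float:
    """Composite score T (lower is better), rounded to 4 decimals.

    ``mre_percent`` is supplied on the percent scale (as reported) and
    enters the weighted sum as a fraction.
    """
    if r2 <= 0:
        raise ValueError("T undefined for R^2 <= 0")
    if mre_percent < 0 or nrmse_value < 0:
        raise ValueError("MRE and NRMSE must be >= 0")
    t = (
        weights.w_r2 / r2
        + weights.w_mre * mre_percent / 100.0
        + weights.w_nrmse * nrmse_value
    )
    return round(float(t), 4)


def relative_improvement(
    reference: float, candidate: float, smaller_is_better: bool = False
) -> float:
    """Signed percent change of a metric between two models.

    100*(reference-candidate)/reference when smaller is better,
    100*(candidate-reference)/reference otherwise.
    """
    if reference == 0:
        raise ValueError("reference metric must be nonzero")
    if smaller_is_better:
        return float(100.0 * (reference - candidate) / reference)
    return float(100.0 * (candidate - reference) / reference)


@dataclass
class EvaluationReport:
    """Headline metrics of one fitted model: modeling R^2, validation
    MRE/RMSE/NRMSE and the composite score T."""

    model_id: str
    r2_modeling: float
    mre_percent: float
    rmse_value: float
    nrmse_value: float
    t: float = field(init=False)
    n_modeling: int = 0
    n_validation: int = 0
    weights: AHPWeights = AHP_WEIGHTS

    def __post_init__(self) -> None:
        self.t = t_score(
            self.r2_modeling, self.mre_percent, self.nrmse_value, self.weights
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "R2": round(self.r2_modeling, 4),
            "MRE_percent": round(self.mre_percent, 4),
            "RMSE": round(self.rmse_value, 6),
            "NRMSE": round(self.nrmse_value, 4),
            "T": self.t,
            "n_modeling": self.n_modeling,
            "n_validation": self.n_validation,
        }


def evaluate_model(
    results,
    X_modeling,
    y_modeling,
    X_validation,
    y_validation,
    model_id: str,
    weights: AHPWeights = AHP_WEIGHTS,
) -> EvaluationReport:
    """Score a fitted model on the modeling/validation split."""
    y_model = np.asarray(y_modeling, dtype=float)
    y_valid = np.asarray(y_validation, dtype=float)
    yhat_model = np.asarray(results.predict(X_modeling), dtype=float)
    yhat_valid = np.asarray(results.predict(X_validation), dtype=float)
    return EvaluationReport(
        model_id=model_id,
        r2_modeling=r_squared(y_model, yhat_model),
        mre_percent=mre(y_valid, yhat_valid),
        rmse_value=rmse(y_valid, yhat_valid),
        nrmse_value=nrmse(y_valid, yhat_valid),
        n_modeling=y_model.size,
        n_validation=y_valid.size,
        weights=weights,
    )
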