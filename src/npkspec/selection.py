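"""Correlation screening of spectral variables and wavelet coefficients.

Each candidate variable (one of the 24 characteristic variables, or one
detail-band coefficient position of one wavelet basis and level) is
scored by its sample Pearson correlation with a nutrient content across
samples; significance comes from the usual t reference distribution,
t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom, two-sided.  The
"wavelet sensitivity coefficients" of a nutrient are the k detail-band
positions with the largest |r| across all bases, levels and bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .wavelet import BASES

__all__ = [
    "CorrelationRecord",
    "SensitivityCoefficient",
    "pearson_r",
    "significance",
    "correlation_table",
    "select_sensitivity_coefficients",
]


@dataclass
class CorrelationRecord:
    variable: str
    r: float
    p: float
    flag: str  # "", "0.05" or "0.01"


@dataclass(frozen=True)
class SensitivityCoefficient:
    """One selected detail-band position: basis, level, band index, r."""

    basis: str
    level: int
    band_index: int
    r: float

    @property
    def name(self) -> str:
        return f"X{self.basis}-D{self.level}-{self.band_index}"


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    return float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))


def significance(r: float, n: int) -> tuple[float, str]:
    """Two-sided p-value and significance flag for a Pearson r at sample size n."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    flag = "0.01" if p < 0.01 else ("0.05" if p < 0.05 else "")
    return p, flag


def correlation_table(variables: pd.DataFrame, y: pd.Series) -> pd.DataFrame:
    """Pearson r, p and significance flag of every column against y.

    Constant columns yield an ``r = NaN`` row flagged ``undefined``
    instead of an error.  Output rows are in column order, ready for a
    star-annotated report.
    """
    y_aligned = y.loc[variables.index].to_numpy(dtype=float)
    rows = []
    for col in variables.columns:
        x = variables[col].to_numpy(dtype=float)
        try:
            r = pearson_r(x, y_aligned)
            p, flag = significance(r, len(x))
        except ValueError:
            r, p, flag = np.nan, np.nan, "undefined"
        rows.append((col, r, p, flag))
    return pd.DataFrame(rows, columns=["variable", "r", "p", "flag"]).set_index(
        "variable"
    )


def _columnwise_r(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2, axis=0))
    sy = np.sqrt(np.sum(yc**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


def select_sensitivity_coefficients(
    bank: dict[tuple[str, int], np.ndarray],
    y,
    k: int = 3,
) -> list[SensitivityCoefficient]:
    """Top-k detail-band coefficient positions by |Pearson r| with y.

    ``bank`` maps (basis, level) to a (n_samples, n_bands) detail
    matrix (see :func:`npkspec.wavelet.detail_bank`).  Ties are broken
    by basis order (db2 < db3 < db4 < db5), then lower level, then lower
    band index; the result is sorted by |r| descending.
    """
    y = np.asarray(y, dtype=float)
    basis_order = {b: i for i, b in enumerate(BASES)}
    cands: list[tuple[float, int, int, int, float]] = []
    for (basis, level), X in bank.items():
        if X.shape[0] != y.size:
            raise ValueError("bank and y disagree on sample count")
        r = _columnwise_r(np.asarray(X, dtype=float), y)
        for band in np.flatnonzero(np.isfinite(r)):
            cands.append(
                (-abs(r[band]), basis_order[basis], level, int(band), float(r[band]))
            )
    if k > len(cands):
        raise ValueError(f"k={k} exceeds {len(cands)} usable candidates")
    cands.sort()
    return [
        SensitivityCoefficient(
            basis=BASES[b], level=lvl, band_index=band, r=r
        )
        for _, b, lvl, band, r in cands[:k]
    ]
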