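"""The 24 classical spectral characteristic variables of leaf spectra.

Three families of variables are computed per spectrum:

* position variables — blue-edge (490–530 nm), yellow-edge (560–640 nm)
  and red-edge (680–760 nm) first-derivative maxima (D_b, D_y, D_r) and
  their wavelengths (lambda_b, lambda_y, lambda_r); green-peak maximum
  reflectance R_g / lambda_g on 510–560 nm and red-valley minimum
  reflectance R_r / lambda_o on 650–690 nm;
* area variables — trapezoidal areas of the reflectance curve over the
  blue-edge, yellow-edge, red-edge and green-peak windows (SD_b, SD_y,
  SD_r, SD_g);
* vegetation indices VI1..VI10 combining the above with reflectances at
  445, 680, 705, 720, 750 and 800 nm.

The green-peak/red-valley variables are reflectance extrema by default
(the conventional red-edge-literature reading of their names); a literal
first-derivative mode is available, as is a derivative-based area mode.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_NAMES",
    "WINDOWS",
    "first_derivative",
    "band_reflectance",
    "extract_features",
    "feature_table",
]

WINDOWS = {
    "blue_edge": (490.0, 530.0),
    "yellow_edge": (560.0, 640.0),
    "red_edge": (680.0, 760.0),
    "green_peak": (510.0, 560.0),
    "red_valley": (650.0, 690.0),
}

FEATURE_NAMES = (
    "Db", "lambda_b", "Dy", "lambda_y", "Dr", "lambda_r",
    "Rg", "lambda_g", "Rr", "lambda_o",
    "SDb", "SDy", "SDr", "SDg",
    "VI1", "VI2", "VI3", "VI4", "VI5", "VI6", "VI7", "VI8", "VI9", "VI10",
)

_VI_BANDS = (445.0, 680.0, 705.0, 720.0, 750.0, 800.0)


def first_derivative(wavelengths: np.ndarray, values: np.ndarray) -> np.ndarray:
    """First-order differential spectrum.

    Central differences (R[i+1] - R[i-1]) / (w[i+1] - w[i-1]) in the
    interior, one-sided differences at the ends; same length as input.
    """
    w = np.asarray(wavelengths, dtype=float)
    v = np.asarray(values, dtype=float)
    if w.size < 3:
        raise ValueError("need at least 3 bands for a derivative")
    if np.any(np.diff(w) <= 0):
        raise ValueError("wavelength grid must be strictly increasing (no duplicates)")
    d = np.empty_like(v)
    d[1:-1] = (v[2:] - v[:-2]) / (w[2:] - w[:-2])
    d[0] = (v[1] - v[0]) / (w[1] - w[0])
    d[-1] = (v[-1] - v[-2]) / (w[-1] - w[-2])
    return d


def band_reflectance(spectrum: pd.Series, target_nm: float) -> float:
    """Reflectance at the band nearest ``target_nm`` (ties -> lower band)."""
    w = spectrum.index.to_numpy(dtype=float)
    if target_nm < w.min() or target_nm > w.max():
        raise ValueError(
            f"target {target_nm} nm outside grid [{w.min()}, {w.max()}] nm"
        )
    return float(spectrum.iloc[int(np.argmin(np.abs(w - target_nm)))])


def _window_mask(w: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (w >= lo) & (w <= hi)


def extract_features(
    spectrum: pd.Series,
    extrema_mode: str = "reflectance",
    area_mode: str = "reflectance",
) -> pd.Series:
    """Compute all 24 characteristic variables of one spectrum.

    ``extrema_mode`` governs R_g/lambda_g and R_r/lambda_o:
    "reflectance" (default) takes reflectance extrema in their windows,
    "derivative" takes first-derivative extrema.  ``area_mode`` governs
    whether SD areas integrate the reflectance curve (default) or the
    first-derivative curve.
    """
    if extrema_mode not in ("reflectance", "derivative"):
        raise ValueError(f"unknown extrema_mode {extrema_mode!r}")
    if area_mode not in ("reflectance", "derivative"):
        raise ValueError(f"unknown area_mode {area_mode!r}")

    w = spectrum.index.to_numpy(dtype=float)
    v = spectrum.to_numpy(dtype=float)
    missing = [
        f"{name} {win[0]:g}-{win[1]:g} nm"
        for name, win in WINDOWS.items()
        if win[0] < w.min() or win[1] > w.max()
    ]
    missing += [f"{b:g} nm" for b in _VI_BANDS if b < w.min() or b > w.max()]
    if missing:
        raise ValueError("grid does not cover: " + ", ".join(missing))

    deriv = first_derivative(w, v)
    out: dict[str, float] = {}

    def edge(window: str, d_key: str, l_key: str) -> None:
        m = _window_mask(w, WINDOWS[window])
        i = int(np.argmax(deriv[m]))
        out[d_key] = float(deriv[m][i])
        out[l_key] = float(w[m][i])

    edge("blue_edge", "Db", "lambda_b")
    edge("yellow_edge", "Dy", "lambda_y")
    edge("red_edge", "Dr", "lambda_r")

    curve = deriv if extrema_mode == "derivative" else v
    mg = _window_mask(w, WINDOWS["green_peak"])
    ig = int(np.argmax(curve[mg]))
    out["Rg"], out["lambda_g"] = float(curve[mg][ig]), float(w[mg][ig])
    mo = _window_mask(w, WINDOWS["red_valley"])
    io = int(np.argmin(curve[mo]))
    out["Rr"], out["lambda_o"] = float(curve[mo][io]), float(w[mo][io])

    area_curve = deriv if area_mode == "derivative" else v
    for key, window in (
        ("SDb", "blue_edge"), ("SDy", "yellow_edge"),
        ("SDr", "red_edge"), ("SDg", "green_peak"),
    ):
        m = _window_mask(w, WINDOWS[window])
        out[key] = float(np.trapezoid(area_curve[m], w[m]))

    r = {b: band_reflectance(spectrum, b) for b in _VI_BANDS}
    out["VI1"] = out["Rg"] / out["Rr"]
    out["VI2"] = (out["Rg"] - out["Rr"]) / (out["Rg"] + out["Rr"])
    out["VI3"] = out["SDr"] / out["SDb"]
    out["VI4"] = out["SDr"] / out["SDy"]
    out["VI5"] = (out["SDr"] - out["SDb"]) / (out["SDr"] + out["SDb"])
    out["VI6"] = (out["SDr"] - out["SDy"]) / (out["SDr"] + out["SDy"])
    out["VI7"] = r[800.0] / r[680.0]
    out["VI8"] = r[750.0] / r[720.0] - 1.0
    out["VI9"] = (r[750.0] - r[445.0]) / (r[705.0] - r[445.0])
    out["VI10"] = (r[750.0] - r[445.0]) / (r[750.0] + r[705.0] - 2.0 * r[445.0])

    return pd.Series([out[k] for k in FEATURE_NAMES], index=list(FEATURE_NAMES),
                     name=spectrum.name)


def feature_table(
    spectra: pd.DataFrame,
    extrema_mode: str = "reflectance",
    area_mode: str = "reflectance",
) -> pd.DataFrame:
    """Per-sample table of the 24 characteristic variables."""
    rows = [
        extract_features(spectra.loc[sid], extrema_mode, area_mode)
        for sid in spectra.index
    ]
    return pd.DataFrame(rows, index=spectra.index)
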