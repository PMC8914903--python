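"""Undecimated dyadic (binary) wavelet decomposition of spectra.

The dyadic wavelet transform restricts the scale parameter to powers of
two, a = 2^j, while the translation stays per-band, so every level
yields approximation (A_j, low-frequency) and detail (D_j,
high-frequency) series of the full grid length, indexable by the
original band position.  This is the stationary (a-trous) wavelet
transform; PyWavelets provides the filter bank (Daubechies db2..db5)
and the transform itself, with the 2^(-j/2) per-level normalization
(``norm=True``).

Spectra whose length is not a multiple of 2^levels are extended
symmetrically before the transform and trimmed afterwards, so the
exposed coefficient series always align with the wavelength grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

__all__ = [
    "BASES",
    "WaveletConfig",
    "WaveletDecomposition",
    "decompose",
    "reconstruct",
    "coefficient_at",
    "detail_bank",
]

BASES = ("db2", "db3", "db4", "db5")


@dataclass
class WaveletConfig:
    """Decomposition settings: Daubechies basis, level count, boundary rule."""

    basis: str = "db2"
    levels: int = 5
    boundary: str = "symmetric"

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise ValueError(f"basis must be one of {BASES}, got {self.basis!r}")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.boundary not in ("symmetric", "periodic", "zero"):
            raise ValueError(f"unsupported boundary rule {self.boundary!r}")


_PAD_MODE = {"symmetric": "symmetric", "periodic": "wrap", "zero": "constant"}


def _pad(values: np.ndarray, block: int, boundary: str) -> tuple[np.ndarray, int]:
    n = values.shape[-1]
    pad = (-n) % block
    if pad == 0:
        return values, 0
    left = pad // 2
    widths = [(0, 0)] * (values.ndim - 1) + [(left, pad - left)]
    return np.pad(values, widths, mode=_PAD_MODE[boundary]), left


@dataclass
class WaveletDecomposition:
    """Full-grid-length A_j / D_j series for one spectrum.

    ``approx[j]`` and ``detail[j]`` (j = 1..levels) are aligned to
    ``grid``; the padded coefficient arrays needed for exact inversion
    are kept internally.
    """

    config: WaveletConfig
    grid: np.ndarray
    approx: dict[int, np.ndarray]
    detail: dict[int, np.ndarray]
    _padded: list[tuple[np.ndarray, np.ndarray]] = field(repr=False)
    _pad_left: int = field(repr=False)

    @property
    def basis(self) -> str:
        return self.config.basis

    @property
    def levels(self) -> int:
        return self.config.levels


def decompose(
    spectrum: pd.Series | np.ndarray, config: WaveletConfig | None = None
) -> WaveletDecomposition:
    """Stationary dyadic wavelet decomposition into 5 levels (default)."""
    config = config if config is not None else WaveletConfig()
    if isinstance(spectrum, pd.Series):
        grid = spectrum.index.to_numpy(dtype=float)
        values = spectrum.to_numpy(dtype=float)
    else:
        values = np.asarray(spectrum, dtype=float)
        grid = np.arange(values.size, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("spectrum contains non-finite values")
    n = values.size
    if 2**config.levels > n:
        raise ValueError(
            f"signal of {n} bands supports at most {int(np.log2(n))} levels, "
            f"{config.levels} requested"
        )
    padded, left = _pad(values, 2**config.levels, config.boundary)
    pairs = pywt.swt(padded, config.basis, level=config.levels, norm=True)
    # pairs = [(A_L, D_L), ..., (A_1, D_1)]
    approx, detail, stored = {}, {}, []
    for offset, (ca, cd) in enumerate(pairs):
        j = config.levels - offset
        approx[j] = ca[left:left + n]
        detail[j] = cd[left:left + n]
        stored.append((ca, cd))
    return WaveletDecomposition(
        config=config, grid=grid, approx=approx, detail=detail,
        _padded=stored, _pad_left=left,
    )


def reconstruct(
    decomposition: WaveletDecomposition,
    detail_levels: list[int] | None = None,
) -> np.ndarray:
    """Invert the transform; exact to floating precision.

    ``detail_levels`` restricts which detail levels are retained
    (``[]`` reconstructs from the coarsest approximation alone, giving
    the wavelet-smoothed curve).
    """
    keep = (
        set(range(1, decomposition.levels + 1))
        if detail_levels is None
        else set(detail_levels)
    )
    pairs = []
    for offset, (ca, cd) in enumerate(decomposition._padded):
        j = decomposition.levels - offset
        pairs.append((ca, cd if j in keep else np.zeros_like(cd)))
    rec = pywt.iswt(pairs, decomposition.basis, norm=True)
    n = decomposition.grid.size
    return np.asarray(rec)[decomposition._pad_left:decomposition._pad_left + n]


def coefficient_at(
    decomposition: WaveletDecomposition,
    band_type: str,
    level: int,
    band_index: int,
) -> float:
    """Single coefficient of the A ('A') or D ('D') series at a grid position."""
    if band_type not in ("A", "D"):
        raise ValueError("band_type must be 'A' or 'D'")
    series = decomposition.approx if band_type == "A" else decomposition.detail
    if level not in series:
        raise ValueError(
            f"level {level} out of range 1..{decomposition.levels}"
        )
    arr = series[level]
    if not 0 <= band_index < arr.size:
        raise ValueError(f"band index {band_index} out of range 0..{arr.size - 1}")
    return float(arr[band_index])


def detail_bank(
    spectra: pd.DataFrame,
    bases: tuple[str, ...] = BASES,
    levels: int = 5,
    boundary: str = "symmetric",
) -> dict[tuple[str, int], np.ndarray]:
    """Detail coefficient matrices for every (basis, level) combination.

    Returns {(basis, level): array of shape (n_samples, n_bands)} with
    coefficients aligned to the wavelength grid — the candidate pool for
    sensitivity-coefficient selection.
    """
    values = spectra.to_numpy(dtype=float)
    n = values.shape[1]
    if 2**levels > n:
        raise ValueError(f"{n} bands support at most {int(np.log2(n))} levels")
    padded, left = _pad(values, 2**levels, boundary)
    bank: dict[tuple[str, int], np.ndarray] = {}
    for basis in bases:
        pairs = pywt.swt(padded, basis, level=levels, norm=True, axis=-1)
        for offset, (_, cd) in enumerate(pairs):
            bank[(basis, levels - offset)] = cd[:, left:left + n]
    return bank
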