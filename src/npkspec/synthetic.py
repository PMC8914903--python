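"""Synthetic sweet-corn leaf reflectance spectra with a nutrient gradient.

Emulates a three-level nitrogen fertilization trial (N0 none, N1 low,
N2 high; 24 leaf samples per treatment by default).  Leaf nitrogen,
phosphorus and potassium contents follow the between-treatment ratios
observed in such trials: nitrogen peaks under moderate fertilization
(N1/N0 = 1.28, N2/N0 = 1.13) while phosphorus and potassium decline
with increasing application (P: N0/N1 = 1.47, N0/N2 = 1.93;
K: N0/N2 = 1.40, N1/N2 = 1.37).

Reflectance curves are a parametric sum of the canonical green-leaf
components — dark baseline, green peak near 550 nm, chlorophyll red
valley near 670 nm, logistic red edge between 680 and 760 nm whose
inflection shifts to longer wavelengths with nitrogen content, and a
near-infrared plateau — plus narrow nutrient-coupled absorption bumps
near 480, 610, 670 and 820 nm that carry the high-frequency information
the wavelet stages exploit, and optional additive band noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TREATMENTS",
    "NUTRIENTS",
    "SimConfig",
    "SyntheticDataset",
    "default_nutrient_means",
    "leaf_reflectance",
    "generate_dataset",
]

TREATMENTS = ("N0", "N1", "N2")
NUTRIENTS = ("N", "P", "K")

# Generator conventions for absolute contents (mass percent of dry leaf);
# only the between-treatment ratios are externally constrained.
_N_BASE = 2.5   # nitrogen at N0
_P_BASE = 0.45  # phosphorus at N0
_K_HIGH = 2.0   # potassium at N2


def default_nutrient_means() -> dict[str, tuple[float, float, float]]:
    """Per-treatment mean (N, P, K) leaf contents in mass percent.

    The returned means satisfy the trial's ratio structure exactly:
    N1/N0 = 1.28 and N2/N0 = 1.13 for nitrogen; N0/N1 = 1.47 and
    N0/N2 = 1.93 for phosphorus; N0/N2 = 1.40 and N1/N2 = 1.37 for
    potassium.
    """
    return {
        "N0": (_N_BASE, _P_BASE, _K_HIGH * 1.40),
        "N1": (_N_BASE * 1.28, _P_BASE / 1.47, _K_HIGH * 1.37),
        "N2": (_N_BASE * 1.13, _P_BASE / 1.93, _K_HIGH),
    }


@dataclass
class SimConfig:
    """Configuration of the synthetic trial.

    Parameters
    ----------
    n_per_treatment : int
        Leaf samples per fertilization level (three levels).
    wavelength_start, wavelength_end : float
        Wavelength grid limits in nm.
    n_bands : int
        Number of bands; must be >= 707 so that all band indices used by
        the wavelet sensitivity analysis exist on the grid.
    noise_sd : float
        Standard deviation of additive Gaussian band noise (reflectance
        units, homoscedastic).
    nutrient_cv : float
        Coefficient of variation of per-sample nutrient contents around
        their treatment mean.
    nutrient_means : dict or None
        treatment -> (N, P, K) means in %, defaults to
        :func:`default_nutrient_means`.
    seed : int
        Seed for all randomness in the generator.
    red_edge_shift_per_N : float
        Red-edge inflection shift in nm per percent leaf nitrogen.
    structural_sd : float
        Relative standard deviation of the per-leaf structural amplitude
        factor applied to the broad curve components (baseline, green
        peak, NIR shoulder).  Models leaf-to-leaf scattering/thickness
        variation that is independent of nutrient status and is what
        keeps broad characteristic variables noisier proxies than the
        narrow absorption features.
    red_edge_jitter_sd : float
        Standard deviation (nm) of nutrient-independent red-edge
        position jitter per leaf.
    """

    n_per_treatment: int = 24
    wavelength_start: float = 400.0
    wavelength_end: float = 1000.0
    n_bands: int = 1001
    noise_sd: float = 0.004
    nutrient_cv: float = 0.05
    nutrient_means: dict[str, tuple[float, float, float]] | None = None
    seed: int = 0
    red_edge_shift_per_N: float = 8.0
    structural_sd: float = 0.08
    red_edge_jitter_sd: float = 2.5

    def __post_init__(self) -> None:
        if self.n_per_treatment < 1:
            raise ValueError("n_per_treatment must be >= 1")
        if self.n_bands < 707:
            raise ValueError(
                "n_bands must be >= 707 (band indices up to 706 are used "
                "by the sensitivity-coefficient analysis)"
            )
        if not self.wavelength_start < self.wavelength_end:
            raise ValueError("wavelength grid must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.nutrient_cv < 0:
            raise ValueError("nutrient_cv must be >= 0")
        if self.structural_sd < 0 or self.red_edge_jitter_sd < 0:
            raise ValueError("structural variation parameters must be >= 0")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wavelength_start, self.wavelength_end, self.n_bands)


@dataclass
class SyntheticDataset:
    """Spectra matrix plus per-sample nutrient table.

    ``spectra``: rows = samples, columns = wavelengths (nm, float).
    ``samples``: treatment label and N/P/K contents (%) per sample.
    """

    spectra: pd.DataFrame
    samples: pd.DataFrame
    config: SimConfig = field(repr=False)


def _gauss(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


def leaf_reflectance(
    nutrients: tuple[float, float, float],
    grid: np.ndarray,
    noise_sd: float = 0.0,
    red_edge_shift_per_N: float = 8.0,
    rng: np.random.Generator | None = None,
    amplitude_factor: float = 1.0,
    red_edge_offset: float = 0.0,
) -> np.ndarray:
    """One leaf reflectance spectrum for given (N, P, K) contents in %.

    Deterministic for ``noise_sd = 0``.  The red-edge inflection moves
    to longer wavelengths with nitrogen; the narrow bumps near 480, 610,
    670 and 820 nm respond nonlinearly (power-law) to P, K and N, which
    is what makes the high-frequency wavelet detail a better predictor
    than any single broad feature.  ``amplitude_factor`` scales the
    broad (scattering-driven) components only and ``red_edge_offset``
    shifts the red-edge inflection, both modelling nutrient-independent
    leaf structure.
    """
    n, p, k = (float(v) for v in nutrients)
    if min(n, p, k) <= 0:
        raise ValueError(f"nutrient contents must be > 0, got {(n, p, k)}")
    if amplitude_factor <= 0:
        raise ValueError("amplitude_factor must be > 0")
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 350.0 or grid.max() > 1100.0:
        raise ValueError("wavelength grid must lie within [350, 1100] nm")
    if noise_sd > 0 and rng is None:
        raise ValueError("rng is required when noise_sd > 0")

    baseline = 0.060 - 0.006 * (n - _N_BASE)  # deeper absorption with more chlorophyll
    center = 688.0 + red_edge_shift_per_N * n + red_edge_offset
    refl = baseline
    refl = refl + (0.40 + 0.03 * (k - 2.5)) / (1.0 + np.exp(-(grid - center) / 9.0))
    refl = refl + (0.110 - 0.012 * (n - _N_BASE)) * _gauss(grid, 548.0, 16.0)
    # P status mildly raises the overall (scattering) reflectance level.
    refl = refl * amplitude_factor * (1.0 + 0.3 * (p - _P_BASE))
    # Narrow nutrient-coupled bumps: the fluctuation-sensitive regions.
    refl = refl + 0.015 * (p / _P_BASE) ** 1.3 * _gauss(grid, 480.0, 5.0)
    refl = refl + 0.012 * (k / 2.8) ** 1.4 * _gauss(grid, 610.0, 5.0)
    refl = refl + 0.014 * (n / _N_BASE) ** 1.5 * _gauss(grid, 670.0, 5.0)
    refl = refl + 0.012 * (n / _N_BASE) ** 1.2 * _gauss(grid, 820.0, 6.0)
    if noise_sd > 0:
        refl = refl + rng.normal(0.0, noise_sd, size=grid.shape)
    return np.clip(refl, 1e-6, 1.0 - 1e-6)


def generate_dataset(config: SimConfig | None = None) -> SyntheticDataset:
    """Generate the full trial: 3 x n_per_treatment spectra + nutrient table.

    Per-sample nutrient contents are drawn around the treatment means
    with coefficient of variation ``nutrient_cv`` (truncated at 20% of
    the mean so contents stay positive); spectra come from
    :func:`leaf_reflectance`.  Byte-identical under a fixed seed.
    """
    config = config if config is not None else SimConfig()
    rng = np.random.default_rng(config.seed)
    means = config.nutrient_means or default_nutrient_means()
    grid = config.wavelengths

    ids: list[str] = []
    rows: list[tuple] = []
    curves: list[np.ndarray] = []
    for treatment in TREATMENTS:
        mu = np.asarray(means[treatment], dtype=float)
        for i in range(config.n_per_treatment):
            npk = mu * (1.0 + config.nutrient_cv * rng.standard_normal(3))
            npk = np.maximum(npk, 0.2 * mu)
            amp = max(1.0 + config.structural_sd * rng.standard_normal(), 0.5)
            offset = config.red_edge_jitter_sd * rng.standard_normal()
            curve = leaf_reflectance(
                tuple(npk), grid, config.noise_sd, config.red_edge_shift_per_N,
                rng, amplitude_factor=amp, red_edge_offset=offset,
            )
            ids.append(f"{treatment}-{i + 1:02d}")
            rows.append((treatment, *npk))
            curves.append(curve)

    index = pd.Index(ids, name="sample_id")
    samples = pd.DataFrame(rows, columns=["treatment", *NUTRIENTS], index=index)
    spectra = pd.DataFrame(np.vstack(curves), index=index, columns=grid)
    return SyntheticDataset(spectra=spectra, samples=samples, config=config)
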