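"""Radiometric correction, replicate averaging, outlier removal and the
modeling/validation split.

Correction follows the standard white-board / dark-board protocol: with
raw counts I, white reference I_W and dark reference I_D, the corrected
signal is log10[(I - I_D)/(I_W - I_D)] (default, as used by the source
instrument software) or the plain reflectance factor
(I - I_D)/(I_W - I_D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "ReferenceSet",
    "SplitIndex",
    "radiometric_correct",
    "average_replicates",
    "remove_outliers",
    "split_modeling_validation",
]


@dataclass
class ReferenceSet:
    """White-board and dark-board reference spectra on the sample grid."""

    white: pd.Series
    dark: pd.Series

    def __post_init__(self) -> None:
        if not self.white.index.equals(self.dark.index):
            raise ValueError("white and dark references are on different grids")
        diff = self.white.to_numpy() - self.dark.to_numpy()
        if np.any(diff <= 0):
            band = self.white.index[int(np.argmax(diff <= 0))]
            raise ValueError(
                f"white reference must exceed dark at every band; "
                f"violated at {band} nm"
            )


def radiometric_correct(
    raw: pd.Series, refs: ReferenceSet, mode: str = "log10-ratio"
) -> pd.Series:
    """Correct a raw spectrum against white/dark references.

    mode="log10-ratio" (default): log10[(I - I_D)/(I_W - I_D)];
    mode="ratio": (I - I_D)/(I_W - I_D).
    """
    if mode not in ("log10-ratio", "ratio"):
        raise ValueError(f"unknown correction mode {mode!r}")
    if not raw.index.equals(refs.white.index):
        raise ValueError("raw spectrum and references are on different grids")
    num = raw.to_numpy(dtype=float) - refs.dark.to_numpy(dtype=float)
    den = refs.white.to_numpy(dtype=float) - refs.dark.to_numpy(dtype=float)
    ratio = num / den
    if mode == "ratio":
        return pd.Series(ratio, index=raw.index, name=raw.name)
    if np.any(ratio <= 0):
        band = raw.index[int(np.argmax(ratio <= 0))]
        raise ValueError(
            f"log10-ratio correction undefined: raw <= dark at {band} nm"
        )
    return pd.Series(np.log10(ratio), index=raw.index, name=raw.name)


def average_replicates(
    replicates: list[pd.Series], expected_count: int = 4
) -> pd.Series:
    """Band-wise arithmetic mean of replicate spectra of one leaf.

    The replicate count is recorded in the result's ``attrs``; a count
    different from ``expected_count`` is allowed (the protocol default
    is four points per leaf).
    """
    if len(replicates) < 1:
        raise ValueError("need at least one replicate")
    grid = replicates[0].index
    for rep in replicates[1:]:
        if not rep.index.equals(grid):
            raise ValueError("replicate spectra are on mismatched wavelength grids")
    mean = pd.Series(
        np.mean([r.to_numpy(dtype=float) for r in replicates], axis=0),
        index=grid,
        name=replicates[0].name,
    )
    mean.attrs["n_replicates"] = len(replicates)
    mean.attrs["expected_count"] = expected_count
    return mean


def remove_outliers(
    spectra: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    method: str = "mahalanobis-pca",
    threshold: float = 0.999,
    n_components: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame]:
    """Flag grossly abnormal spectra before modeling.

    method="mahalanobis-pca": squared Mahalanobis distance of each
    sample in the space of the first ``n_components`` principal
    components, flagged above the chi-square quantile ``threshold``.
    method="none": identity.

    Returns (retained spectra, retained samples, report); the report has
    one row per sample with its distance and removal flag.
    """
    ids = spectra.index
    if method == "none":
        report = pd.DataFrame(
            {"distance2": np.nan, "removed": False}, index=ids
        )
        return spectra, samples, report
    if method != "mahalanobis-pca":
        raise ValueError(f"unknown outlier method {method!r}")
    if len(spectra) < 10:
        raise ValueError("mahalanobis-pca outlier screening needs >= 10 samples")

    k = min(n_components, len(spectra) - 1)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(spectra.to_numpy(dtype=float))
    z = scores / np.sqrt(pca.explained_variance_)
    d2 = np.sum(z**2, axis=1)
    cutoff = stats.chi2.ppf(threshold, df=k)
    removed = d2 > cutoff
    report = pd.DataFrame({"distance2": d2, "removed": removed}, index=ids)
    kept = ids[~removed]
    samples_kept = samples.loc[kept] if samples is not None else None
    return spectra.loc[kept], samples_kept, report


@dataclass
class SplitIndex:
    """Disjoint modeling/validation sample-id partition."""

    modeling_ids: list
    validation_ids: list
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.modeling_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"split is not a partition, shared ids: {overlap}")


def split_modeling_validation(
    sample_ids,
    fraction: float = 2.0 / 3.0,
    seed: int = 0,
    treatments: pd.Series | None = None,
) -> SplitIndex:
    """Random modeling/validation split (default two-thirds modeling).

    With ``treatments`` given, the split is stratified by treatment
    label; by default it is a plain uniform random split.  Sizes are
    round(fraction * n) modeling and the remainder validation, so the
    trial's 72 samples yield 48/24.
    """
    ids = list(sample_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 samples to split")
    rng = np.random.default_rng(seed)

    def _one(group: list) -> tuple[list, list]:
        n_model = int(round(fraction * len(group)))
        n_model = min(max(n_model, 1), len(group) - 1)
        perm = rng.permutation(len(group))
        model = [group[i] for i in perm[:n_model]]
        valid = [group[i] for i in perm[n_model:]]
        return model, valid

    if treatments is None:
        modeling, validation = _one(ids)
    else:
        modeling, validation = [], []
        for _, grp in pd.Series(ids).groupby(treatments.loc[ids].to_numpy()):
            m, v = _one(list(grp))
            modeling += m
            validation += v
    return SplitIndex(modeling_ids=modeling, validation_ids=validation, seed=seed)
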