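import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from npkspec.synthetic import SimConfig, generate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic trial (72 samples) under the default conditions."""
    return generate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free trial with all sample-to-sample variation switched off."""
    cfg = SimConfig(seed=3, noise_sd=0.0, nutrient_cv=0.0,
                    structural_sd=0.0, red_edge_jitter_sd=0.0)
    return generate_dataset(cfg)


@pytest.fixture()
def grid():
    return np.linspace(400.0, 1000.0, 1001)


@pytest.fixture()
def spectrum_series(clean_dataset):
    """A single deterministic leaf spectrum as a wavelength-indexed Series."""
    return clean_dataset.spectra.iloc[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_series(wavelengths, values, name="s"):
    return pd.Series(np.asarray(values, dtype=float),
                     index=np.asarray(wavelengths, dtype=float), name=name)
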