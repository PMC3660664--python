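"""Shared fixtures: small synthetic rasters and binned collections."""

import numpy as np
import pytest

import popdecode as pd


def make_site(rng, n_trials=12, n_timepoints=30, label_values=("A", "B", "C"), **info):
    """One random continuous-valued site with a cyclic label schedule."""
    labels = [label_values[i % len(label_values)] for i in range(n_trials)]
    return pd.RasterSite(
        data=rng.normal(size=(n_trials, n_timepoints)),
        labels={"stimulus_ID": labels},
        site_info={"site_index": int(rng.integers(1000)), **info},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic population: 50 sites, 7 objects x 3 positions."""
    return pd.generate_dataset(pd.SyntheticConfig(seed=2024))


@pytest.fixture(scope="session")
def default_binned(default_dataset):
    """Default dataset binned at 150-point windows stepped by 50."""
    return pd.bin_sites(default_dataset, pd.BinSpec(150, 50))
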