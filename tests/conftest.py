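"""Shared fixtures: small synthetic sessions generated once per run."""

import numpy as np
import pytest

import odorcode as oc


@pytest.fixture(scope="session")
def small_dataset():
    """A compact session: enough cells/trials for qualitative checks."""
    cfg = oc.SyntheticConfig(n_cells_pcx=80, n_cells_ob=30,
                             n_trials_per_stimulus=8, n_blank_trials=8,
                             seed=11)
    return oc.generate_dataset(cfg)


@pytest.fixture(scope="session")
def medium_dataset():
    """Larger cortical population for decoding and correlation structure."""
    cfg = oc.SyntheticConfig(n_cells_pcx=200, n_cells_ob=0, seed=12)
    return oc.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_stats(small_dataset):
    return oc.response_stats_table(small_dataset)


@pytest.fixture(scope="session")
def medium_stats(medium_dataset):
    return oc.response_stats_table(medium_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
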