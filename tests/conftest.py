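"""Shared pytest fixtures."""

import pytest

from msyphylo.simulate import SimConfig, SimDataset, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset() -> SimDataset:
    return simulate_dataset(SimConfig(seed=11, n_modern=30, n_ancient=20))
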