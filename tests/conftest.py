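import numpy as np
import pandas as pd
import pytest

from dietvirome import SimConfig, simulate_study


SMALL_SIM_KWARGS = dict(n_phage=40, n_bacteria=32, n_linked_pairs=8, n_hgt_events=30)


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic study, shared across tests (read-only)."""
    return simulate_study(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_study(SimConfig(seed=11, **SMALL_SIM_KWARGS))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def group_map(sample_info: pd.DataFrame) -> dict:
    return dict(zip(sample_info["sample_id"], sample_info["group"]))
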