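import numpy as np
import pandas as pd
import pytest

from forageome.io import AsvTable
from forageome.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study, shared across tests (read-only)."""
    return simulate_study(SimConfig(seed=20170501))


@pytest.fixture()
def small_table():
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(6, 8))
    return AsvTable([f"S{i}" for i in range(6)],
                    [f"A{i}" for i in range(8)], counts)


@pytest.fixture()
def tiny_metadata():
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(6)],
        "bird_id": ["B0", "B0", "B1", "B1", "B2", "B2"],
        "day_of_year": [121, 130, 125, 135, 128, 140],
        "habitat_at_collection": ["marine"] * 3 + ["terrestrial"] * 3,
        "sex": ["F", "F", "M", "M", "F", "F"],
        "api": [3, 4, 2, 5, 3, 6],
        "flock_size": [10, 12, 8, 30, 22, 5],
        "is_negative_control": [False] * 6,
    })
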