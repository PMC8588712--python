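import numpy as np
import pandas as pd
import pytest

from bnmmi import DiscreteDataset, ScenarioSpec, run_scenario


def make_dataset(columns: dict, levels=None, missing_marker="?") -> DiscreteDataset:
    frame = pd.DataFrame({k: list(map(str, v)) for k, v in columns.items()}, dtype=object)
    return DiscreteDataset(frame, dict(levels or {}), missing_marker)


@pytest.fixture
def toy_missing():
    """Six records; 'fee' missing in rows 1 and 4 (0-based)."""
    return make_dataset(
        {
            "operation": ["0", "1", "1", "0", "1", "0"],
            "fee": ["low", "?", "high", "low", "?", "high"],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)


@pytest.fixture(scope="session")
def mcar05_result():
    """MCAR 5% scenario at reduced replication, shared across tests.

    1,000 replicates of n=2000 — large enough that validity estimates
    carry a Monte-Carlo standard error below 0.006.
    """
    return run_scenario(
        ScenarioSpec("MCAR", 0.05, n=2000, reps=1000, seed=101)
    )


@pytest.fixture(scope="session")
def mar20_result():
    """MAR 20% scenario at reduced replication, shared across tests."""
    return run_scenario(
        ScenarioSpec("MAR", 0.20, n=2000, reps=1000, seed=202)
    )
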