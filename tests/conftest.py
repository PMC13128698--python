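import numpy as np
import pandas as pd
import pytest

from esdbench import ESDataset, EffectRecord, SimulationConfig, simulate_literature


@pytest.fixture
def csv_factory(tmp_path):
    """Write a dict of columns to a CSV and return its path."""

    def make(columns: dict, name: str = "effects.csv"):
        path = tmp_path / name
        pd.DataFrame(columns).to_csv(path, index=False)
        return path

    return make


@pytest.fixture
def small_dataset() -> ESDataset:
    records = [
        EffectRecord(yi=y, sei=s, study_id=f"s{i}", group=g)
        for i, (y, s, g) in enumerate(
            [
                (0.10, 0.10, "a"),
                (-0.25, 0.20, "a"),
                (0.40, 0.15, "a"),
                (0.05, 0.08, "b"),
                (0.60, 0.30, "b"),
                (0.32, 0.12, "b"),
                (0.21, 0.18, None),
            ]
        )
    ]
    return ESDataset(records)


@pytest.fixture(scope="session")
def literature() -> ESDataset:
    """A moderately sized simulated literature with varying SEs."""
    ds, _ = simulate_literature(
        SimulationConfig(k=80, mu=0.25, tau=0.15, selection=0.5, seed=20240917)
    )
    return ds


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(987654321)
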