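import numpy as np
import pandas as pd
import pytest

from lagcv import SimulationConfig, build_feature_matrix, simulate


@pytest.fixture(scope="session")
def short_series():
    """~1.1 years of simulated data; cheap, for mechanics-level tests."""
    return simulate(SimulationConfig(n_days=400, seed=5))


@pytest.fixture(scope="session")
def long_series():
    """Five calendar years, the span the default feature layout assumes."""
    return simulate(SimulationConfig(n_days=1818, seed=5))


@pytest.fixture(scope="session")
def features_long(long_series):
    return build_feature_matrix(long_series)


@pytest.fixture(scope="session")
def features_short(short_series):
    return build_feature_matrix(short_series)


@pytest.fixture
def toy_csv(tmp_path):
    """Write a small daily-series CSV and return its path."""

    def _write(rows, name="toy.csv", header="date,death,temperature,o3,pm25"):
        path = tmp_path / name
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    return _write
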