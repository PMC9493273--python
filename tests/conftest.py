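import numpy as np
import pandas as pd
import pytest

from soilnorm import MarkerMatrix, SimulationConfig, TrialTable, simulate_dataset


def make_table(rows):
    """rows: iterable of (line, env, year, location, soil, yield)."""
    return TrialTable(
        pd.DataFrame(rows, columns=["line", "env", "year", "location", "soil", "yield"])
    )


@pytest.fixture
def toy_table():
    """Three records: g1 and g2 in e1 (silt loam), g1 in e2 (clay)."""
    return make_table(
        [
            ("g1", "e1", 2020, "farmA", "silt_loam", 40.0),
            ("g1", "e2", 2020, "farmA", "clay", 44.0),
            ("g2", "e1", 2020, "farmA", "silt_loam", 38.0),
        ]
    )


@pytest.fixture
def toy_markers():
    return MarkerMatrix(
        pd.DataFrame(
            [[0.0, 2.0], [2.0, 0.0], [1.0, 1.0]],
            index=["g1", "g2", "g3"],
            columns=["m1", "m2"],
        )
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but structured trial: 30 lines, 2 years x 5 environments."""
    cfg = SimulationConfig(n_lines=30, p_markers=80, n_years=2, seed=11)
    return simulate_dataset(cfg)
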