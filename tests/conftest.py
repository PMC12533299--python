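import numpy as np
import pandas as pd
import pytest

from ctcmet import (IntensityMatrix, SimCellConfig, simulate_cell_matrix,
                    three_subgroup_config, two_population_config)


@pytest.fixture(scope="session")
def tiny_config():
    """2+2 cells, 5 metabolites, no dropout, no jitter: exact bookkeeping."""
    return SimCellConfig(
        n_cells_per_population={"A": 2, "B": 2},
        signature_sets={"A": frozenset({0}), "B": frozenset({1})},
        n_metabolites=5, dropout_rate=0.0, ppm_jitter_sd=0.0, is_log_sd=0.0)


@pytest.fixture(scope="session")
def two_group_screen():
    """One default two-population dataset plus its screen, shared across tests."""
    from ctcmet import screen_differential
    cfg = two_population_config()
    matrix, truth = simulate_cell_matrix(cfg, seed=11)
    table, model = screen_differential(matrix, truth.cell_labels)
    return cfg, matrix, truth, table, model


@pytest.fixture(scope="session")
def subgroup_dataset():
    """One default three-subgroup dataset with its autoscaled matrix."""
    from ctcmet import impute_and_scale
    cfg = three_subgroup_config()
    matrix, truth = simulate_cell_matrix(cfg, seed=7)
    scaled = impute_and_scale(matrix, scale="autoscale")
    return cfg, matrix, scaled, truth


def random_matrix(n, m, seed, missing=0.0):
    rng = np.random.default_rng(seed)
    values = np.power(10.0, rng.normal(0, 0.5, (n, m)))
    if missing:
        values[rng.random((n, m)) < missing] = np.nan
    data = pd.DataFrame(values,
                        index=[f"c{i}" for i in range(n)],
                        columns=[f"M{j:04d}" for j in range(m)])
    return IntensityMatrix(data, state="is_normalized")
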