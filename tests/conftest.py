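import pandas as pd
import pytest

from metphos.simulate import SimConfig, make_design, simulate_phospho


@pytest.fixture(scope="session")
def small_design() -> pd.DataFrame:
    """2 cell lines x 4 conditions x 3 replicates = 24 runs."""
    return make_design(SimConfig(n_cell_lines=2, n_sites=10))


@pytest.fixture(scope="session")
def panel_design() -> pd.DataFrame:
    """The full 12-line design (144 runs)."""
    return make_design(SimConfig())


@pytest.fixture(scope="session")
def small_simulation():
    """A small complete simulated experiment (200 sites, 12 lines)."""
    config = SimConfig(n_sites=200, seed=11)
    report, design, truth = simulate_phospho(config)
    return config, report, design, truth


def log2_matrix_from_report(report, floor=500.0):
    """Representative precursor -> floored log2 matrix, no normalization
    (keeps test runtimes low where LOESS is irrelevant)."""
    from metphos.preprocess import (floor_log_transform, report_to_matrix,
                                    select_representative_precursor)
    best = select_representative_precursor(report)
    return floor_log_transform(report_to_matrix(best), floor)
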