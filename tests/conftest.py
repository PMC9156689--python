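import warnings

import numpy as np
import pandas as pd
import pytest

from dosagebalance.preprocess import CountMatrix, rpm_normalize
from dosagebalance.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated dosage study shared across tests."""
    cfg = SimConfig(n_lines=3, n_mirnas=150, n_genes=80, seed=20)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def study_dir(small_study, tmp_path_factory):
    from dosagebalance.simulate import write_study

    d = tmp_path_factory.mktemp("study")
    write_study(small_study, d)
    return d


@pytest.fixture()
def toy_counts():
    """Deterministic 4-feature, 2x2-sample count matrix."""
    counts = pd.DataFrame(
        {
            "a1": [50, 100, 0, 10],
            "a2": [60, 90, 0, 12],
            "b1": [100, 100, 5, 11],
            "b2": [110, 110, 4, 9],
        },
        index=["f1", "f2", "f3", "f4"],
    )
    return CountMatrix(counts, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})


@pytest.fixture()
def toy_rpm(toy_counts):
    return rpm_normalize(toy_counts)


@pytest.fixture(autouse=True)
def _quiet_degenerate_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        yield


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
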