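"""Shared fixtures.

The expensive simulation panels are session-scoped so the acceptance-level
checks and the statistical property tests share one run.  Panel sizes:
50 adaptive-procedure listeners, 100 listeners per baseline strategy, and
20 listeners per band count in the sweep — all at 500 trials with the fast
rank-one (fisher) selection mode.
"""

from __future__ import annotations

import numpy as np
import pytest

from qbif import BandGrid, SpectralWeights
from qbif.simulators import nband_sweep, run_strategy_experiment

SEED = 1


@pytest.fixture(scope="session")
def grid6() -> BandGrid:
    return BandGrid()


@pytest.fixture(scope="session")
def qbif_outcome():
    return run_strategy_experiment("qbif", n_listeners=50, n_trials=500, seed=SEED)


@pytest.fixture(scope="session")
def compound_outcome():
    return run_strategy_experiment("compound", n_listeners=100, n_trials=500, seed=SEED)


@pytest.fixture(scope="session")
def random_outcome():
    return run_strategy_experiment("random", n_listeners=100, n_trials=500, seed=SEED)


@pytest.fixture(scope="session")
def nband_curves():
    return nband_sweep([4, 6, 8, 10], n_listeners=20, n_trials=500, seed=SEED)


def make_weights(values) -> SpectralWeights:
    arr = np.asarray(values, dtype=float)
    return SpectralWeights(tuple(arr / arr.sum()))
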