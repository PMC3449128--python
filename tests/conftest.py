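import numpy as np
import pytest

import fibrostab as fs
from fibrostab.fixtures import sample_ensemble


@pytest.fixture(scope="session")
def stable_params():
    return fs.DEFAULT_STABLE


@pytest.fixture(scope="session")
def unstable_params():
    return fs.DEFAULT_UNSTABLE_B24


@pytest.fixture(scope="session")
def existence_ensemble():
    """200 parameter sets with an interior equilibrium (both sign branches)."""
    return sample_ensemble("existence_eq13", 100, seed=11) + sample_ensemble(
        "existence_eq14", 100, seed=12
    )


@pytest.fixture(scope="session")
def ode_stable_ensemble():
    return sample_ensemble("ode_stable", 100, seed=21)


@pytest.fixture(scope="session")
def coeff_ensemble(existence_ensemble):
    """Equilibrium linearizations of the existence ensemble."""
    return [
        (p, fs.linear_coefficients(p, fs.interior_equilibrium(p)))
        for p in existence_ensemble
    ]


def match_spectra(a: np.ndarray, b: np.ndarray) -> float:
    """Max |difference| after optimal pairing of two unordered spectra."""
    from scipy.optimize import linear_sum_assignment

    cost = np.abs(a[:, None] - b[None, :])
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].max())
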