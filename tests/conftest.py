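"""Shared fixtures: small stable systems, default grids, and the
session-scoped in-silico runs used by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from structec.forward import EffectiveConnectivity, HemodynamicParams, NoiseSpectraParams, default_grid
from structec.simulate import SimulationConfig


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def stable_a3():
    """Stable 3-region effective connectivity used across modules."""
    return EffectiveConnectivity(
        np.array(
            [
                [-0.5, 0.3, 0.0],
                [0.2, -0.5, -0.25],
                [0.0, 0.4, -0.5],
            ]
        )
    )


@pytest.fixture
def hemo3():
    return HemodynamicParams.canonical(3)


@pytest.fixture
def white_noise3():
    """Flat neuronal spectrum, negligible observation noise."""
    return NoiseSpectraParams(np.full(3, np.log(0.01)), -np.inf, np.full(3, np.log(1e-8)), -np.inf)


def random_stable_system(rng: np.random.Generator, n: int = 3) -> EffectiveConnectivity:
    a = 0.3 * rng.standard_normal((n, n))
    np.fill_diagonal(a, -rng.uniform(0.4, 0.8, n))
    w = np.linalg.eigvals(a).real.max()
    if w > -0.1:
        a[np.diag_indices(n)] -= w + 0.1
    return EffectiveConnectivity(a)


@pytest.fixture
def small_sim_config():
    return SimulationConfig(n_regions=3, subjects=4, instantiations=2, n_samples=400, seed=5)
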