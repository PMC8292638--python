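import numpy as np
import pytest

from vte_kit.core_io import NONVTE, VTE, FeatureTable
from vte_kit.synthetic import SimConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """One 20-trial simulated session shared by read-only tests."""
    return simulate_session(SimConfig(n_trials=20, seed=7))


@pytest.fixture(scope="session")
def gaussian_features():
    """Balanced 142-per-class table of 7 weakly informative Gaussian features."""
    rng = np.random.default_rng(11)
    n = 142
    x_vte = rng.normal(0.4, 1.0, size=(n, 7))
    x_non = rng.normal(0.0, 1.0, size=(n, 7))
    values = np.vstack([x_vte, x_non])
    labels = np.array([VTE] * n + [NONVTE] * n, object)
    return FeatureTable(
        np.arange(2 * n), [f"f{i}" for i in range(7)], values, labels
    )
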