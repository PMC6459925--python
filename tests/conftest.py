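import numpy as np
import pandas as pd
import pytest

from mirecur import SimulationConfig, simulate


@pytest.fixture(scope="session")
def tiny_config():
    """Small panel, full-size cohort: fast but structurally faithful."""
    return SimulationConfig(
        n_target_probes=80,
        n_internal_controls=8,
        n_negative_controls=30,
        n_up_markers=2,
        n_down_markers=1,
        seed=3,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_config):
    """(panel, cohort, samples, raw matrix, truth) for the tiny design."""
    return simulate(tiny_config)


@pytest.fixture
def two_class_frame():
    """Well-separated 3-feature Gaussian classes, 30 + 30 patients."""
    rng = np.random.default_rng(42)
    x1 = rng.normal([2.0, 1.0, 0.0], 1.0, size=(30, 3))
    x0 = rng.normal([0.0, 0.0, 0.5], 1.0, size=(30, 3))
    X = pd.DataFrame(np.vstack([x1, x0]), columns=["a", "b", "c"])
    y = np.array([1] * 30 + [0] * 30)
    return X, y
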