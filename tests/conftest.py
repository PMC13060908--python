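import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netswitch import SimulationConfig, WindowStack, generate_scan

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_stack(n_nodes: int, n_layers: int, seed: int) -> WindowStack:
    """Random symmetric nonnegative hollow stack (a generic small fixture)."""
    r = np.random.default_rng(seed)
    a = r.uniform(0, 1, (n_nodes, n_nodes, n_layers))
    a = (a + a.transpose(1, 0, 2)) / 2
    for s in range(n_layers):
        np.fill_diagonal(a[:, :, s], 0)
    return WindowStack(a, 3, 1, [f"n{i}" for i in range(n_nodes)])


def planted_stack(
    n_nodes: int,
    n_layers: int,
    membership: np.ndarray,
    within: float = 0.9,
    across: float = 0.05,
) -> WindowStack:
    """Stack with a planted community structure per layer.

    ``membership`` is node x layer community labels; same-community pairs get
    weight ``within``, the rest ``across``.
    """
    a = np.full((n_nodes, n_nodes, n_layers), across)
    for s in range(n_layers):
        same = membership[:, s][:, None] == membership[:, s][None, :]
        a[:, :, s][same] = within
        np.fill_diagonal(a[:, :, s], 0)
    return WindowStack(a, 3, 1, [f"n{i}" for i in range(n_nodes)])


@pytest.fixture
def small_cohort():
    """A tiny labelled cohort with the default planted state difference."""
    cfg = SimulationConfig(n_nodes=8, n_time=300, window_length=40)
    scans, labels = [], []
    for i in range(6):
        state = "alert" if i < 3 else "drowsy"
        scans.append(generate_scan(cfg, state, seed=900 + i))
        labels.append(state)
    return cfg, scans, labels
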