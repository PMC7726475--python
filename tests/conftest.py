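"""Shared fixtures: small ground-truth models and simulated recordings."""

import numpy as np
import pytest

from dcgnet import GroundTruthModel, make_sparse_model, simulate_var1


@pytest.fixture(scope="session")
def model5():
    """Sparse 5-channel VAR(1) with known support (the standard benchmark)."""
    return make_sparse_model(5, density=0.2, seed=1)


@pytest.fixture(scope="session")
def recording5(model5):
    """t=2000 simulation from :func:`model5`."""
    return simulate_var1(model5, 2000, seed=2)


@pytest.fixture(scope="session")
def recording3():
    """Small, fast 3-channel recording for cheap structural tests."""
    model = make_sparse_model(3, density=0.3, seed=7)
    return simulate_var1(model, 400, seed=8)


def make_strong_weak_model(seed: int, m: int = 5):
    """Ground truth with 3 strong (|coef| in [0.4, 0.5]) and 3 weak
    (|coef| in [0.01, 0.03], i.e. at the t=2000 estimation noise floor)
    off-diagonal lag links; identity error precision.

    Returns (model, strong_positions, weak_positions).
    """
    rng = np.random.default_rng(seed)
    gamma = np.zeros((m, m))
    gamma[np.diag_indices(m)] = rng.uniform(0.2, 0.5, m)
    off = [(i, j) for i in range(m) for j in range(m) if i != j]
    idx = rng.choice(len(off), 6, replace=False)
    strong = [off[k] for k in idx[:3]]
    weak = [off[k] for k in idx[3:]]
    for (i, j) in strong:
        gamma[i, j] = rng.uniform(0.4, 0.5) * rng.choice([-1.0, 1.0])
    for (i, j) in weak:
        gamma[i, j] = rng.uniform(0.01, 0.03) * rng.choice([-1.0, 1.0])
    rho = np.abs(np.linalg.eigvals(gamma)).max()
    if rho >= 0.95:
        gamma *= 0.9 / rho
    eye = np.eye(m)
    model = GroundTruthModel(
        gamma, np.zeros(m), eye, eye.copy(), [f"ch{i}" for i in range(m)]
    )
    return model, strong, weak


def support_f1(estimated: np.ndarray, true: np.ndarray) -> float:
    """F1 of the off-diagonal nonzero pattern of a lag-matrix estimate."""
    m = true.shape[0]
    off = ~np.eye(m, dtype=bool)
    est = (np.abs(estimated) > 1e-12)[off]
    tru = (np.abs(true) > 1e-12)[off]
    tp = np.sum(est & tru)
    fp = np.sum(est & ~tru)
    fn = np.sum(~est & tru)
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else 1.0
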