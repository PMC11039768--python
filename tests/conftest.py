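import numpy as np
import pytest

from netgimme import PathPattern, StackedCov, default_atlas
from netgimme.simulate import simulate_var


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


def make_var_data(A, Phi, T, seed, standardize=False):
    """Simulate a series from (A, Phi) and return (X, StackedCov)."""
    X = simulate_var(np.asarray(A, float), np.asarray(Phi, float), T, seed)
    return X, StackedCov.from_data(X, standardize=standardize)


@pytest.fixture(scope="session")
def three_roi_fixture():
    """A 3-ROI series from a known uSEM: one contemporaneous path,
    three AR paths, one cross-lagged path."""
    p = 3
    A = np.zeros((p, p))
    A[1, 0] = 0.5
    Phi = np.diag([0.4, 0.3, 0.5])
    Phi[2, 0] = 0.3
    X, data = make_var_data(A, Phi, T=800, seed=42)
    pattern = PathPattern.ar_only(p).with_paths([(0, 1, 0), (0, 2, 1)])
    return {"A": A, "Phi": Phi, "X": X, "data": data, "pattern": pattern}
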