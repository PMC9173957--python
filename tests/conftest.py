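import numpy as np
import pytest

from cofsvm import FCMConfig, fcm_fit, fcm_update_memberships


@pytest.fixture(scope="session")
def two_blobs():
    """Two tight, far-separated Gaussian blobs with known means."""
    rng = np.random.default_rng(42)
    m0, m1 = np.array([0.0, 0.0]), np.array([10.0, 10.0])
    X = np.vstack(
        [m0 + rng.normal(0, 1.0, (200, 2)), m1 + rng.normal(0, 1.0, (200, 2))]
    )
    labels = np.repeat([0, 1], 200)
    return X, labels, np.vstack([m0, m1])


@pytest.fixture(scope="session")
def four_point_instance():
    """The 4-point / 2-centre instance used for hand-checkable updates."""
    X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
    centers = np.array([[0.0, 0.5], [10.0, 0.5]])
    U = fcm_update_memberships(X, centers, fuzzifier=2.0)
    return X, centers, U


@pytest.fixture(scope="session")
def separable_binary():
    """Linearly separable two-class set in 2-D (roles +1 / -1)."""
    rng = np.random.default_rng(7)
    Xp = rng.normal(0, 0.5, (30, 2)) + [3.0, 0.0]
    Xn = rng.normal(0, 0.5, (30, 2)) + [-3.0, 0.0]
    X = np.vstack([Xp, Xn])
    y = np.repeat([1, -1], 30)
    return X, y
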