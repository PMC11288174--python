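import numpy as np
import pytest

from petkin.experiments import (
    default_ground_truth,
    frame_schedule,
    simulate_ground_truth,
)


@pytest.fixture(scope="session")
def ground_truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def schedule():
    return frame_schedule()


@pytest.fixture(scope="session")
def clean_data(ground_truth, schedule):
    """Noiseless measurements and auxiliary curves at the ground truth."""
    return simulate_ground_truth(ground_truth, schedule)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_valid_config(rng, p=None, degenerate=False):
    """Random kinetic parameters and input curve in the solver domain.

    With ``degenerate`` the curve is engineered to hit the special branches
    mu_j = 0 and k2 + k3 + mu_j = 0 of the closed-form tissue curve.
    """
    from petkin.model import KineticParams, PolyexpCurve

    p = p if p is not None else int(rng.integers(1, 5))
    K = KineticParams(*rng.uniform(0.05, 0.5, size=3))
    mus = -rng.uniform(0.005, 15.0, size=p)
    while p > 1 and np.min(np.diff(np.sort(mus))) < 1e-6:
        mus = -rng.uniform(0.005, 15.0, size=p)
    if degenerate and p >= 2:
        mus[0] = 0.0
        mus[1] = -(K.k2 + K.k3)
    lams = rng.uniform(-10.0, 10.0, size=p)
    return K, PolyexpCurve(lams, mus)


def quadrature_ct(K, cp, t):
    """Independent oracle: adaptive quadrature of the integral representation
    C_T = (K1 k2/k) e^{-kt} int_0^t e^{ks} C_P + (K1 k3/k) int_0^t C_P."""
    from scipy.integrate import quad

    from petkin.model import eval_polyexp

    k = K.k2 + K.k3
    i1 = quad(lambda s: np.exp(k * (s - t)) * eval_polyexp(cp, s), 0, t,
              limit=400, epsabs=1e-13, epsrel=1e-12)[0]
    i2 = quad(lambda s: eval_polyexp(cp, s), 0, t,
              limit=400, epsabs=1e-13, epsrel=1e-12)[0]
    return K.K1 * K.k2 / k * i1 + K.K1 * K.k3 / k * i2
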