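"""Forward model for the irreversible two-tissue compartment model.

The tracer kinetics in each tissue region are governed by

    dC_F/dt = K1*C_P - (k2 + k3)*C_F,   dC_B/dt = k3*C_F,
    C_F(0) = C_B(0) = 0,

with C_T = C_F + C_B the (extra-vascular) tissue concentration measured by
PET.  The arterial plasma input C_P is parametrized as a polyexponential
sum(lambda_j * exp(mu_j * t)), which yields closed-form expressions for C_F,
C_B and C_T.  The whole-blood concentration relates to the plasma input via
the parent plasma fraction f(t): C_P = f * C_WB.

All rates are in 1/min and times in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolyexpCurve",
    "PlasmaFractionParams",
    "KineticParams",
    "ParameterVector",
    "MeasurementSchedule",
    "CompartmentState",
    "MeasurementSet",
    "eval_polyexp",
    "eval_plasma_fraction",
    "solve_compartments",
    "ct_closed_form",
    "c_wb",
    "c_pet",
    "pet_to_tissue",
    "forward_operator",
]

_MU_DISTINCT_TOL = 1e-12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolyexpCurve:
    """Polyexponential curve ``sum_j lambdas[j] * exp(mus[j] * t)``.

    Degree 0 (empty coefficient arrays) is the zero function.  The exponents
    must be pairwise distinct; coefficients and exponents must have equal
    length.
    """

    lambdas: np.ndarray
    mus: np.ndarray

    def __post_init__(self) -> None:
        lam = np.atleast_1d(np.asarray(self.lambdas, dtype=float))
        mu = np.atleast_1d(np.asarray(self.mus, dtype=float))
        if lam.shape != mu.shape or lam.ndim != 1:
            raise ValueError(
                f"coefficients and exponents must be 1-d of equal length, "
                f"got {lam.shape} and {mu.shape}"
            )
        if mu.size > 1:
            diffs = np.abs(mu[:, None] - mu[None, :])
            np.fill_diagonal(diffs, np.inf)
            if diffs.min() <= _MU_DISTINCT_TOL * max(1.0, np.abs(mu).max()):
                raise ValueError("exponents mu must be pairwise distinct")
        object.__setattr__(self, "lambdas", lam)
        object.__setattr__(self, "mus", mu)

    @property
    def degree(self) -> int:
        return self.lambdas.size

    def __call__(self, t):
        return eval_polyexp(self, t)


@dataclass(frozen=True)
class PlasmaFractionParams:
    """Biexponential parent plasma fraction f(t) = A*e^{xi1 t} + (1-A)*e^{xi2 t}.

    f(0) = 1 by construction.  A >= 0 and xi1, xi2 <= 0 so that f decays from
    one as metabolites accumulate in blood.  The uniqueness degree of this
    family (number of samples pinning it down) is q = 4.
    """

    A: float
    xi1: float
    xi2: float

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError(f"amplitude A must be >= 0, got {self.A}")
        if self.xi1 > 0 or self.xi2 > 0:
            raise ValueError("exponents xi1, xi2 must be <= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.xi1, self.xi2])

    def __call__(self, t):
        return eval_plasma_fraction(self, t)


@dataclass(frozen=True)
class KineticParams:
    """Rate constants (K1, k2, k3) of one tissue region, all in 1/min.

    K1: plasma -> free tissue transport; k2: free tissue -> plasma efflux;
    k3: irreversible binding (trapping).  k2 + k3 must be nonzero for the
    closed-form solution to exist.
    """

    K1: float
    k2: float
    k3: float

    def __post_init__(self) -> None:
        if self.k2 + self.k3 == 0:
            raise ValueError("k2 + k3 must be nonzero")

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3])


@dataclass(frozen=True)
class MeasurementSchedule:
    """Tissue measurement times ``t`` (length T) and blood sample times ``s``
    (length q), both strictly increasing, in minutes."""

    t: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.t, dtype=float))
        s = np.atleast_1d(np.asarray(self.s, dtype=float))
        for name, arr in (("t", t), ("s", s)):
            if arr.size and (np.any(np.diff(arr) <= 0) or arr[0] < 0):
                raise ValueError(f"{name} must be strictly increasing and >= 0")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "s", s)

    @property
    def T(self) -> int:
        return self.t.size

    @property
    def q(self) -> int:
        return self.s.size


@dataclass(frozen=True)
class CompartmentState:
    """Free/bound/total tissue concentrations at the requested times."""

    times: np.ndarray
    CF: np.ndarray
    CB: np.ndarray

    @property
    def CT(self) -> np.ndarray:
        return self.CF + self.CB


@dataclass
class MeasurementSet:
    """Stacked measurement data: n x T tissue values, q whole-blood samples
    and the discrepancy noise level delta_y (Y-norm units)."""

    CT_matrix: np.ndarray
    CWB_samples: np.ndarray
    delta_y: float = 0.0

    def __post_init__(self) -> None:
        self.CT_matrix = np.atleast_2d(np.asarray(self.CT_matrix, dtype=float))
        self.CWB_samples = np.atleast_1d(np.asarray(self.CWB_samples, dtype=float))
        if self.delta_y < 0:
            raise ValueError("delta_y must be >= 0")

    @property
    def n_regions(self) -> int:
        return self.CT_matrix.shape[0]

    def stacked(self) -> np.ndarray:
        """Data vector y = (C_T entries region-major, zeros for the F^2 block).

        The second block of the forward operator is a consistency residual
        C_WB*f - C_P whose target value is zero, so the data vector carries
        zeros there regardless of the C_WB samples (those enter F itself).
        """
        return np.concatenate(
            [self.CT_matrix.ravel(), np.zeros(self.CWB_samples.size)]
        )


@dataclass(frozen=True)
class ParameterVector:
    """All unknowns x = (lambda, mu, m, K^1, ..., K^n) of the joint problem.

    Packing order: lambda_1..lambda_p, mu_1..mu_p, m = (A, xi1, xi2),
    then (K1, k2, k3) per region.  Packed length is 2p + 3 + 3n.
    """

    polyexp: PolyexpCurve
    fraction: PlasmaFractionParams
    regions: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))

    @property
    def p(self) -> int:
        return self.polyexp.degree

    @property
    def n(self) -> int:
        return len(self.regions)

    @property
    def size(self) -> int:
        return 2 * self.p + 3 + 3 * self.n

    def pack(self) -> np.ndarray:
        parts = [self.polyexp.lambdas, self.polyexp.mus, self.fraction.as_array()]
        parts += [K.as_array() for K in self.regions]
        return np.concatenate(parts)

    @classmethod
    def unpack(cls, x: np.ndarray, p: int, n: int) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        if x.size != 2 * p + 3 + 3 * n:
            raise ValueError(
                f"packed length {x.size} != 2*{p}+3+3*{n} = {2 * p + 3 + 3 * n}"
            )
        lam, mu = x[:p], x[p:2 * p]
        A, xi1, xi2 = x[2 * p:2 * p + 3]
        regions = tuple(
            KineticParams(*x[2 * p + 3 + 3 * i:2 * p + 6 + 3 * i]) for i in range(n)
        )
        return cls(PolyexpCurve(lam, mu), PlasmaFractionParams(A, xi1, xi2), regions)


# index helpers for the packed layout -------------------------------------

def lambda_slice(p: int) -> slice:
    return slice(0, p)


def mu_slice(p: int) -> slice:
    return slice(p, 2 * p)


def fraction_slice(p: int) -> slice:
    return slice(2 * p, 2 * p + 3)


def kinetic_slice(p: int, n: int) -> slice:
    return slice(2 * p + 3, 2 * p + 3 + 3 * n)


# ---------------------------------------------------------------------------
# stable exponential-integral helpers
# ---------------------------------------------------------------------------

def _phi(z: np.ndarray) -> np.ndarray:
    """expm1(z)/z, with the removable singularity phi(0) = 1 filled in."""
    z = np.asarray(z, dtype=float)
    out = np.ones_like(z)
    nz = z != 0.0
    out[nz] = np.expm1(z[nz]) / z[nz]
    return out


def _G(d, t):
    """(exp(d*t) - 1)/d elementwise, equal to t at d = 0.  Stable for all d."""
    d = np.asarray(d, dtype=float)
    t = np.asarray(t, dtype=float)
    return t * _phi(d * t)


def _Gprime(d, t):
    """d/dd of (exp(d*t)-1)/d, with a series branch near d*t = 0.

    For |z| = |d*t| below 1e-3 the closed form (t*e^{dt} - G)/d suffers
    cancellation; the Taylor series t^2*(1/2 + z/3 + z^2/8 + z^3/30) is then
    accurate to ~1e-13 relative.
    """
    d = np.asarray(d, dtype=float)
    t = np.asarray(t, dtype=float)
    d, t = np.broadcast_arrays(d, t)
    z = d * t
    small = np.abs(z) < 1e-3
    out = np.empty_like(z)
    zs = z[small]
    out[small] = t[small] ** 2 * (0.5 + zs / 3.0 + zs**2 / 8.0 + zs**3 / 30.0)
    big = ~small
    out[big] = (t[big] * np.exp(z[big]) - _G(d[big], t[big])) / d[big]
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def eval_polyexp(curve: PolyexpCurve, t):
    """Evaluate sum_j lambda_j * exp(mu_j * t) elementwise."""
    t = np.asarray(t, dtype=float)
    if curve.degree == 0:
        return np.zeros_like(t)
    return np.exp(np.multiply.outer(t, curve.mus)) @ curve.lambdas


def eval_plasma_fraction(params: PlasmaFractionParams, t):
    """Evaluate f(t) = A*exp(xi1*t) + (1-A)*exp(xi2*t)."""
    t = np.asarray(t, dtype=float)
    return params.A * np.exp(params.xi1 * t) + (1.0 - params.A) * np.exp(
        params.xi2 * t
    )


def solve_compartments(K: KineticParams, cp: PolyexpCurve, times) -> CompartmentState:
    """Closed-form solution (C_F, C_B) of the compartment ODEs for a
    polyexponential input.

    C_F(t) = K1 e^{-kt} int_0^t e^{ks} C_P(s) ds  with k = k2 + k3, and
    C_B(t) = k3 int_0^t C_F(s) ds = -(k3/k) C_F(t) + (K1 k3/k) int_0^t C_P.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    k = K.k2 + K.k3
    if cp.degree == 0:
        z = np.zeros_like(t)
        return CompartmentState(times=t, CF=z, CB=z.copy())
    d = k + cp.mus  # shape (p,)
    # int_0^t e^{ks} e^{mu s} ds = G(k+mu, t); times exp(-kt) for C_F
    Gd = _G(d[None, :], t[:, None])  # (T, p)
    CF = K.K1 * np.exp(-k * t) * (Gd @ cp.lambdas)
    int_cp = _G(cp.mus[None, :], t[:, None]) @ cp.lambdas
    CB = -(K.k3 / k) * CF + (K.K1 * K.k3 / k) * int_cp
    return CompartmentState(times=t, CF=CF, CB=CB)


def ct_closed_form(K: KineticParams, cp: PolyexpCurve, times) -> np.ndarray:
    """Total tissue concentration C_T(t) = C_F + C_B in closed form.

    Equivalent grouping of the explicit polyexponential expansion:

        C_T = (K1 k2 / k) * sum_j lambda_j e^{-kt} G(k+mu_j, t)
            + (K1 k3 / k) * sum_j lambda_j G(mu_j, t),     k = k2+k3,

    with G(d, t) = (e^{dt}-1)/d evaluated stably through expm1 so that the
    degenerate cases mu_j = 0 (linear-in-t term) and k2+k3+mu_j = 0
    (t*e^{-kt} term) come out as exact limits rather than 0/0.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    k = K.k2 + K.k3
    if cp.degree == 0:
        return np.zeros_like(t)
    P = np.exp(-k * t) * (_G((k + cp.mus)[None, :], t[:, None]) @ cp.lambdas)
    Q = _G(cp.mus[None, :], t[:, None]) @ cp.lambdas
    return K.K1 * (K.k2 * P + K.k3 * Q) / k


def c_wb(cp_values, f_values) -> np.ndarray:
    """Whole-blood concentration C_WB = C_P / f (f must be positive)."""
    cp_values = np.asarray(cp_values, dtype=float)
    f_values = np.asarray(f_values, dtype=float)
    if np.any(f_values <= 0):
        raise ZeroDivisionError("parent plasma fraction must be positive")
    return cp_values / f_values


def c_pet(ct_values, cwb_values, VB: float) -> np.ndarray:
    """Measured PET signal: convex mix (1-VB)*C_T + VB*C_WB of tissue and
    blood, with VB the fractional blood volume."""
    if not 0.0 <= VB <= 1.0:
        raise ValueError(f"VB must be in [0, 1], got {VB}")
    return (1.0 - VB) * np.asarray(ct_values, float) + VB * np.asarray(
        cwb_values, float
    )


def pet_to_tissue(cpet_values, cwb_values, VB: float) -> np.ndarray:
    """Exact left inverse of :func:`c_pet`: recover C_T from C_PET and C_WB."""
    if VB >= 1.0:
        raise ValueError("VB must be < 1 to invert the blood-volume mixing")
    return (np.asarray(cpet_values, float) - VB * np.asarray(cwb_values, float)) / (
        1.0 - VB
    )


def forward_operator(
    x: ParameterVector, schedule: MeasurementSchedule, cwb_data
) -> np.ndarray:
    """Joint forward operator F(x) = (F^1(x), F^2(x)) stacked into R^{nT+q}.

    F^1 stacks the tissue curves C_T^i(t_l) region-major; F^2 is the
    plasma-consistency residual C_WB(s_l)*f_m(s_l) - C_P(s_l) against the
    measured whole-blood samples ``cwb_data`` (given data, never recomputed
    from x).
    """
    cwb_data = np.atleast_1d(np.asarray(cwb_data, dtype=float))
    if cwb_data.size != schedule.q:
        raise ValueError(
            f"cwb_data has length {cwb_data.size}, schedule expects q={schedule.q}"
        )
    F1 = np.concatenate(
        [ct_closed_form(K, x.polyexp, schedule.t) for K in x.regions]
    )
    F2 = cwb_data * eval_plasma_fraction(x.fraction, schedule.s) - eval_polyexp(
        x.polyexp, schedule.s
    )
    return np.concatenate([F1, F2])
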