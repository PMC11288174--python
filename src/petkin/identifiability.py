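"""Checkable sufficient conditions for unique kinetic-parameter recovery.

From tissue curves alone, the rates k2, k3 of every region and the K1
profile (up to one global scale zeta shared by all regions and the input
amplitude) are uniquely determined, provided

* enough measurement time points: T >= 2(p+3) for input degree p,
* a region-distinctness condition: for every input exponent, at least three
  regions with pairwise-distinct k3 and k2+k3 whose tissue curves actually
  carry that exponent (the "assumption (A)" disjunction below),

which in turn is implied by having at least p+3 regions with pairwise
distinct k3 and pairwise distinct k2+k3.  Adding q whole-blood samples,
with q at least the uniqueness degree of the parent-fraction family
(q = 4 for the biexponential model), pins zeta = 1 and recovers f.

All "distinct"/"nonzero" judgements are made at a relative floating-point
tolerance; margins below 1e-4 are flagged as practically non-identifiable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .model import ParameterVector

__all__ = [
    "IdentifiabilityReport",
    "check_assumption_A",
    "check_region_distinctness",
    "min_timepoints",
    "min_blood_samples",
    "align_scale",
    "generalized_polyexp_root_bound",
]

DEFAULT_TOL = 1e-9
_PRACTICAL_MARGIN = 1e-4

#: registered parent-fraction families and their uniqueness degree q
FRACTION_FAMILY_DEGREES = {"biexponential": 4}


@dataclass
class IdentifiabilityReport:
    passes_A: bool
    witnesses: dict = field(default_factory=dict)  # exponent index -> region triple
    distinct_region_count: int = 0
    required_T: int = 0
    required_q: int = 0
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "passes_A": self.passes_A,
            "witnesses": {int(k): list(v) for k, v in self.witnesses.items()},
            "distinct_region_count": self.distinct_region_count,
            "required_T": self.required_T,
            "required_q": self.required_q,
            "notes": list(self.notes),
        }


def _distinct(a: float, b: float, tol: float) -> bool:
    return abs(a - b) > tol * max(1.0, abs(a), abs(b))


def min_timepoints(p: int) -> int:
    """Minimum number of tissue measurement time points, 2(p+3), that
    guarantees unique identifiability for an input of degree p."""
    if p < 0:
        raise ValueError("degree p must be >= 0")
    return 2 * (p + 3)


def min_blood_samples(fraction_model: str) -> int:
    """Uniqueness degree q of a registered parent-fraction family: the number
    of whole-blood samples needed to pin the global scale and recover f."""
    try:
        return FRACTION_FAMILY_DEGREES[fraction_model]
    except KeyError:
        raise KeyError(
            f"unknown fraction family {fraction_model!r}; "
            f"registered: {sorted(FRACTION_FAMILY_DEGREES)}"
        ) from None


def generalized_polyexp_root_bound(m_list) -> int:
    """Upper bound sum(m_i) - 1 on the number of real roots of
    P_1(t)e^{mu_1 t} + ... + P_l(t)e^{mu_l t} with deg P_i = m_i - 1."""
    m_list = list(m_list)
    if not m_list:
        raise ValueError("multiplicity list must be nonempty")
    if any(m < 1 for m in m_list):
        raise ValueError("all multiplicities must be >= 1")
    return sum(m_list) - 1


def check_region_distinctness(regions, p: int, tol: float = DEFAULT_TOL):
    """True iff >= p+3 regions can be chosen with pairwise-distinct k3 and
    pairwise-distinct k2+k3 — the simple sufficient condition for the
    region-distinctness assumption.

    Returns (ok, count) where count is the size of the largest such subset
    found.
    """
    if p < 1:
        raise ValueError("degree p must be >= 1")
    k3s = [K.k3 for K in regions]
    sums = [K.k2 + K.k3 for K in regions]
    n = len(regions)
    need = p + 3

    def subset_ok(idx):
        for a, b in itertools.combinations(idx, 2):
            if not _distinct(k3s[a], k3s[b], tol):
                return False
            if not _distinct(sums[a], sums[b], tol):
                return False
        return True

    best = 0
    # largest subset first; n is small in practice (a handful of ROIs)
    for size in range(n, 0, -1):
        if size <= best:
            break
        for idx in itertools.combinations(range(n), size):
            if subset_ok(idx):
                best = size
                break
    return best >= need, best


def check_assumption_A(
    config: ParameterVector, tol: float = DEFAULT_TOL
) -> IdentifiabilityReport:
    """Check the region-distinctness assumption for unique identifiability.

    For every input exponent index j0 there must exist three regions i_1,
    i_2, i_3 with pairwise-distinct k3 and pairwise-distinct k2+k3, with
    mu_{j0} + k3 != 0, and such that either mu_{j0} + k2 + k3 = 0 or the
    lumped coefficient sum over j with mu_j + k2 + k3 != 0 of
    lambda_j / (k2 + k3 + mu_j) is nonzero (i.e. the e^{-(k2+k3)t} term of
    that region's tissue curve does not accidentally vanish).
    """
    cp = config.polyexp
    p = cp.degree
    regions = config.regions
    if p < 1 or len(regions) < 1:
        raise ValueError("need p >= 1 and at least one region")
    if np.any(cp.lambdas == 0):
        raise ValueError("all lambda_j must be nonzero")

    notes: list = []
    witnesses: dict = {}
    passes = True

    def region_clause(j0: int, i: int) -> bool:
        K = regions[i]
        ksum = K.k2 + K.k3
        mu0 = cp.mus[j0]
        if not _distinct(mu0 + K.k3, 0.0, tol):
            return False
        if not _distinct(mu0 + ksum, 0.0, tol):
            # mu_{j0} + k2 + k3 = 0 branch of the disjunction
            return True
        active = np.array([_distinct(m + ksum, 0.0, tol) for m in cp.mus])
        terms = cp.lambdas[active] / (ksum + cp.mus[active])
        total = terms.sum()
        scale = np.abs(terms).sum()
        if scale == 0.0:
            return False
        if abs(total) <= tol * scale:
            return False
        if abs(total) < _PRACTICAL_MARGIN * scale:
            notes.append(
                f"exponent {j0}, region {i}: coefficient-sum margin "
                f"{abs(total) / scale:.2e} below {_PRACTICAL_MARGIN:g} — "
                "practically non-identifiable"
            )
        return True

    for j0 in range(p):
        found = None
        for triple in itertools.combinations(range(len(regions)), 3):
            k3s = [regions[i].k3 for i in triple]
            sums = [regions[i].k2 + regions[i].k3 for i in triple]
            if not all(
                _distinct(a, b, tol)
                for a, b in itertools.combinations(k3s, 2)
            ):
                continue
            if not all(
                _distinct(a, b, tol)
                for a, b in itertools.combinations(sums, 2)
            ):
                continue
            if all(region_clause(j0, i) for i in triple):
                found = triple
                break
        if found is None:
            passes = False
            notes.append(f"no witness region triple for exponent index {j0}")
        else:
            witnesses[j0] = found

    _, count = check_region_distinctness(regions, p=max(p, 1), tol=tol)
    return IdentifiabilityReport(
        passes_A=passes,
        witnesses=witnesses,
        distinct_region_count=count,
        required_T=min_timepoints(p),
        required_q=min_blood_samples("biexponential"),
        notes=notes,
    )


def align_scale(x_a: ParameterVector, x_b: ParameterVector):
    """Resolve the global K1/input-amplitude scale between two parameter
    vectors describing the same tissue curves.

    Without blood data, configurations (lambda, K1) and (lambda/zeta,
    zeta*K1)... more precisely (zeta*lambda, K1/zeta) produce identical
    tissue curves.  This returns ``zeta`` = median over regions of
    K1_a / K1_b (so that K1_a = zeta * K1_b when the two are gauge
    equivalent), an aligned copy of x_b mapped into x_a's gauge
    (K1 -> zeta*K1, lambda -> lambda/zeta), and a consistency ``spread``:
    the relative spread of the per-region K1 ratios (0 when the two vectors
    are exactly gauge equivalent in the K1 profile).

    Returns (zeta, aligned_x_b, spread, ratios).
    """
    if x_a.p != x_b.p or x_a.n != x_b.n:
        raise ValueError("parameter vectors must share degrees p and n")
    K1a = np.array([K.K1 for K in x_a.regions])
    K1b = np.array([K.K1 for K in x_b.regions])
    if np.any(K1b == 0):
        raise ZeroDivisionError("x_b has a zero K1 entry")
    ratios = K1a / K1b
    zeta = float(np.median(ratios))
    if zeta == 0:
        raise ZeroDivisionError("median K1 ratio is zero")
    spread = float(np.max(np.abs(ratios - zeta)) / max(abs(zeta), 1e-300))
    from .model import KineticParams, PolyexpCurve  # local to avoid cycle noise

    aligned = ParameterVector(
        polyexp=PolyexpCurve(x_b.polyexp.lambdas / zeta, x_b.polyexp.mus),
        fraction=x_b.fraction,
        regions=tuple(
            KineticParams(K.K1 * zeta, K.k2, K.k3) for K in x_b.regions
        ),
    )
    return zeta, aligned, spread, ratios
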