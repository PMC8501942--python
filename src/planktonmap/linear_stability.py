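"""Linearisation, Jury classification and the Neimark-Sacker critical step.

For a planar map with characteristic polynomial
``M(xi) = xi^2 - Tr xi + Dt`` and ``M(1) > 0``, the Jury conditions
classify a fixed point by the signs of ``M(-1)`` and ``Dt - 1``:

* sink            M(-1) > 0 and Dt < 1
* source          M(-1) > 0 and Dt > 1
* saddle          M(-1) < 0
* nonhyperbolic   Tr^2 - 4 Dt < 0 and Dt = 1 (complex pair on the unit circle)

The interior fixed point of the plankton map is independent of the step
size ``h`` while its Jacobian is not, so ``h`` acts as a bifurcation
parameter: the nonhyperbolic (Neimark-Sacker) step size ``h*`` solves
``Dt(h) = 1`` with a complex eigenvalue pair.

The Jacobian entries here are closed-form partial derivatives of the map
itself (quotient rule applied to the two rational components), not a
transcription of any tabulated matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .equilibria import interior_equilibrium
from .model_core import DomainError, ModelParams, State

__all__ = [
    "JacobianReport",
    "StabilityClassification",
    "CriticalStep",
    "map_jacobian",
    "jury_classify",
    "classify_equilibrium",
    "critical_step",
    "NoCrossingError",
]

#: half-width of the band around a Jury boundary reported as "marginal"
BOUNDARY_TOL = 1e-10


class NoCrossingError(RuntimeError):
    """Dt(h) = 1 has no admissible solution in the requested range."""


@dataclass(frozen=True)
class JacobianReport:
    """2x2 linearisation of the map at a state, with derived scalars."""

    j11: float
    j12: float
    j21: float
    j22: float

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.j11, self.j12], [self.j21, self.j22]])

    @property
    def trace(self) -> float:
        return self.j11 + self.j22

    @property
    def det(self) -> float:
        return self.j11 * self.j22 - self.j12 * self.j21

    @property
    def M1(self) -> float:
        """M(1) = 1 - Tr + Dt."""
        return 1.0 - self.trace + self.det

    @property
    def Mm1(self) -> float:
        """M(-1) = 1 + Tr + Dt."""
        return 1.0 + self.trace + self.det

    @property
    def discriminant(self) -> float:
        return self.trace**2 - 4.0 * self.det

    @property
    def eigenvalues(self) -> tuple[complex, complex]:
        """Roots of M(xi); the first has non-negative imaginary part."""
        tr, dt = self.trace, self.det
        disc = self.discriminant
        if disc < 0.0:
            root = complex(tr / 2.0, math.sqrt(-disc) / 2.0)
            return root, root.conjugate()
        s = math.sqrt(disc)
        return complex((tr + s) / 2.0), complex((tr - s) / 2.0)


@dataclass(frozen=True)
class StabilityClassification:
    verdict: str      # sink | source | saddle | nonhyperbolic | marginal
    lemma_case: str   # a | b | c | d | hypothesis-violated | boundary
    M1: float
    Mm1: float
    det: float
    trace: float
    discriminant: float


@dataclass(frozen=True)
class CriticalStep:
    """Neimark-Sacker critical step size and its certificates."""

    h_star: float
    bracket: tuple[float, float]
    residual: float                # |Dt(h*) - 1|
    transversality: float          # d sqrt(Dt)/dh at h*
    non_resonant: bool             # Tr(h*) not in {-2, 0, 1, 2}
    trace_at_star: float
    eq_closed_form: float          # tabulated closed-form h expression at h*
    closed_form_discrepancy: float


def map_jacobian(params: ModelParams, s: State) -> JacobianReport:
    """Closed-form Jacobian of the NSFD map at a non-negative state.

    At (0, 0) the off-diagonal entries vanish exactly and the diagonal is
    ``((1+hr)/(1+E h q1), 1/(1 + h delta + E h q2))``.
    """
    p, z = s
    if not (math.isfinite(p) and math.isfinite(z)) or p < 0.0 or z < 0.0:
        raise DomainError(f"state must be finite and non-negative, got {s!r}")
    a, r, k, h = params.a, params.r, params.k, params.h
    alpha, beta, rho = params.alpha, params.beta, params.rho
    ap = a + p

    # p-component: N1/D1 with N1 = (1+hr) p
    D1 = 1.0 + h * (r / k * p + alpha * z / ap + params.m1 * p * p
                    + params.q1 * params.E)
    D1_p = h * (r / k - alpha * z / ap**2 + 2.0 * params.m1 * p)
    j11 = (1.0 + h * r) * (D1 - p * D1_p) / D1**2
    j12 = -(1.0 + h * r) * p * h * alpha / ap / D1**2

    # z-component: N2/D2 with N2 = (1 + h beta p/(a+p)) z
    growth = 1.0 + h * beta * p / ap
    D2 = 1.0 + h * (rho * p / ap + params.delta + params.m2 * z
                    + params.q2 * params.E)
    j21 = (z * h * beta * a / ap**2 * D2
           - growth * z * h * rho * a / ap**2) / D2**2
    j22 = growth * (D2 - z * h * params.m2) / D2**2
    return JacobianReport(j11, j12, j21, j22)


def jury_classify(tr: float, dt: float,
                  boundary_tol: float = BOUNDARY_TOL) -> StabilityClassification:
    """Classify a fixed point from (Tr, Dt) via the Jury conditions.

    Values within ``boundary_tol`` of a case boundary are reported as
    "marginal" rather than forced into a case.  ``M(1) < 0`` violates the
    standing hypothesis of the four-case lemma (recorded in
    ``lemma_case``), but the verdict is still decided: the real roots
    then straddle +1, giving a saddle when ``M(-1) > 0`` and a source
    (second root below -1) when ``M(-1) < 0``.  ``M(1) = 0`` means an
    eigenvalue exactly at +1 and is marginal.
    """
    M1 = 1.0 - tr + dt
    Mm1 = 1.0 + tr + dt
    disc = tr**2 - 4.0 * dt
    base = dict(M1=M1, Mm1=Mm1, det=dt, trace=tr, discriminant=disc)
    if M1 <= boundary_tol:
        if M1 < -boundary_tol and Mm1 > boundary_tol:
            return StabilityClassification("saddle", "hypothesis-violated", **base)
        if M1 < -boundary_tol and Mm1 < -boundary_tol:
            return StabilityClassification("source", "hypothesis-violated", **base)
        return StabilityClassification("marginal", "hypothesis-violated", **base)
    if abs(dt - 1.0) <= boundary_tol and disc < 0.0:
        return StabilityClassification("nonhyperbolic", "d", **base)
    if abs(Mm1) <= boundary_tol or abs(dt - 1.0) <= boundary_tol:
        return StabilityClassification("marginal", "boundary", **base)
    if Mm1 > 0.0 and dt < 1.0:
        return StabilityClassification("sink", "a", **base)
    if Mm1 > 0.0 and dt > 1.0:
        return StabilityClassification("source", "b", **base)
    return StabilityClassification("saddle", "c", **base)


def classify_equilibrium(
    params: ModelParams,
    which: str,
    point: State | None = None,
) -> tuple[StabilityClassification, dict[str, float]]:
    """Jury verdict at a named equilibrium plus supporting diagnostics.

    ``which`` is one of ``trivial``, ``axial``, ``interior``.  The
    diagnostics record the quantities the closed-form stability criteria
    compare (e.g. ``r`` vs ``E q1`` for the extinction point).
    """
    from .equilibria import axial_equilibrium  # local to avoid cycle noise

    if which == "trivial":
        at = State(0.0, 0.0)
    elif which == "axial":
        if point is None:
            at, exists = axial_equilibrium(params)
            if not exists:
                raise ValueError("axial equilibrium does not exist (r <= q1 E)")
        else:
            at = point
    elif which == "interior":
        if point is None:
            at, _, _, _ = interior_equilibrium(params)
            if at is None:
                raise ValueError("no interior equilibrium for these parameters")
        else:
            at = point
    else:
        raise ValueError(f"unknown equilibrium {which!r}")

    jac = map_jacobian(params, at)
    cls = jury_classify(jac.trace, jac.det)
    diag: dict[str, float] = {
        "p": at.p, "z": at.z,
        "trace": jac.trace, "det": jac.det,
        "M1": jac.M1, "Mm1": jac.Mm1,
    }
    if which == "trivial":
        diag["r"] = params.r
        diag["Eq1"] = params.E * params.q1
    return cls, diag


def _det_at(params: ModelParams, point: State, h: float) -> float:
    return map_jacobian(params.with_h(h), point).det


def critical_step(
    params: ModelParams,
    h_range: tuple[float, float] = (1e-4, 1.0),
    scan_nodes: int = 256,
) -> CriticalStep:
    """Locate the step size h* where Dt(h) = 1 with a complex pair.

    The interior fixed point itself does not depend on ``h``, so the
    crossing is found by a uniform scan of ``Dt(h) - 1`` over ``h_range``
    followed by bisection (Brent) to ~1e-12, restricted to crossings
    where the eigenvalues are complex.  Also reported: the transversality
    ``d sqrt(Dt)/dh`` at h* (one-sided safe central difference), the
    low-order non-resonance flags (Tr not in {-2, 0, 1, 2}), and the
    value of the tabulated closed-form expression for the critical step,
    whose discrepancy from h* is recorded rather than trusted.
    """
    point, _, _, _ = interior_equilibrium(params)
    if point is None:
        raise NoCrossingError("no interior equilibrium for these parameters")
    lo, hi = h_range
    hs = np.linspace(lo, hi, scan_nodes)
    vals = np.array([_det_at(params, point, h) - 1.0 for h in hs])
    h_star = None
    bracket = (lo, hi)
    for i in range(scan_nodes - 1):
        if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0.0:
            bracket = (float(hs[i]), float(hs[i + 1]))
            cand = (bracket[0] if vals[i] == 0.0 else
                    brentq(lambda h: _det_at(params, point, h) - 1.0,
                           *bracket, xtol=1e-14, rtol=8.9e-16))
            jac = map_jacobian(params.with_h(cand), point)
            if jac.discriminant < 0.0:
                h_star = float(cand)
                break
    if h_star is None:
        raise NoCrossingError(
            f"no Neimark-Sacker point in h range {h_range} "
            "(Dt(h) - 1 has no sign change with a complex pair)")

    residual = abs(_det_at(params, point, h_star) - 1.0)
    dh = 1e-6 * max(1.0, h_star)
    sq = lambda h: math.sqrt(_det_at(params, point, h))
    transversality = (sq(h_star + dh) - sq(h_star - dh)) / (2.0 * dh)
    tr = map_jacobian(params.with_h(h_star), point).trace
    non_resonant = all(abs(tr - v) > 1e-8 for v in (-2.0, 0.0, 1.0, 2.0))
    closed = _closed_form_h(params.with_h(h_star), point)
    return CriticalStep(
        h_star=h_star,
        bracket=bracket,
        residual=residual,
        transversality=transversality,
        non_resonant=non_resonant,
        trace_at_star=tr,
        eq_closed_form=closed,
        closed_form_discrepancy=closed - h_star,
    )


def _closed_form_h(params: ModelParams, point: State) -> float:
    """Tabulated closed-form expression for the nonhyperbolic step size.

    Evaluated verbatim with the auxiliary scalars
    ``sigma = delta + rho + E q2 - beta``, ``phi = beta + h beta delta -
    rho + E h beta q2``, ``eta = 1 + h r`` at the supplied ``h``; the
    expression is implicit in ``h``, so the caller records its value at
    the computed crossing and the discrepancy from it.  Kept for
    cross-reference only -- the crossing itself is always located on the
    exact Jacobian determinant.
    """
    a, r, k, h = params.a, params.r, params.k, params.h
    p, z = point
    m1, m2 = params.m1, params.m2
    E, q1 = params.E, params.q1
    alpha, beta, rho = params.alpha, params.beta, params.rho
    sigma = params.delta + rho + E * params.q2 - beta
    phi = beta + h * beta * params.delta - rho + E * h * beta * params.q2
    eta = 1.0 + h * r
    bracket_term = (a - k) * r + E * k * q1 + p * (2.0 * r + k * m1 * (2.0 * a + 3.0 * p))
    num = (a * phi * p * bracket_term
           + a * k * eta * (beta - rho) * m2 * (a + p) * z)
    den = p * z * (k * alpha * sigma**2
                   - m2 * (a * rho * bracket_term
                           - 2.0 * k * alpha * sigma * z
                           - k * alpha * m2 * z**2))
    return num / den
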