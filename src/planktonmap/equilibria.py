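"""Trapping region, fixed points and existence diagnostics of the plankton map.

Because the NSFD discretisation preserves equilibria, the fixed points of
the map are exactly the equilibria of the continuous model and do not
depend on the step size ``h``:

* the extinction point (0, 0);
* the zooplankton-free (axial) point (x, 0) with x the positive root of
  ``m1 x^2 + (r/k) x - (r - q1 E) = 0``;
* the interior coexistence point (p, z), characterised by the scalar
  root problem ``F(p) = 0`` with

      f(p) = (a + p) (r - r p/k - m1 p^2 - q1 E) / alpha         (z-nullcline)
      F(p) = a (beta-rho) / [(beta-rho) - (delta + m2 f(p) + q2 E)] - a - p

  and z = f(p).

Every orbit started in the box ``[0, k] x [0, k(beta-rho)/(m2(k+a))]``
stays there whenever ``beta > rho`` (the trapping region), and the
interior point, when it exists, lies inside that box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model_core import ModelParams, ParameterError, State, step, validate

__all__ = [
    "BoundingBox",
    "EquilibriumSet",
    "ExistenceReport",
    "WorkedBoundsReport",
    "PoleError",
    "bounding_box",
    "axial_equilibrium",
    "eval_f",
    "eval_F",
    "interior_equilibrium",
    "existence_report",
    "worked_bounds_report",
    "equilibrium_set",
]

#: nodes of the uniform sign-change scan of F over (0, k]
SCAN_NODES = 512
#: nodes of the lambda-grid for the derivative condition of the
#: uniqueness theorem
DERIV_GRID = 101


class PoleError(ArithmeticError):
    """F(p) evaluated at (or numerically on) its pole."""


@dataclass(frozen=True)
class BoundingBox:
    """Forward-invariant trapping box [0, p_max] x [0, z_max]."""

    p_max: float
    z_max: float

    def contains(self, s: State, slack: float = 0.0) -> bool:
        return (-slack <= s.p <= self.p_max + slack
                and -slack <= s.z <= self.z_max + slack)


@dataclass(frozen=True)
class EquilibriumSet:
    """The three fixed points with existence flags and map residuals."""

    trivial: State
    axial: State | None
    axial_exists: bool
    interior: State | None
    interior_exists: bool
    interior_residuals: tuple[float, float] | None
    unique: bool
    extra_roots: tuple[float, ...] = ()


@dataclass(frozen=True)
class ExistenceReport:
    """Inequality-by-inequality record of the uniqueness conditions.

    The interior point exists and is unique when (i) ``r > q1 E``; (ii)
    the net conversion margin ``beta - rho`` exceeds
    ``delta + m2 f(lambda) + q2 E`` on (0, k] (so F has a negative tail)
    while falling below it at ``lambda = 0`` is *not* required numerically
    -- we record the sign of F at both ends instead; and (iii) the
    derivative condition ``r - q1 E < (r/k + m1 lambda) lambda`` making F
    strictly decreasing.  The verdict is drawn from the recorded signs.
    """

    r_gt_q1E: bool
    F0_sign: int
    Fk_sign: int
    margin_at_0: float
    margin_at_k: float
    margin_positive_on_grid: bool
    derivative_condition_on_grid: bool
    verdict: str  # "unique" | "none" | "indeterminate"


@dataclass(frozen=True)
class WorkedBoundsReport:
    """Closed-form bound quantities with the frozen upper-bound variant.

    ``f_upper`` uses the constant form ``-(a+k)(m1 r^2 + q1 E)/alpha``
    (note ``r^2`` where the nullcline f carries ``lambda^2``); this
    variant is kept separate from :func:`eval_f` so the analysis path
    stays on the exact nullcline while these reference digits remain
    reproducible.
    """

    f0: float
    s0: float
    F0: float
    f_upper: float
    fprime_k: float
    Fprime_upper: float


def _require_analysis(params: ModelParams) -> None:
    report = validate(params)
    if not report.ok:
        raise ParameterError("; ".join(report.hard_errors))


def bounding_box(params: ModelParams) -> BoundingBox:
    """Trapping region (k, k(beta-rho)/(m2(k+a))); requires beta > rho."""
    _require_analysis(params)
    if params.m2 <= 0.0:
        raise ParameterError("m2 must be positive for a finite z bound")
    z_max = params.k * (params.beta - params.rho) / (params.m2 * (params.k + params.a))
    return BoundingBox(p_max=params.k, z_max=z_max)


def axial_equilibrium(params: ModelParams) -> tuple[State | None, bool]:
    """Zooplankton-free point ((sqrt(4 k^2 m1 r + r^2 - 4 E k^2 m1 q1) - r)/(2 k m1), 0).

    Returns ``(point, exists)``; the point is positive iff ``r > q1 E``.
    With ``m1 = 0`` the quadratic degenerates and the linear branch
    ``x = k (1 - q1 E / r)`` is used.
    """
    r, k, m1, q1E = params.r, params.k, params.m1, params.q1 * params.E
    if r <= q1E:
        return None, False
    if m1 == 0.0:
        x = k * (1.0 - q1E / r)
    else:
        x = (np.sqrt(4.0 * k**2 * m1 * r + r**2 - 4.0 * k**2 * m1 * q1E) - r) / (2.0 * k * m1)
    return State(float(x), 0.0), True


def eval_f(params: ModelParams, p: float) -> float:
    """Zooplankton nullcline z = f(p) = (a+p)(r - r p/k - m1 p^2 - q1 E)/alpha."""
    return ((params.a + p)
            * (params.r - params.r * p / params.k - params.m1 * p * p
               - params.q1 * params.E)
            / params.alpha)


def eval_F(params: ModelParams, p: float, pole_tol: float = 1e-12) -> float:
    """Interior fixed-point residual function F(p); raises PoleError at its pole."""
    margin = params.beta - params.rho
    denom = margin - (params.delta + params.m2 * eval_f(params, p)
                      + params.q2 * params.E)
    if abs(denom) <= pole_tol * max(1.0, abs(margin)):
        raise PoleError(f"F has a pole at p={p!r}")
    return params.a * margin / denom - params.a - p


def interior_equilibrium(
    params: ModelParams,
    tol: float = 1e-12,
) -> tuple[State | None, tuple[float, float] | None, bool, tuple[float, ...]]:
    """Interior point by bracketed root-finding of F on (0, k].

    A uniform scan (``SCAN_NODES`` nodes) locates every sign change of F;
    each bracket is polished by Brent's method to relative tolerance
    ``tol``.  Returns ``(point, map_residuals, unique, all_roots)``;
    ``point`` is the smallest root with positive ``z = f(p)``, and the
    residuals are the relative fixed-point defects of the two map
    components.  More than one sign change flags ``unique = False``
    rather than failing.
    """
    if tol <= 0.0:
        raise ValueError("tol must be positive")
    _require_analysis(params)
    k = params.k
    grid = np.linspace(1e-12 * k, k, SCAN_NODES)
    vals = np.empty_like(grid)
    for i, p in enumerate(grid):
        try:
            vals[i] = eval_F(params, p)
        except PoleError:
            vals[i] = np.nan
    def F_or_nan(p: float) -> float:
        try:
            return eval_F(params, p)
        except PoleError:
            return np.nan

    roots: list[float] = []
    for i in range(len(grid) - 1):
        lo, hi = vals[i], vals[i + 1]
        if np.isnan(lo) or np.isnan(hi):
            continue
        if lo == 0.0:
            roots.append(float(grid[i]))
        elif lo * hi < 0.0:
            # a bracket may straddle the pole of F instead of a root;
            # reject candidates where F is not actually small
            try:
                cand = float(brentq(F_or_nan, grid[i], grid[i + 1],
                                    xtol=tol * k, rtol=max(tol, 8.9e-16)))
            except (ValueError, PoleError):
                continue
            if abs(F_or_nan(cand)) <= 1e-6 * max(1.0, params.a):
                roots.append(cand)
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    roots = sorted(set(roots))
    positive = [p for p in roots if eval_f(params, p) > 0.0]
    if not positive:
        return None, None, False, tuple(roots)
    p_bar = positive[0]
    z_bar = eval_f(params, p_bar)
    point = State(p_bar, z_bar)
    nxt = step(params, point)
    residuals = (abs(nxt.p - p_bar) / max(1.0, abs(p_bar)),
                 abs(nxt.z - z_bar) / max(1.0, abs(z_bar)))
    return point, residuals, len(positive) == 1, tuple(roots)


def existence_report(params: ModelParams) -> ExistenceReport:
    """Evaluate every existence/uniqueness inequality and draw a verdict."""
    q1E = params.q1 * params.E
    r_ok = params.r > q1E
    margin = params.beta - params.rho
    lam = np.linspace(0.0, params.k, DERIV_GRID)

    def net_loss(p: float) -> float:
        return params.delta + params.m2 * eval_f(params, p) + params.q2 * params.E

    margin0 = margin - net_loss(0.0)
    margink = margin - net_loss(params.k)
    margin_on_grid = all(margin - net_loss(p) > 0.0 for p in lam[1:])
    deriv_ok = all(params.r - q1E < (params.r / params.k + params.m1 * x) * x
                   for x in lam[1:])

    def sign_of_F(p: float) -> int:
        try:
            v = eval_F(params, p)
        except PoleError:
            return 0
        return int(np.sign(v))

    F0s, Fks = sign_of_F(0.0), sign_of_F(params.k)
    if not r_ok or margin0 <= 0.0:
        verdict = "none"
    elif F0s > 0 and Fks < 0 and margin_on_grid:
        verdict = "unique"
    elif F0s > 0 and Fks < 0:
        verdict = "indeterminate"
    else:
        verdict = "none" if F0s <= 0 else "indeterminate"
    return ExistenceReport(
        r_gt_q1E=r_ok,
        F0_sign=F0s,
        Fk_sign=Fks,
        margin_at_0=margin0,
        margin_at_k=margink,
        margin_positive_on_grid=margin_on_grid,
        derivative_condition_on_grid=deriv_ok,
        verdict=verdict,
    )


def worked_bounds_report(params: ModelParams) -> WorkedBoundsReport:
    """Closed-form bound quantities (frozen upper-bound variant of f).

    f0 = a (r - q1 E)/alpha;  s0 = delta + m2 f0 + q2 E;
    F0 = a s0 / ((beta-rho) - s0);
    f_upper = -(a+k)(m1 r^2 + q1 E)/alpha;
    f'(k) of the exact nullcline; and the decreasingness witness
    F'(k) = -1 + a (beta-rho) m2 f'(k) / ((beta-rho) - (delta + m2 f_upper + q2 E))^2.
    """
    a, r, k, al = params.a, params.r, params.k, params.alpha
    m1, m2, q1E, q2E = params.m1, params.m2, params.q1 * params.E, params.q2 * params.E
    margin = params.beta - params.rho
    f0 = a * (r - q1E) / al
    s0 = params.delta + m2 * f0 + q2E
    if margin == s0:
        raise PoleError("F(0) pole: (beta-rho) equals delta + m2 f(0) + q2 E")
    F0 = a * s0 / (margin - s0)
    f_upper = -(a + k) * (m1 * r**2 + q1E) / al
    fprime_k = (-(a + k) * (r / k + 2.0 * m1 * k) / al
                + (r - r * k / k - m1 * k**2 - q1E) / al)
    denom = margin - (params.delta + m2 * f_upper + q2E)
    if denom == 0.0:
        raise PoleError("F'(k) pole in the frozen-variant denominator")
    Fprime_upper = -1.0 + a * margin * m2 * fprime_k / denom**2
    return WorkedBoundsReport(f0=f0, s0=s0, F0=F0, f_upper=f_upper,
                              fprime_k=fprime_k, Fprime_upper=Fprime_upper)


def equilibrium_set(params: ModelParams, tol: float = 1e-12) -> EquilibriumSet:
    """All fixed points of the map with existence flags and residuals."""
    axial, axial_ok = axial_equilibrium(params)
    interior, residuals, unique, roots = interior_equilibrium(params, tol)
    return EquilibriumSet(
        trivial=State(0.0, 0.0),
        axial=axial,
        axial_exists=axial_ok,
        interior=interior,
        interior_exists=interior is not None,
        interior_residuals=residuals,
        unique=unique,
        extra_roots=roots,
    )
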