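"""Neimark-Sacker normal form and first Lyapunov quantity of the plankton map.

At the critical step size ``h*`` the interior fixed point has a complex
eigenvalue pair on the unit circle.  Writing the map in shifted
coordinates ``(P, Z) = (p - p_bar, z - z_bar)`` and Taylor-expanding to
cubic order,

    (P, Z) -> J (P, Z) + (f(P,Z), g(P,Z)),

the similarity transformation ``P = v12 X``, ``Z = (l - v11) X - w Y``
with ``l = Tr/2`` and ``w = sqrt(4 Dt - Tr^2)/2`` brings the linear part
to the rotation form ``[[l, -w], [w, l]]``.  The transformed
nonlinearities ``(F(X,Y), G(X,Y))`` feed the standard complex normal-form
coefficients theta_20, theta_11, theta_02, theta_21, and the first
Lyapunov quantity

    Omega = -Re((1 - 2 xi1) xi2^2 / (1 - xi1) theta20 theta11)
            - |theta11|^2 / 2 - |theta02|^2 + Re(xi2 theta21),

with ``xi1 = l + i w`` the upper-half-plane eigenvalue and ``xi2`` its
conjugate.  ``Omega < 0`` marks a supercritical bifurcation: an
attracting invariant closed curve of radius ~ sqrt(h - h*) exists just
past criticality.  The Taylor coefficients are differentiated
symbolically (sympy) and cross-checked against Richardson-extrapolated
central differences.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import sympy as sp

from .equilibria import interior_equilibrium
from .linear_stability import map_jacobian
from .model_core import ModelParams, State, step

__all__ = [
    "NormalFormReport",
    "CanonicalForm",
    "ResonanceError",
    "taylor_coefficients",
    "taylor_coefficients_fd",
    "canonical_transform",
    "lyapunov_coefficient",
    "circle_radius_scan",
]

_PARAM_ORDER = ("a", "r", "k", "alpha", "beta", "delta", "rho",
                "m1", "m2", "q1", "q2", "E", "h")

#: (i, j) partial-derivative orders behind each Taylor slot v_(c)(s);
#: slot s in 1..9 maps to d^(i+j)/dP^i dZ^j with the 1/(i! j!) factor.
_SLOT_ORDERS = {
    1: (1, 0), 2: (0, 1),
    3: (2, 0), 4: (1, 1), 5: (0, 2),
    6: (3, 0), 7: (2, 1), 8: (1, 2), 9: (0, 3),
}


class ResonanceError(RuntimeError):
    """Low-order resonance (Tr in {-2, 0, 1, 2}) or zero transversality."""


@dataclass(frozen=True)
class CanonicalForm:
    ell: float
    wp: float
    T: np.ndarray | None = None
    T_inv: np.ndarray | None = None


@dataclass(frozen=True)
class NormalFormReport:
    h_star: float
    fixed_point: State
    v: dict[str, float]            # v11..v29 Taylor table
    ell: float
    wp: float
    theta20: complex
    theta11: complex
    theta02: complex
    theta21: complex
    omega: float
    omega_uncertainty: float       # |symbolic - finite-difference| route gap
    d_modulus_dh: float            # eigenvalue-modulus growth rate in h
    verdict: str                   # supercritical | subcritical | degenerate


@lru_cache(maxsize=1)
def _symbolic_derivatives():
    """Lambdified partials of both map components up to total order 3."""
    syms = sp.symbols(" ".join(_PARAM_ORDER), positive=True)
    a, r, k, alpha, beta, delta, rho, m1, m2, q1, q2, E, h = syms
    p, z = sp.symbols("p z", nonnegative=True)
    f1 = (1 + h * r) * p / (1 + h * (r / k * p + alpha * z / (a + p)
                                     + m1 * p**2 + q1 * E))
    f2 = ((1 + h * beta * p / (a + p)) * z
          / (1 + h * (rho * p / (a + p) + delta + m2 * z + q2 * E)))
    args = (*syms, p, z)
    table = {}
    for comp, expr in ((1, f1), (2, f2)):
        for slot, (i, j) in _SLOT_ORDERS.items():
            d = sp.diff(expr, p, i, z, j)
            table[(comp, slot)] = sp.lambdify(args, d, modules="numpy")
    return table


def _taylor_factor(i: int, j: int) -> float:
    return 1.0 / (math.factorial(i) * math.factorial(j))


def taylor_coefficients(params: ModelParams, h: float | None = None,
                        at: State | None = None) -> dict[str, float]:
    """Taylor table v11..v29 of the shifted map at the interior point.

    ``v(c)(1)``/``v(c)(2)`` are the Jacobian entries of component ``c``;
    slots 3-5 are the quadratic coefficients (P^2, PZ, Z^2) and 6-9 the
    cubic ones (P^3, P^2 Z, P Z^2, Z^3), i.e. the partial derivatives
    scaled by 1/(i! j!).  Symbolic differentiation path.
    """
    if h is None:
        h = params.h
    params = params.with_h(h)
    if at is None:
        at, _, _, _ = interior_equilibrium(params)
        if at is None:
            raise ValueError("no interior equilibrium for these parameters")
    table = _symbolic_derivatives()
    base = tuple(getattr(params, name) for name in _PARAM_ORDER)
    out: dict[str, float] = {}
    for (comp, slot), fn in table.items():
        i, j = _SLOT_ORDERS[slot]
        out[f"v{comp}{slot}"] = float(fn(*base, at.p, at.z)) * _taylor_factor(i, j)
    return out


def taylor_coefficients_fd(params: ModelParams | None, h: float | None = None,
                           at: State | None = None,
                           map_fn=None) -> dict[str, float]:
    """Finite-difference route to the same Taylor table (one Richardson level).

    Independent of the symbolic path: partial derivatives of the raw map
    are taken with central differences of the appropriate tensor order
    at steps ``e`` and ``e/2`` and Richardson-combined.  ``map_fn`` may
    replace the plankton map by any callable ``(p, z) -> (p', z')`` (the
    expansion point ``at`` is then required), which allows the machinery
    to be exercised on maps with known coefficients.
    """
    if map_fn is None:
        if h is None:
            h = params.h
        params = params.with_h(h)
        map_fn = lambda p, z: step(params, State(p, z), check=False)
    elif at is None:
        raise ValueError("an expansion point is required with a custom map_fn")
    if at is None:
        at, _, _, _ = interior_equilibrium(params)
        if at is None:
            raise ValueError("no interior equilibrium for these parameters")

    def component(comp: int, p: float, z: float) -> float:
        return map_fn(p, z)[comp - 1]

    def partial(comp: int, i: int, j: int, e_p: float, e_z: float) -> float:
        # i-th difference in p of the j-th difference in z
        def dz(p: float) -> float:
            if j == 0:
                return component(comp, p, at.z)
            offs = {1: [(1, 0.5), (-1, -0.5)],
                    2: [(1, 1.0), (0, -2.0), (-1, 1.0)],
                    3: [(2, 0.5), (1, -1.0), (-1, 1.0), (-2, -0.5)]}[j]
            return sum(w * component(comp, p, at.z + m * e_z)
                       for m, w in offs) / e_z**j
        if i == 0:
            return dz(at.p)
        offs = {1: [(1, 0.5), (-1, -0.5)],
                2: [(1, 1.0), (0, -2.0), (-1, 1.0)],
                3: [(2, 0.5), (1, -1.0), (-1, 1.0), (-2, -0.5)]}[i]
        return sum(w * dz(at.p + m * e_p) for m, w in offs) / e_p**i

    out: dict[str, float] = {}
    for comp in (1, 2):
        for slot, (i, j) in _SLOT_ORDERS.items():
            order = i + j
            e_base = 1e-4 if order <= 2 else 5e-3
            e_p = e_base * (1.0 + abs(at.p))
            e_z = e_base * (1.0 + abs(at.z))
            coarse = partial(comp, i, j, e_p, e_z)
            fine = partial(comp, i, j, e_p / 2.0, e_z / 2.0)
            # central differences are O(e^2): one Richardson level
            out[f"v{comp}{slot}"] = ((4.0 * fine - coarse) / 3.0
                                     * _taylor_factor(i, j))
    return out


def canonical_transform(tr: float, dt: float,
                        v11: float | None = None,
                        v12: float | None = None) -> CanonicalForm:
    """Rotation-form scalars (l, w) and, if v11/v12 are given, T and T^-1.

    Requires a complex eigenvalue pair (Tr^2 < 4 Dt).  ``T`` maps the
    canonical coordinates to the shifted ones: columns [[v12, 0],
    [l - v11, -w]].
    """
    disc = tr * tr - 4.0 * dt
    if disc >= 0.0:
        raise ValueError("real eigenvalues: canonical rotation form undefined")
    ell = tr / 2.0
    wp = math.sqrt(-disc) / 2.0
    if v11 is None or v12 is None:
        return CanonicalForm(ell, wp)
    T = np.array([[v12, 0.0], [ell - v11, -wp]])
    T_inv = np.array([[1.0 / v12, 0.0],
                      [(ell - v11) / (wp * v12), -1.0 / wp]])
    return CanonicalForm(ell, wp, T, T_inv)


def _thetas(v: dict[str, float], ell: float, wp: float
            ) -> tuple[complex, complex, complex, complex]:
    """Normal-form coefficients from the Taylor table, exactly.

    The transformed nonlinearities are polynomials in (X, Y) obtained by
    substituting P = v12 X and Z = (l - v11) X - w Y, so their partials
    at the origin come from exact polynomial expansion.
    """
    X, Y = sp.symbols("X Y")
    v12 = v["v12"]
    P = v12 * X
    Z = (ell - v["v11"]) * X - wp * Y

    def poly(comp: int) -> sp.Poly:
        c = lambda s: v[f"v{comp}{s}"]
        expr = (c(3) * P**2 + c(4) * P * Z + c(5) * Z**2
                + c(6) * P**3 + c(7) * P**2 * Z + c(8) * P * Z**2 + c(9) * Z**3)
        return sp.Poly(sp.expand(expr), X, Y)

    f_poly = poly(1)
    g_poly = poly(2)
    lam = ell - v["v11"]

    def partials(is_F: bool) -> dict[tuple[int, int], float]:
        out = {}
        for (i, j) in [(2, 0), (1, 1), (0, 2), (3, 0), (2, 1), (1, 2), (0, 3)]:
            cf = float(f_poly.coeff_monomial(X**i * Y**j))
            cg = float(g_poly.coeff_monomial(X**i * Y**j))
            # F = f/v12 ; G = (lam f / v12 - g)/w
            val = cf / v12 if is_F else (lam * cf / v12 - cg) / wp
            out[(i, j)] = val * math.factorial(i) * math.factorial(j)
        return out

    F = partials(True)
    G = partials(False)
    th20 = (F[(2, 0)] - F[(0, 2)] + 2.0 * G[(1, 1)]
            + 1j * (G[(2, 0)] - G[(0, 2)] - 2.0 * F[(1, 1)])) / 8.0
    th11 = (F[(2, 0)] + F[(0, 2)] + 1j * (G[(2, 0)] + G[(0, 2)])) / 4.0
    th02 = (F[(2, 0)] - F[(0, 2)] - 2.0 * G[(1, 1)]
            + 1j * (G[(2, 0)] - G[(0, 2)] + 2.0 * F[(1, 1)])) / 8.0
    th21 = ((F[(3, 0)] + F[(1, 2)] + G[(2, 1)] + G[(0, 3)])
            + 1j * (G[(3, 0)] + G[(1, 2)] - F[(2, 1)] - F[(0, 3)])) / 16.0
    return th20, th11, th02, th21


def _omega(th: tuple[complex, complex, complex, complex],
           ell: float, wp: float) -> float:
    th20, th11, th02, th21 = th
    xi1 = complex(ell, wp)
    xi2 = xi1.conjugate()
    term = ((1.0 - 2.0 * xi1) * xi2**2 / (1.0 - xi1)) * th20 * th11
    return (-term.real - 0.5 * abs(th11)**2 - abs(th02)**2
            + (xi2 * th21).real)


def lyapunov_coefficient(params: ModelParams,
                         h_star: float | None = None) -> NormalFormReport:
    """Full normal-form report at the critical step size.

    ``h_star`` defaults to the Dt(h) = 1 crossing located by
    :func:`planktonmap.linear_stability.critical_step`.  Raises
    :class:`ResonanceError` if the trace at criticality sits on a
    low-order resonance or the eigenvalue modulus is stationary in h.
    """
    from .linear_stability import critical_step

    if h_star is None:
        cs = critical_step(params)
        h_star = cs.h_star
        transversality = cs.transversality
        if not cs.non_resonant:
            raise ResonanceError("Tr(h*) at a low-order resonance")
    else:
        point, _, _, _ = interior_equilibrium(params)
        if point is None:
            raise ValueError("no interior equilibrium for these parameters")
        dh = 1e-6 * max(1.0, h_star)
        sq = lambda h: math.sqrt(map_jacobian(params.with_h(h), point).det)
        transversality = (sq(h_star + dh) - sq(h_star - dh)) / (2.0 * dh)

    at, _, _, _ = interior_equilibrium(params)
    jac = map_jacobian(params.with_h(h_star), at)
    tr, dt = jac.trace, jac.det
    if any(abs(tr - v) <= 1e-8 for v in (-2.0, 0.0, 1.0, 2.0)):
        raise ResonanceError(f"trace {tr} within 1e-8 of a low-order resonance")
    if abs(transversality) < 1e-12:
        raise ResonanceError("zero transversality at h*")
    cf = canonical_transform(tr, dt)

    v_sym = taylor_coefficients(params, h_star, at)
    v_fd = taylor_coefficients_fd(params, h_star, at)
    th = _thetas(v_sym, cf.ell, cf.wp)
    omega = _omega(th, cf.ell, cf.wp)
    omega_fd = _omega(_thetas(v_fd, cf.ell, cf.wp), cf.ell, cf.wp)

    if omega < 0.0:
        verdict = "supercritical"
    elif omega > 0.0:
        verdict = "subcritical"
    else:
        verdict = "degenerate"
    return NormalFormReport(
        h_star=h_star,
        fixed_point=at,
        v=v_sym,
        ell=cf.ell,
        wp=cf.wp,
        theta20=th[0],
        theta11=th[1],
        theta02=th[2],
        theta21=th[3],
        omega=omega,
        omega_uncertainty=abs(omega - omega_fd),
        d_modulus_dh=transversality,
        verdict=verdict,
    )


def circle_radius_scan(
    params: ModelParams,
    h_values,
    n_steps: int = 10_000,
    transient: int = 10_000,
    perturbation: float = 1e-4,
) -> list[dict[str, float]]:
    """Post-transient orbit radius around the interior point per step size.

    Starts each orbit at ``(p_bar + perturbation, z_bar)``, discards
    ``transient`` iterates, and reports the mean and maximum distance
    from the fixed point over the following ``n_steps``.  Divergence is
    recorded per row (``diverged`` flag) instead of aborting the scan.
    """
    at, _, _, _ = interior_equilibrium(params)
    if at is None:
        raise ValueError("no interior equilibrium for these parameters")
    rows = []
    for h in h_values:
        ph = params.with_h(float(h))
        s = State(at.p + perturbation, at.z)
        diverged = False
        for _ in range(transient):
            s = step(ph, s, check=False)
            if not (math.isfinite(s.p) and math.isfinite(s.z)):
                diverged = True
                break
        dsum = 0.0
        dmax = 0.0
        if not diverged:
            for _ in range(n_steps):
                s = step(ph, s, check=False)
                if not (math.isfinite(s.p) and math.isfinite(s.z)):
                    diverged = True
                    break
                d = math.hypot(s.p - at.p, s.z - at.z)
                dsum += d
                dmax = max(dmax, d)
        rows.append({
            "h": float(h),
            "mean_radius": dsum / n_steps if not diverged else math.inf,
            "max_radius": dmax if not diverged else math.inf,
            "diverged": diverged,
        })
    return rows
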