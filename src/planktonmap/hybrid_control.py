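"""Hybrid and modified (cubed-gain) hybrid control of the plankton map.

Both schemes blend one map iterate with the identity,

    x_{n+1} = c g(x_n) + (1 - c) x_n,

with effective gain ``c = S1`` for the classic hybrid method and
``c = L^3`` for the modified one (``S1, L`` in (0, 1]).  Fixed points are
untouched, and the controlled Jacobian is the exact segment
``J_c = c J + (1 - c) I``, so each eigenvalue moves along the straight
line ``mu = 1 + c (xi - 1)``.  For an unstable complex pair ``xi`` with
``|xi| > 1`` the largest stabilising effective gain has the closed form

    c* = 2 (1 - Re xi) / |xi - 1|^2,

the gain at which ``|mu| = 1`` again; the modified method's bound on
``L`` is the cube root of the same ``c*``, which is why its usable gain
interval is always the longer of the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .equilibria import interior_equilibrium
from .linear_stability import JacobianReport, map_jacobian
from .model_core import ModelParams, State, step

__all__ = [
    "ControlSpec",
    "ControlInterval",
    "controlled_step",
    "controlled_jacobian",
    "stability_interval",
    "comparison_table",
]

_METHODS = ("hybrid", "modified_hybrid")


@dataclass(frozen=True)
class ControlSpec:
    """Control method and gain; ``iterations`` (the iterate count) is fixed to 1."""

    method: str
    gain: float
    iterations: int = 1

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if not (0.0 < self.gain <= 1.0):
            raise ValueError(f"gain must lie in (0, 1], got {self.gain!r}")
        if self.iterations != 1:
            raise NotImplementedError("only the single-iterate scheme is implemented")

    @property
    def effective_gain(self) -> float:
        """Blend weight c applied to the map iterate (gain or gain^3)."""
        if self.method == "hybrid":
            return self.gain
        return self.gain**3


@dataclass(frozen=True)
class ControlInterval:
    """Stability interval (0, upper) of the control gain at one step size."""

    h: float
    method: str
    lower: float
    upper: float
    binding: str  # which Jury boundary limits the gain ("modulus" | "none")

    @property
    def length(self) -> float:
        return self.upper - self.lower


def controlled_step(params: ModelParams, spec: ControlSpec, s: State) -> State:
    """One iterate of the controlled map c*g(s) + (1-c)*s."""
    c = spec.effective_gain
    nxt = step(params, s)
    return State(c * nxt.p + (1.0 - c) * s.p,
                 c * nxt.z + (1.0 - c) * s.z)


def controlled_jacobian(params: ModelParams, spec: ControlSpec,
                        at: State) -> JacobianReport:
    """Jacobian of the controlled map: the exact identity c J + (1-c) I."""
    c = spec.effective_gain
    j = map_jacobian(params, at)
    return JacobianReport(
        j11=c * j.j11 + (1.0 - c),
        j12=c * j.j12,
        j21=c * j.j21,
        j22=c * j.j22 + (1.0 - c),
    )


def _critical_effective_gain(jac: JacobianReport) -> tuple[float, str]:
    """Supremum of c in (0, 1] keeping every mu = 1 + c(xi - 1) inside the unit circle."""
    xi1, xi2 = jac.eigenvalues
    if all(abs(xi) < 1.0 for xi in (xi1, xi2)):
        return 1.0, "none"
    sup = 1.0
    for xi in {xi1, xi2}:
        if abs(xi) < 1.0:
            continue
        if xi == 1.0:
            return 0.0, "modulus"  # eigenvalue pinned at +1: uncontrollable
        c_star = 2.0 * (1.0 - xi.real) / abs(xi - 1.0)**2
        if c_star <= 0.0:
            return 0.0, "modulus"
        sup = min(sup, c_star)
    return sup, "modulus" if sup < 1.0 else "none"


def stability_interval(params: ModelParams, h: float,
                       method: str = "hybrid") -> ControlInterval:
    """Largest gain interval (0, upper) stabilising the interior point at step h.

    Uses the closed-form critical effective gain from the eigenvalue
    segment; the modified method's bound is its cube root.  When the
    uncontrolled point is already stable the whole gain range (0, 1) works.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    point, _, _, _ = interior_equilibrium(params)
    if point is None:
        raise ValueError("no interior equilibrium for these parameters")
    jac = map_jacobian(params.with_h(h), point)
    c_sup, binding = _critical_effective_gain(jac)
    upper = min(c_sup, 1.0)
    if method == "modified_hybrid":
        upper = upper ** (1.0 / 3.0)
    return ControlInterval(h=float(h), method=method, lower=0.0,
                           upper=float(upper), binding=binding)


def comparison_table(params: ModelParams, h_list) -> list[dict[str, float | str | bool]]:
    """Per-h comparison of the two methods' gain intervals.

    Each row carries the modified interval I1, the classic interval I2,
    their lengths, and a flag marking rows where the modified method is
    *not* strictly longer.
    """
    rows = []
    for h in h_list:
        i1 = stability_interval(params, h, "modified_hybrid")
        i2 = stability_interval(params, h, "hybrid")
        rows.append({
            "h": float(h),
            "modified_upper": i1.upper,
            "hybrid_upper": i2.upper,
            "modified_length": i1.length,
            "hybrid_length": i2.length,
            "modified_not_longer": i1.length <= i2.length,
        })
    return rows
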