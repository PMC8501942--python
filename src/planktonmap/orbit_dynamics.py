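"""Orbit simulation, bifurcation sweeps and the maximum Lyapunov exponent."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .linear_stability import map_jacobian
from .model_core import ModelParams, State, step

__all__ = [
    "Orbit",
    "LyapunovEstimate",
    "SweepResult",
    "simulate",
    "max_lyapunov",
    "bifurcation_sweep",
]


@dataclass(frozen=True)
class Orbit:
    params: ModelParams
    initial: State
    states: np.ndarray       # (n_kept, 2) post-transient states
    transient: int
    truncated: bool = False  # overflow before the requested length


@dataclass(frozen=True)
class LyapunovEstimate:
    """Maximum Lyapunov exponent (nats per iteration) by tangent propagation."""

    value: float
    n_iterations: int
    transient: int
    renormalizations: int


@dataclass(frozen=True)
class SweepResult:
    h_grid: np.ndarray
    samples: list[np.ndarray]       # per-h post-transient state samples
    summaries: list[str]            # "fixed point" | "circle" | "irregular" | "diverged"
    radii: np.ndarray = field(default_factory=lambda: np.array([]))


def simulate(params: ModelParams, s0: State, n: int,
             transient: int = 0) -> Orbit:
    """Iterate the map n times from s0, keeping the post-transient states.

    Deterministic: identical inputs give bit-identical orbits.  Overflow
    truncates the orbit and sets the ``truncated`` flag instead of raising.
    """
    if not n > transient >= 0:
        raise ValueError("need n > transient >= 0")
    states = np.empty((n - transient, 2))
    s = s0
    truncated = False
    kept = 0
    for i in range(n):
        s = step(params, s, check=(i == 0))
        if not (math.isfinite(s.p) and math.isfinite(s.z)):
            truncated = True
            break
        if i >= transient:
            states[kept] = s
            kept += 1
    return Orbit(params=params, initial=s0, states=states[:kept],
                 transient=transient, truncated=truncated)


def max_lyapunov(params: ModelParams, s0: State, n: int = 100_000,
                 transient: int = 10_000,
                 step_fn=None, jacobian_fn=None) -> LyapunovEstimate:
    """Maximum Lyapunov exponent by single-tangent-vector propagation.

    A unit tangent vector is pushed forward by the analytic Jacobian
    along the orbit and renormalised every step; the estimate is the
    mean log stretch over the post-transient steps.  ``step_fn`` /
    ``jacobian_fn`` can replace the plankton map and its Jacobian by any
    ``State -> State`` / ``State -> 2x2 array`` pair, e.g. a linear test
    map with a known exponent.
    """
    if not n > transient >= 0:
        raise ValueError("need n > transient >= 0")
    if step_fn is None:
        step_fn = lambda s: step(params, s, check=False)
    if jacobian_fn is None:
        jacobian_fn = lambda s: map_jacobian(params, s).matrix
    s = s0
    for _ in range(transient):
        s = step_fn(s)
        if not (math.isfinite(s.p) and math.isfinite(s.z)):
            raise RuntimeError("orbit diverged during the transient")
    v = np.array([1.0, 0.0])
    log_sum = 0.0
    count = 0
    for _ in range(n - transient):
        v = jacobian_fn(s) @ v
        norm = math.hypot(v[0], v[1])
        if norm == 0.0 or not math.isfinite(norm):
            raise RuntimeError("tangent vector collapsed or diverged")
        log_sum += math.log(norm)
        v /= norm
        count += 1
        s = step_fn(s)
        if not (math.isfinite(s.p) and math.isfinite(s.z)):
            raise RuntimeError("orbit diverged")
    return LyapunovEstimate(value=log_sum / count, n_iterations=n,
                            transient=transient, renormalizations=count)


def bifurcation_sweep(
    params: ModelParams,
    h_min: float,
    h_max: float,
    n_h: int = 64,
    n: int = 12_000,
    transient: int = 10_000,
    s0: State | None = None,
    fixed_point_tol: float = 1e-6,
) -> SweepResult:
    """Post-transient attractor samples over a grid of step sizes.

    Each row simulates from the interior fixed point perturbed by +1e-4
    in p (unless ``s0`` is given) and summarises the attractor by the
    spread of post-transient radii around the fixed point: below
    ``fixed_point_tol`` -> "fixed point"; a thin annulus -> "circle";
    anything broader -> "irregular".
    """
    if not (0.0 < h_min < h_max <= 1.0):
        raise ValueError("need 0 < h_min < h_max <= 1")
    from .equilibria import interior_equilibrium

    point, _, _, _ = interior_equilibrium(params)
    if point is None:
        raise ValueError("no interior equilibrium for these parameters")
    start = s0 if s0 is not None else State(point.p + 1e-4, point.z)
    grid = np.linspace(h_min, h_max, n_h)
    samples: list[np.ndarray] = []
    summaries: list[str] = []
    radii = np.empty(n_h)
    for i, h in enumerate(grid):
        orbit = simulate(params.with_h(float(h)), start, n, transient)
        samples.append(orbit.states)
        if orbit.truncated or orbit.states.size == 0:
            summaries.append("diverged")
            radii[i] = math.inf
            continue
        d = np.hypot(orbit.states[:, 0] - point.p, orbit.states[:, 1] - point.z)
        radii[i] = float(d.mean())
        if d.max() <= fixed_point_tol:
            summaries.append("fixed point")
        elif d.min() > 0.2 * d.max():
            summaries.append("circle")
        else:
            summaries.append("irregular")
    return SweepResult(h_grid=grid, samples=samples, summaries=summaries,
                       radii=radii)
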