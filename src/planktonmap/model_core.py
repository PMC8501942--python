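"""Parameters and evaluation of the plankton map and its parent vector field.

The continuous model couples a logistically growing phytoplankton
population ``p`` and a grazing zooplankton population ``z`` through a
Holling type-II functional response ``p/(a+p)``, with cubic phytoplankton
self-toxicity (``m1 p^3``), quadratic zooplankton toxicity (``m2 z^2``),
toxin release (``rho``) and catch-per-unit-effort harvesting of both
populations (``q1 E``, ``q2 E``):

    dp/dt = r p (1 - p/k) - alpha p z/(a+p) - m1 p^3 - q1 E p
    dz/dt = beta p z/(a+p) - delta z - rho p z/(a+p) - m2 z^2 - q2 E z

The discrete map is a Mickens-type nonstandard finite-difference (NSFD)
discretisation of that system with step size ``h``.  Loss terms are
evaluated at the forward time level, which makes each update a ratio of
positive quantities:

    p'  =  (1 + h r) p  /  [1 + h (r p/k + alpha z/(a+p) + m1 p^2 + q1 E)]
    z'  =  (1 + h beta p/(a+p)) z  /
           [1 + h (rho p/(a+p) + delta + m2 z + q2 E)]

so non-negative states stay non-negative for every step size, and the
fixed points of the map coincide exactly with the equilibria of the ODE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParams",
    "State",
    "ValidationReport",
    "ParameterError",
    "DomainError",
    "validate",
    "step",
    "ode_rhs",
    "integrate_ode",
    "read_params",
    "write_params",
    "orbit_to_csv",
]

PARAM_KEYS = ("a", "r", "k", "alpha", "beta", "delta", "rho",
              "m1", "m2", "q1", "q2", "E", "h")


class ParameterError(ValueError):
    """Raised when parameters violate a hard model invariant."""


class DomainError(ValueError):
    """Raised when a state is outside the admissible domain."""


@dataclass(frozen=True)
class ModelParams:
    """The thirteen scalar parameters of the plankton map.

    a      half-saturation (partial capturing saturation) constant
    r      phytoplankton intrinsic growth rate
    k      environmental carrying capacity
    alpha  maximal grazing (takeover) rate of zooplankton
    beta   phytoplankton-to-zooplankton conversion rate
    delta  natural death rate of zooplankton
    rho    toxin-release rate of phytoplankton
    m1     phytoplankton toxicity coefficient
    m2     zooplankton toxicity coefficient
    q1     catchability of phytoplankton
    q2     catchability of zooplankton
    E      combined harvesting effort
    h      step size of the NSFD scheme
    """

    a: float
    r: float
    k: float
    alpha: float
    beta: float
    delta: float
    rho: float
    m1: float
    m2: float
    q1: float
    q2: float
    E: float
    h: float = 0.1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ParameterError(f"parameter {f.name} must be finite, got {v!r}")
            object.__setattr__(self, f.name, float(v))

    def with_h(self, h: float) -> "ModelParams":
        """Copy of the parameter set with a different step size."""
        return replace(self, h=float(h))

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class State(NamedTuple):
    """A (phytoplankton, zooplankton) density pair."""

    p: float
    z: float


@dataclass(frozen=True)
class ValidationReport:
    """Hard-invariant violations and soft advisory warnings for a parameter set."""

    hard_errors: tuple[str, ...]
    warnings: tuple[str, ...]

    @property
    def ok(self) -> bool:
        """True iff the full analysis tool-chain may run on these parameters."""
        return not self.hard_errors


def validate(params: ModelParams) -> ValidationReport:
    """Check hard invariants and modelling-assumption advisories.

    Hard errors: a negative parameter, ``h <= 0``, or ``beta <= rho``
    (net zooplankton gain from grazing must outpace toxin intake, or the
    model has no biologically meaningful interior state).  Advisories
    flag parameter sets outside the regime the existence theory assumes
    (``a > k``, ``beta < alpha``, ``0 < m2 < m1``); the map itself is
    still well defined there.
    """
    hard: list[str] = []
    warn: list[str] = []
    for key in PARAM_KEYS:
        if getattr(params, key) < 0.0:
            hard.append(f"{key} < 0")
    if params.h <= 0.0:
        hard.append("h <= 0")
    if params.beta <= params.rho:
        hard.append("beta <= rho (no net zooplankton growth from grazing)")
    if params.a <= params.k:
        warn.append("a <= k (half-saturation below carrying capacity)")
    if params.beta >= params.alpha:
        warn.append("beta >= alpha (conversion rate not below grazing rate)")
    if not (0.0 < params.m2 < params.m1):
        warn.append("toxicity coefficients outside 0 < m2 < m1")
    return ValidationReport(tuple(hard), tuple(warn))


def _require_valid(params: ModelParams) -> None:
    report = validate(params)
    if not report.ok:
        raise ParameterError("; ".join(report.hard_errors))


def _require_steppable(params: ModelParams) -> None:
    # Plain iteration is well defined even when beta <= rho (the map is a
    # ratio of positive quantities); only negativity and h <= 0 are fatal.
    bad = [key for key in PARAM_KEYS if getattr(params, key) < 0.0]
    if bad:
        raise ParameterError("negative parameter(s): " + ", ".join(bad))
    if params.h <= 0.0:
        raise ParameterError("h <= 0")


def _require_state(s: State) -> None:
    p, z = s
    if not (math.isfinite(p) and math.isfinite(z)):
        raise DomainError(f"state must be finite, got {s!r}")
    if p < 0.0 or z < 0.0:
        raise DomainError(f"state must be non-negative, got {s!r}")


def step(params: ModelParams, s: State, *, check: bool = True) -> State:
    """One iterate of the NSFD map.

    Both components are single rational expressions with denominators
    >= 1 for non-negative input, so positivity is preserved without any
    clipping.  Evaluated exactly in the form given in the module
    docstring (no algebraic rearrangement).
    """
    if check:
        _require_steppable(params)
        _require_state(s)
    a, r, k = params.a, params.r, params.k
    h = params.h
    p, z = s
    p_next = (1.0 + h * r) * p / (
        1.0 + h * (r / k * p + params.alpha * z / (a + p)
                   + params.m1 * p * p + params.q1 * params.E)
    )
    z_next = (1.0 + h * params.beta * p / (a + p)) * z / (
        1.0 + h * (params.rho * p / (a + p) + params.delta
                   + params.m2 * z + params.q2 * params.E)
    )
    return State(p_next, z_next)


def ode_rhs(params: ModelParams, s: State, *, check: bool = True) -> tuple[float, float]:
    """Right-hand side (dp/dt, dz/dt) of the continuous model."""
    if check:
        _require_steppable(params)
        _require_state(s)
    a = params.a
    p, z = s
    holling = p / (a + p)
    dp = (params.r * p * (1.0 - p / params.k)
          - params.alpha * holling * z
          - params.m1 * p ** 3
          - params.q1 * params.E * p)
    dz = (params.beta * holling * z
          - params.delta * z
          - params.rho * holling * z
          - params.m2 * z * z
          - params.q2 * params.E * z)
    return dp, dz


def integrate_ode(
    params: ModelParams,
    s0: State,
    t_end: float,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the ODE with an adaptive high-order method.

    Returns ``(t, y)`` with dense output sampled on the NSFD grid
    ``t_n = n h`` up to ``t_end`` (the endpoint is always included).
    Raises ``RuntimeError`` if the integrator fails (e.g. blow-up)
    rather than returning a silently truncated trajectory.
    """
    if tol <= 0.0:
        raise ValueError("tol must be positive")
    _require_steppable(params)
    _require_state(s0)
    if t_end == 0.0:
        return np.array([0.0]), np.array([[s0.p], [s0.z]])
    n_grid = int(math.floor(t_end / params.h + 1e-12))
    t_eval = np.unique(np.append(params.h * np.arange(n_grid + 1), t_end))
    sol = solve_ivp(
        lambda _t, y: ode_rhs(params, State(*y), check=False),
        (0.0, t_end),
        [s0.p, s0.z],
        method="DOP853",
        rtol=tol,
        atol=tol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.t, sol.y


# -- plain-text parameter configuration (key=value, one pair per line) --

def read_params(path: str | Path) -> ModelParams:
    """Read a ``key=value`` parameter file with the thirteen model keys."""
    values: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in PARAM_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        values[key] = float(value.strip())
    missing = [key for key in PARAM_KEYS if key not in values]
    if missing:
        raise ValueError(f"{path}: missing parameter(s): {', '.join(missing)}")
    return ModelParams(**values)


def write_params(params: ModelParams, path: str | Path) -> None:
    """Write a parameter set in the ``key=value`` config format."""
    lines = [f"{key}={getattr(params, key)!r}" for key in PARAM_KEYS]
    Path(path).write_text("\n".join(lines) + "\n")


def orbit_to_csv(states: Sequence[State], h: float, path: str | Path,
                 n0: int = 0) -> None:
    """Write a trajectory as CSV with header ``n,t,p,z``."""
    rows = ["n,t,p,z"]
    for i, (p, z) in enumerate(states):
        n = n0 + i
        rows.append(f"{n},{n * h!r},{p!r},{z!r}")
    Path(path).write_text("\n".join(rows) + "\n")
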