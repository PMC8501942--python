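"""Named benchmark parameter sets shipped with the package.

Three sets are provided:

* ``ns_bloom`` -- a strongly grazed, strongly toxic bloom regime.  It has
  a unique interior point near (0.1053, 6.888), a Neimark-Sacker
  crossing of the step size inside (0.40, 0.50), and is the set behind
  every worked quantity in the test suite.  Note it sits outside the
  advisory assumptions (beta > alpha here), which is harmless for the
  computations but is flagged by :func:`planktonmap.model_core.validate`.
* ``consistency_stable`` / ``consistency_unstable`` -- a mild-toxicity
  regime (a < k) used to compare the discrete map against its continuous
  parent; the two differ only in the phytoplankton toxicity coefficient
  m1 (0.06 vs 0.025).  The source listing for these sets names a
  harvesting-effort-like constant ``c = 0.14`` that matches no other
  symbol; it is read as the effort E here, and the reported interior
  point of that listing does not satisfy the fixed-point equations, so
  these fixtures carry a note and are excluded from numeric benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model_core import ModelParams, State

__all__ = ["Fixture", "load_fixture", "fixture_names"]


@dataclass(frozen=True)
class Fixture:
    name: str
    params: ModelParams
    initial: State | None
    notes: str


_BLOOM = dict(a=2.0099, q1=0.0189, q2=1.2994, r=10.5923, E=0.9959,
              k=1.3997, beta=98.499, alpha=2.9999, delta=0.0384,
              rho=10.5842, m1=0.6222, m2=0.4422)

_MILD = dict(a=2.1, q1=0.09, q2=0.3, r=1.5, k=100.0, beta=0.5,
             alpha=0.69, delta=0.001, rho=0.1, m2=0.021, E=0.14)

_FIXTURES: dict[str, Fixture] = {
    "ns_bloom": Fixture(
        name="ns_bloom",
        params=ModelParams(**_BLOOM, h=0.3),
        initial=State(0.105348, 6.8884251),
        notes=("Benchmark bloom regime; interior point near "
               "(0.1053484433, 6.88842511); Neimark-Sacker crossing of h "
               "in (0.40, 0.50). beta > alpha (advisory only)."),
    ),
    "consistency_stable": Fixture(
        name="consistency_stable",
        params=ModelParams(**_MILD, m1=0.06, h=0.0399909),
        initial=State(2.3059, 7.38854),
        notes=("Mild-toxicity regime, stable side (m1 = 0.06). 'c = 0.14' "
               "in the source listing read as the effort E. The listed "
               "interior point does not satisfy the fixed-point equations; "
               "excluded from numeric benchmarks."),
    ),
    "consistency_unstable": Fixture(
        name="consistency_unstable",
        params=ModelParams(**_MILD, m1=0.025, h=0.0399909),
        initial=State(2.8059, 8.8854),
        notes=("Mild-toxicity regime, unstable side (m1 = 0.025). Same "
               "caveats as consistency_stable."),
    ),
}


def fixture_names() -> tuple[str, ...]:
    return tuple(_FIXTURES)


def load_fixture(name: str) -> Fixture:
    """Look up a benchmark parameter set by name."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(_FIXTURES)}"
        ) from None
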