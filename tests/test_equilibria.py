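"""Trapping box, fixed points and existence/uniqueness diagnostics."""

import math
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from planktonmap import (
    ModelParams,
    State,
    axial_equilibrium,
    bounding_box,
    equilibrium_set,
    eval_F,
    eval_f,
    existence_report,
    interior_equilibrium,
    simulate,
    step,
)
from planktonmap.equilibria import worked_bounds_report
from planktonmap.model_core import ParameterError


def test_bounding_box_values(bloom):
    box = bounding_box(bloom)
    assert box.p_max == pytest.approx(1.3997, abs=0.0)
    assert box.z_max == pytest.approx(81.61590194902372, rel=1e-13)


def test_bounding_box_degenerate_when_no_margin(bloom):
    with pytest.raises(ParameterError):
        bounding_box(replace(bloom, rho=bloom.beta))


def test_axial_equilibrium_reference_value(bloom):
    point, exists = axial_equilibrium(bloom)
    assert exists
    assert point.z == 0.0
    assert point.p == pytest.approx(1.26553, rel=5e-6)  # 6 significant digits


def test_axial_collapses_when_growth_equals_harvest(bloom):
    params = replace(bloom, r=bloom.q1 * bloom.E)
    point, exists = axial_equilibrium(params)
    assert not exists  # r > q1 E fails (boundary)
    params = replace(bloom, r=bloom.q1 * bloom.E * 1.0000001)
    point, exists = axial_equilibrium(params)
    assert exists and point.p < 1e-4


@settings(deadline=None, max_examples=150)
@given(r=st.floats(0.5, 20.0), k=st.floats(0.5, 10.0),
       m1=st.floats(0.01, 2.0), q1=st.floats(0.0, 1.0), E=st.floats(0.0, 1.0))
def test_axial_root_satisfies_quadratic(r, k, m1, q1, E):
    """The closed form solves m1 x^2 + (r/k) x - (r - q1 E) = 0."""
    params = ModelParams(a=2.0, r=r, k=k, alpha=1.0, beta=2.0, delta=0.1,
                         rho=0.5, m1=m1, m2=0.1, q1=q1, q2=0.1, E=E, h=0.1)
    point, exists = axial_equilibrium(params)
    if not exists:
        return
    x = point.p
    resid = m1 * x * x + (r / k) * x - (r - q1 * E)
    assert abs(resid) < 1e-10 * max(1.0, r)


def test_nullcline_values(bloom):
    assert eval_f(bloom, 0.0) == pytest.approx(7.084113606170539, rel=1e-13)
    assert eval_F(bloom, 0.0) == pytest.approx(0.10754185654404144, rel=1e-12)
    # direct arithmetic of the nullcline at p = k (second factor at p = k)
    assert eval_f(bloom, bloom.k) == pytest.approx(-1.406861400582013, rel=1e-12)


def test_interior_point_reference_digits(bloom, bloom_interior):
    assert bloom_interior.p == pytest.approx(0.1053484433, rel=1e-9)
    assert bloom_interior.z == pytest.approx(6.88842511, rel=1e-8)
    _, residuals, unique, _ = interior_equilibrium(bloom)
    assert unique
    assert max(residuals) < 1e-9


def test_interior_point_matches_fixed_point_iteration_oracle(bloom, bloom_interior):
    """Independent route: iterate p -> a m/(m - (delta + m2 f(p) + q2 E)) - a."""
    m = bloom.beta - bloom.rho
    p = 0.05
    for _ in range(500):
        s = bloom.delta + bloom.m2 * eval_f(bloom, p) + bloom.q2 * bloom.E
        p_new = bloom.a * m / (m - s) - bloom.a
        if abs(p_new - p) < 1e-15:
            break
        p = p_new
    assert p == pytest.approx(bloom_interior.p, abs=1e-9)


def test_interior_point_inside_box(bloom, bloom_interior):
    box = bounding_box(bloom)
    assert box.contains(bloom_interior)


def test_existence_report_verdicts(bloom):
    rep = existence_report(bloom)
    assert rep.verdict == "unique"
    assert rep.F0_sign > 0 and rep.Fk_sign < 0
    assert rep.r_gt_q1E
    # margin destroyed everywhere -> no interior point
    rep = existence_report(replace(bloom, delta=bloom.beta))
    assert rep.verdict == "none"
    # growth below harvest -> no interior point
    rep = existence_report(replace(bloom, r=0.5 * bloom.q1 * bloom.E))
    assert not rep.r_gt_q1E and rep.verdict == "none"


def test_worked_bounds_report_reference_values(bloom):
    rep = worked_bounds_report(bloom)
    assert rep.f0 == pytest.approx(7.084113606170539, rel=1e-13)
    assert rep.s0 == pytest.approx(4.465067496648613, rel=1e-12)
    assert rep.F0 == pytest.approx(0.10754185654404144, rel=1e-12)
    assert rep.f_upper == pytest.approx(-79.36413532682512, rel=1e-12)
    assert rep.fprime_k == pytest.approx(-10.993342080620321, rel=1e-12)
    assert rep.Fprime_upper == pytest.approx(-1.0580185510185083, rel=1e-12)


def test_trapping_box_forward_invariance(bloom):
    """Long orbits started inside the box never leave it."""
    box = bounding_box(bloom)
    for h, s0 in [(0.3, State(0.105348, 6.8884251)),
                  (0.7, State(1.0, 50.0))]:
        orbit = simulate(bloom.with_h(h), s0, 100_000, transient=0)
        assert not orbit.truncated
        assert orbit.states[:, 0].max() <= box.p_max + 1e-12
        assert orbit.states[:, 1].max() <= box.z_max + 1e-12
        assert orbit.states.min() >= 0.0


def test_interior_approaches_axial_as_zooplankton_toxicity_grows(bloom):
    """Along an m2 path the coexistence point slides onto the axial one."""
    ax, _ = axial_equilibrium(bloom)
    gaps, zs = [], []
    for m2 in [0.4422, 10.0, 100.0, 1000.0]:
        point, _, _, _ = interior_equilibrium(replace(bloom, m2=m2))
        gaps.append(ax.p - point.p)
        zs.append(point.z)
    assert all(g > 0 for g in gaps)
    assert gaps == sorted(gaps, reverse=True)
    assert zs == sorted(zs, reverse=True)
    assert zs[-1] < 0.05 and gaps[-1] < 0.005


def test_equilibrium_set_bundles_everything(bloom):
    eqs = equilibrium_set(bloom)
    assert eqs.trivial == (0.0, 0.0)
    assert eqs.axial_exists and eqs.interior_exists and eqs.unique
    nxt = step(bloom, eqs.interior)
    assert math.hypot(nxt.p - eqs.interior.p, nxt.z - eqs.interior.z) < 1e-9
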