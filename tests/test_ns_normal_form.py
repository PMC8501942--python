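"""Taylor table, canonical rotation form and the first Lyapunov quantity."""

import math

import numpy as np
import pytest

from planktonmap import (
    canonical_transform,
    circle_radius_scan,
    critical_step,
    lyapunov_coefficient,
    map_jacobian,
    taylor_coefficients,
)
from planktonmap.ns_normal_form import taylor_coefficients_fd


def test_linear_slots_equal_jacobian(bloom, bloom_interior, bloom_hstar):
    v = taylor_coefficients(bloom, bloom_hstar.h_star, bloom_interior)
    jac = map_jacobian(bloom.with_h(bloom_hstar.h_star), bloom_interior)
    assert v["v11"] == pytest.approx(jac.j11, rel=1e-10)
    assert v["v12"] == pytest.approx(jac.j12, rel=1e-10)
    assert v["v21"] == pytest.approx(jac.j21, rel=1e-10)
    assert v["v22"] == pytest.approx(jac.j22, rel=1e-10)


def test_quadratic_z_slot_matches_closed_form(bloom, bloom_interior, bloom_hstar):
    """v15 = h^2 p (1+hr) alpha^2 / ((a+p)^2 (1+x1)^3), by direct arithmetic."""
    h = bloom_hstar.h_star
    p, z = bloom_interior
    a, r, al = bloom.a, bloom.r, bloom.alpha
    x1 = h * (p * r / bloom.k + z * al / (a + p) + p * p * bloom.m1
              + bloom.q1 * bloom.E)
    closed = h * h * p * (1 + h * r) * al * al / ((a + p) ** 2 * (1 + x1) ** 3)
    v = taylor_coefficients(bloom, h, bloom_interior)
    assert v["v15"] == pytest.approx(closed, rel=1e-12)


def test_symbolic_and_numeric_tables_agree(bloom, bloom_interior, bloom_hstar):
    v_sym = taylor_coefficients(bloom, bloom_hstar.h_star, bloom_interior)
    v_fd = taylor_coefficients_fd(bloom, bloom_hstar.h_star, bloom_interior)
    for key, sym in v_sym.items():
        assert v_fd[key] == pytest.approx(sym, rel=1e-5, abs=1e-8), key


def test_constructed_quadratic_map_recovered_exactly():
    """FD machinery on a hand-built polynomial map with known coefficients."""
    want = {"v11": 0.3, "v12": -0.1, "v13": 0.5, "v14": -0.25, "v15": 0.125,
            "v16": 0.0625, "v17": -0.3, "v18": 0.2, "v19": -0.05,
            "v21": 0.7, "v22": 0.4, "v23": -0.5, "v24": 0.35, "v25": -0.15,
            "v26": 0.1, "v27": 0.05, "v28": -0.02, "v29": 0.01}

    def poly_map(p, z):
        c = want
        f = (c["v11"] * p + c["v12"] * z + c["v13"] * p**2 + c["v14"] * p * z
             + c["v15"] * z**2 + c["v16"] * p**3 + c["v17"] * p**2 * z
             + c["v18"] * p * z**2 + c["v19"] * z**3)
        g = (c["v21"] * p + c["v22"] * z + c["v23"] * p**2 + c["v24"] * p * z
             + c["v25"] * z**2 + c["v26"] * p**3 + c["v27"] * p**2 * z
             + c["v28"] * p * z**2 + c["v29"] * z**3)
        return f, g

    from planktonmap.model_core import State

    got = taylor_coefficients_fd(None, at=State(0.0, 0.0), map_fn=poly_map)
    for key, val in want.items():
        assert got[key] == pytest.approx(val, rel=1e-7, abs=1e-9), key


def test_canonical_transform_three_four_five():
    cf = canonical_transform(1.6, 1.0)
    assert cf.ell == pytest.approx(0.8) and cf.wp == pytest.approx(0.6)


def test_canonical_transform_inverse_and_boundary():
    rng = np.random.default_rng(3)
    for _ in range(20):
        dt = rng.uniform(0.5, 2.0)
        tr = rng.uniform(-1, 1) * 2.0 * math.sqrt(dt) * 0.95
        v11, v12 = rng.uniform(-1, 1), rng.uniform(0.1, 1.0)
        cf = canonical_transform(tr, dt, v11, v12)
        assert np.allclose(cf.T @ cf.T_inv, np.eye(2), atol=1e-12)
    with pytest.raises(ValueError):
        canonical_transform(2.0, 1.0)  # Tr^2 = 4 Dt


def test_rotation_form_of_transformed_linear_part(bloom, bloom_interior, bloom_hstar):
    """T^-1 J T equals [[l, -w], [w, l]] at criticality."""
    jac = map_jacobian(bloom.with_h(bloom_hstar.h_star), bloom_interior)
    cf = canonical_transform(jac.trace, jac.det, jac.j11, jac.j12)
    rot = cf.T_inv @ jac.matrix @ cf.T
    expect = np.array([[cf.ell, -cf.wp], [cf.wp, cf.ell]])
    assert np.allclose(rot, expect, atol=1e-8)


def test_lyapunov_coefficient_supercritical(bloom, bloom_hstar):
    nf = lyapunov_coefficient(bloom, bloom_hstar.h_star)
    assert nf.omega < 0.0
    assert nf.verdict == "supercritical"
    assert nf.omega_uncertainty < 0.1 * abs(nf.omega)
    assert nf.ell**2 + nf.wp**2 == pytest.approx(1.0, abs=1e-8)
    assert nf.d_modulus_dh > 0.0
    assert math.isfinite(nf.omega)


def test_invariant_circle_radius_scaling(bloom, bloom_hstar):
    """Mean radius grows ~ sqrt(h - h*) past a supercritical crossing."""
    h_star = bloom_hstar.h_star
    offsets = [0.01, 0.02, 0.04]
    rows = circle_radius_scan(bloom, [h_star - 0.05] + [h_star + d for d in offsets])
    assert rows[0]["mean_radius"] <= 1e-6  # stable focus below criticality
    radii = [row["mean_radius"] for row in rows[1:]]
    assert radii == sorted(radii)  # monotone growth just past h*
    slope = np.polyfit(np.log(offsets), np.log(radii), 1)[0]
    assert 0.35 <= slope <= 0.65


def test_omega_sign_matches_orbit_behaviour_on_jittered_sets(bloom):
    """The analytic verdict agrees with simulated orbits on nearby regimes."""
    rng = np.random.default_rng(11)
    checked = 0
    while checked < 3:
        factors = rng.uniform(0.97, 1.03, 12)
        d = bloom.as_dict()
        for key, fac in zip(("a", "r", "k", "alpha", "beta", "delta", "rho",
                             "m1", "m2", "q1", "q2", "E"), factors):
            d[key] = d[key] * fac
        from planktonmap import ModelParams
        from planktonmap.linear_stability import NoCrossingError

        params = ModelParams(**d)
        try:
            cs = critical_step(params)
            nf = lyapunov_coefficient(params, cs.h_star)
        except (NoCrossingError, ValueError):
            continue
        rows = circle_radius_scan(params, [cs.h_star + 0.02],
                                  n_steps=4000, transient=6000)
        bounded_circle = (not rows[0]["diverged"]
                          and 1e-5 < rows[0]["mean_radius"] < 50.0)
        if nf.verdict == "supercritical":
            assert bounded_circle
        checked += 1
    assert checked == 3
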