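"""Coupled macroscale solver: exact states, interface physics, stability."""

import math

import numpy as np
import pytest
from dataclasses import replace

from lnflow.params import (derive_exchange_coefficients, EffectiveTransport)
from lnflow.macro import (solve_coupled, solve_lc_only, SolverConfig,
                          assemble_interface_terms)
from lnflow.post import mass_balance
from lnflow.verify import sphere_oracle, manufactured_stokes_check


def test_interface_robin_coefficient():
    c, no_slip = assemble_interface_terms(1.0, 3.65e-9, mu=1.0)
    assert c == pytest.approx(1.0 / math.sqrt(3.65e-9), rel=1e-12)
    assert c == pytest.approx(1.655e4, rel=1e-3)
    assert not no_slip
    # free-slip limit: infinite permeability kills the penalty
    c_free, _ = assemble_interface_terms(1.0, 1e12)
    assert c_free < 1e-5
    with pytest.raises(ValueError):
        assemble_interface_terms(-1.0, 3.65e-9)


def test_exact_rest_state(blocks, transport, sphere_mesh_coarse, sphere_geom):
    """v_in = 0 with p_v_bar = p_out + sigma*delta_pi is an exact
    equilibrium: the Starling bracket vanishes identically and all fields
    are constants; the discrete solver reproduces it to solver tolerance."""
    fluid, _, ex0, bc = blocks
    sdp = ex0.sigma * ex0.delta_pi
    ex = derive_exchange_coefficients(replace(ex0, p_v_bar=bc.p_out + sdp),
                                      sphere_geom.lc_volume())
    sol = solve_coupled(sphere_mesh_coarse, fluid, ex, transport,
                        replace(bc, v_in=0.0))
    assert np.abs(sol.u).max() < 1e-8
    assert np.abs(sol.p_f - bc.p_out).max() < 1e-3
    assert np.abs(sol.p_m - bc.p_out).max() < 1e-2
    assert np.abs(sol.p_v - ex.p_v_bar).max() < 1e-5
    fr = mass_balance(sol)
    assert abs(fr.Q_in) < 1e-10 and abs(fr.Q_lc_to_blood) < 1e-10


def test_affine_superposition(blocks, transport, sphere_mesh_coarse,
                              sphere_geom):
    """The discrete system is affine in (v_in, p_out, p_v_bar, sigma*dpi)."""
    fluid, _, ex0, bc0 = blocks

    def solve(v_in, p_out, pv, dpi):
        ex = derive_exchange_coefficients(
            replace(ex0, p_v_bar=pv, delta_pi=dpi), sphere_geom.lc_volume())
        return solve_coupled(sphere_mesh_coarse, fluid, ex, transport,
                             replace(bc0, v_in=v_in, p_out=p_out))

    th1 = (0.22, 6.18e5, 1.06e6, 1.02e6)
    th2 = (0.40, 4.00e5, 1.30e6, 0.80e6)
    thm = tuple(0.5 * (a + b) for a, b in zip(th1, th2))
    s1, s2, sm = solve(*th1), solve(*th2), solve(*thm)
    for name in ("u", "p_f", "p_m", "p_v"):
        mix = 0.5 * (getattr(s1, name) + getattr(s2, name))
        ref = getattr(sm, name)
        err = np.linalg.norm(mix - ref) / np.linalg.norm(ref)
        assert err < 1e-8, name


def test_mass_balance_residual(coarse_solution):
    fr = mass_balance(coarse_solution)
    assert abs(fr.residual) < 5e-3 * fr.Q_in
    # steady state: LC stores no fluid
    assert fr.Q_scs_to_lc == pytest.approx(fr.Q_lc_to_blood, rel=1e-2)


def test_velocity_scale_separation(coarse_solution, transport):
    """Interstitial speeds are orders of magnitude below the SCS speeds."""
    sol = coarse_solution
    sl = sol.space_lc
    G = sl.phys_grads()
    gp = np.einsum("tqid,ti->tqd", G, sol.p_m[sl.lconn])
    u_m_max = transport.Kbar_m * np.linalg.norm(gp, axis=-1).max()
    u_f_max = np.abs(sol.u).max()
    assert u_m_max < 1e-2 * u_f_max
    assert u_m_max < 6e-4            # literature range upper bound


def test_pressure_bounds(coarse_solution):
    """p_m stays between its interface trace and the Starling equilibrium
    pressure p_v_bar - sigma*delta_pi (discrete maximum principle)."""
    sol = coarse_solution
    ex = sol.exchange
    iface = np.unique(sol.mesh.facet_p2("interface"))
    trace = sol.p_m[sol.space_lc.g2l[iface]]
    p_eq = ex.p_v_bar - ex.sigma * ex.delta_pi
    lo = min(trace.min(), p_eq) - 1.0
    hi = max(trace.max(), p_eq) + 1.0
    assert sol.p_m.min() >= lo and sol.p_m.max() <= hi


def test_alpha_M_weak_influence(blocks, transport, sphere_mesh_coarse,
                                sphere_exchange):
    """Finite vs infinite BJS slip barely changes the pressure fields."""
    fluid, _, _, bc = blocks
    s_inf = solve_coupled(sphere_mesh_coarse, fluid, sphere_exchange,
                          transport, bc, SolverConfig(alpha_M=math.inf))
    s_one = solve_coupled(sphere_mesh_coarse, fluid, sphere_exchange,
                          transport, bc, SolverConfig(alpha_M=1.0))
    sl = s_inf.space_lc
    num = math.sqrt(sl.integrate((s_inf.p_m - s_one.p_m) ** 2))
    den = math.sqrt(sl.integrate(s_inf.p_m ** 2))
    assert num / den < 0.05


def test_lc_block_against_sphere_oracle(blocks, transport,
                                        sphere_mesh_coarse, sphere_exchange,
                                        sphere_geom):
    """LC-only solve with uniform Dirichlet data vs the closed form."""
    _, _, _, bc = blocks
    lc = solve_lc_only(sphere_mesh_coarse, sphere_exchange, transport,
                       P_b=bc.p_out)
    orc = sphere_oracle(sphere_exchange, transport, bc.p_out,
                        sphere_geom.R - sphere_geom.h)
    r = np.linalg.norm(lc.space_lc.coords, axis=1)
    for fem, exact in ((lc.p_m, orc.p_m(r)), (lc.p_v, orc.p_v(r))):
        err = math.sqrt(lc.space_lc.integrate((fem - exact) ** 2)
                        / lc.space_lc.integrate(exact ** 2))
        assert err < 1e-2
    q_fem = 2 * math.pi * sphere_exchange.C_m * lc.space_lc.integrate(
        lc.p_m - lc.p_v + sphere_exchange.sigma * sphere_exchange.delta_pi)
    assert q_fem == pytest.approx(orc.net_exchange(sphere_exchange.C_m),
                                  rel=1e-2)


def test_stokes_block_convergence_rates():
    """Manufactured axisymmetric solution: Taylor-Hood rates 3 (u), 2 (p)."""
    res = manufactured_stokes_check((4, 8, 16))
    assert res["rate_u"] > 0.8 * 3.0
    assert res["rate_p"] > 0.8 * 2.0
    # rest field sanity: errors decrease monotonically
    assert res["err_u"][2] < res["err_u"][1] < res["err_u"][0]


def test_missing_exchange_coefficients_rejected(blocks, transport,
                                                sphere_mesh_coarse):
    fluid, _, ex0, bc = blocks
    with pytest.raises(ValueError, match="not derived"):
        solve_coupled(sphere_mesh_coarse, fluid, ex0, transport, bc)
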