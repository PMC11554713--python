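"""The closed-form sphere oracle and the lumped Starling balance."""

import math

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from lnflow.params import (default_params, derive_exchange_coefficients,
                           EffectiveTransport)
from lnflow.verify import sphere_oracle, lumped_balance


@pytest.fixture(scope="module")
def derived_exchange():
    _, _, ex, _ = default_params()
    return derive_exchange_coefficients(ex, 4 / 3 * math.pi * 0.48**3)


def test_decoupled_limit(derived_exchange):
    ex = replace(derived_exchange, C_m=0.0, C_v=0.0)
    orc = sphere_oracle(ex, EffectiveTransport(), P_b=6.18e5, R=0.48)
    r = np.linspace(0.0, 0.48, 20)
    assert np.allclose(orc.p_m(r), 6.18e5)
    assert np.allclose(orc.p_v(r), ex.p_v_bar)
    assert orc.net_exchange(0.0) == 0.0


def test_equilibrium_boundary_data(derived_exchange):
    """P_b = p_v_bar - sigma*delta_pi makes the bracket vanish identically."""
    ex = derived_exchange
    Pb = ex.p_v_bar - ex.sigma * ex.delta_pi
    orc = sphere_oracle(ex, EffectiveTransport(), P_b=Pb, R=0.48)
    r = np.linspace(0.0, 0.48, 20)
    assert np.allclose(orc.bracket(r), 0.0, atol=1e-6)
    assert np.allclose(orc.p_m(r), Pb, atol=1e-6)
    assert abs(orc.net_exchange(ex.C_m)) < 1e-18


def test_strong_form_residual(derived_exchange):
    """The oracle satisfies both radial Darcy equations to round-off.

    Radial Laplacian (1/r^2) d/dr(r^2 dp/dr) is evaluated by central
    differences with Richardson extrapolation at random interior radii.
    """
    ex = derived_exchange
    tr = EffectiveTransport()
    orc = sphere_oracle(ex, tr, P_b=6.18e5, R=0.48)

    def lap(f, r, h=1e-4):
        return (f(r + h) - 2.0 * f(r) + f(r - h)) / h**2 \
            + (f(r + h) - f(r - h)) / (h * r)

    rng = np.linspace(0.05, 0.45, 9)
    B = orc.bracket(rng)
    res_m = tr.Kbar_m * lap(orc.p_m, rng) - ex.C_m * B
    res_v = tr.Kbar_v * lap(orc.p_v, rng) + ex.C_v * B
    scale_m = abs(ex.C_m * B).max()
    scale_v = abs(ex.C_v * B).max()
    assert np.abs(res_m).max() < 1e-5 * scale_m
    assert np.abs(res_v).max() < 1e-5 * scale_v


def test_bracket_is_modified_helmholtz_mode(derived_exchange):
    """B(r) = A sinh(lambda r)/r with lambda^2 = C_m/K_m + C_v/K_v."""
    ex = derived_exchange
    tr = EffectiveTransport()
    orc = sphere_oracle(ex, tr, P_b=6.0e5, R=0.48)
    lam_sq = ex.C_m / tr.Kbar_m + ex.C_v / tr.Kbar_v
    assert orc.lam**2 == pytest.approx(lam_sq, rel=1e-12)
    r = np.array([0.1, 0.2, 0.4])
    expect = orc.A * np.sinh(orc.lam * r) / r
    assert np.allclose(orc.bracket(r), expect, rtol=1e-12)
    # boundary value honoured
    assert orc.bracket(np.array([0.48]))[0] == pytest.approx(
        6.0e5 - ex.p_v_bar + ex.sigma * ex.delta_pi, rel=1e-12)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(pm=st.floats(4e5, 9e5))
def test_lumped_balance_affine(derived_exchange, pm):
    """The lumped flux is affine in the mean pressure with slope L_p S_tot."""
    ex = derived_exchange
    q0 = lumped_balance(ex, pm)
    q1 = lumped_balance(ex, pm + 1e4)
    slope = (q1 - q0) / 1e4
    assert slope == pytest.approx(ex.L_p * ex.S_tot, rel=1e-9)
    # equilibrium mean pressure gives zero flux
    assert lumped_balance(ex, ex.p_v_bar - ex.sigma * ex.delta_pi) == \
        pytest.approx(0.0, abs=1e-18)


def test_lumped_magnitude_matches_physiology(derived_exchange):
    """At the default working point the drainage is a few 1e-4 mm^3/s."""
    q = lumped_balance(derived_exchange, 6.2e5)
    # L_p*S_tot = 7.3365e-10 mm^3/(s mPa) times a bracket of ~4.78e5 mPa
    assert q == pytest.approx(7.3365e-10 * 4.78e5, rel=0.05)
    assert 3e-4 < q < 4e-4
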