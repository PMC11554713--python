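"""Parameter defaults, derived exchange coefficients, config round-trips."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from lnflow.params import (default_params, default_parameter_set,
                           derive_exchange_coefficients, load_config,
                           save_config, ExchangeParams, FluidParams)
from lnflow.params import InvalidGeometryError
from dataclasses import replace


def test_table_defaults():
    fluid, micro, ex, bc = default_params()
    assert fluid.mu == 1.0
    assert fluid.mu_star == pytest.approx(1.0 / fluid.phi)
    assert micro.K_m_nd == pytest.approx(3.84e-9 / 0.02**2)   # 9.6e-6
    assert micro.rbar == pytest.approx(0.085)
    assert micro.epsilon == pytest.approx(0.02)
    assert ex.sigma == 0.9
    assert ex.delta_pi == 1.02e6
    assert ex.L_p == 5.475e-11
    assert bc.v_in == 0.22
    assert bc.p_out == 6.18e5
    assert math.isinf(bc.alpha_M)


def test_exchange_coefficients_partitioned_convention():
    """With |Omega_m| = V_LC - V_v the sphere values match direct arithmetic."""
    _, _, ex, _ = default_params()
    ex = replace(ex, interstitial_volume="lc_minus_vascular")
    v_lc = 4.0 / 3.0 * math.pi * 0.48**3
    out = derive_exchange_coefficients(ex, v_lc)
    assert out.V_m_tot == pytest.approx(v_lc - 0.0322)
    assert out.C_m == pytest.approx(1.702e-9, rel=1e-3)
    assert out.C_v == pytest.approx(5.475e-11 * 13.4 / 0.0322, rel=1e-12)
    assert out.C_v == pytest.approx(2.278e-8, rel=1e-3)
    assert out.C_m < out.C_v


def test_exchange_wall_conductance_shared():
    """C_m V_m = C_v V_v = L_p S_tot: both phases see one wall conductance."""
    _, _, ex, _ = default_params()
    out = derive_exchange_coefficients(ex, 0.4632)
    assert out.C_m * out.V_m_tot == pytest.approx(ex.L_p * ex.S_tot, rel=1e-12)
    assert out.C_v * out.V_v_tot == pytest.approx(ex.L_p * ex.S_tot, rel=1e-12)


def test_zero_permeability_wall():
    _, _, ex, _ = default_params()
    out = derive_exchange_coefficients(replace(ex, L_p=0.0), 0.4632)
    assert out.C_m == 0.0 and out.C_v == 0.0


def test_invalid_geometry_rejected():
    _, _, ex, _ = default_params()
    ex = replace(ex, interstitial_volume="lc_minus_vascular")
    with pytest.raises(InvalidGeometryError):
        derive_exchange_coefficients(ex, 0.01)   # smaller than V_v_tot


def test_validation_errors():
    with pytest.raises(ValueError):
        FluidParams(mu=-1.0)
    with pytest.raises(ValueError):
        ExchangeParams(sigma=1.5)


def test_unit_consistency():
    """mu*v_in/h is a pressure scale: finite and positive in mPa."""
    fluid, _, _, bc = default_params()
    p_scale = fluid.mu * bc.v_in / 0.01
    assert p_scale > 0 and math.isfinite(p_scale)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(lp=st.floats(1e-12, 1e-8), sigma=st.floats(0.5, 1.0),
       vin=st.floats(0.0, 1.0))
def test_config_round_trip(tmp_path_factory, lp, sigma, vin):
    """Saving and reloading a parameter set reproduces every field exactly."""
    ps = default_parameter_set()
    ps.exchange.L_p = lp
    ps.exchange.sigma = sigma
    ps.bc.v_in = vin
    path = tmp_path_factory.mktemp("cfg") / "c.yaml"
    save_config(ps, path)
    ps2 = load_config(path)
    assert ps2.exchange.L_p == lp
    assert ps2.exchange.sigma == sigma
    assert ps2.bc.v_in == vin
    assert math.isinf(ps2.bc.alpha_M)
    assert ps2.geometry.shape == ps.geometry.shape


def test_config_unknown_keys_rejected(tmp_path):
    p = tmp_path / "bad.yaml"
    p.write_text("fluid.mu: 1.0\nnot.a.key: 2\n")
    with pytest.raises(ValueError, match="not.a.key"):
        load_config(p)
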