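"""Physiological parameters and the unit system of the lymph-node flow model.

Single source of truth for defaults and for every derived scalar coefficient
used by the macroscale solver.  The unit system is millimetre / second /
milligram / millipascal throughout, so 1 mg mm^-1 s^-2 = 1 mPa and every
literature value enters without conversion.

Parameter provenance (all defaults are the documented physiological values):

=============  ==========================  =====================================
symbol         default                     meaning
=============  ==========================  =====================================
mu             1 mg mm^-1 s^-1             lymph dynamic viscosity (water-like)
phi            0.75                        porosity of the FRC conduit network
mu_star        1/phi                       effective-to-fluid viscosity ratio
K_hat_m        3.84e-9 mm^2                interstitial permeability
r_c, d         1.7e-3, 2e-2 mm             vascularized-cylinder radius/spacing
K_v d^2/mu     1.1e-6 mm^3 s/mg            vascular conductivity (Kozeny-Carman)
sigma          0.9                         Staverman reflection coefficient
delta_pi       1.02e6 mPa                  oncotic pressure difference pi_v-pi_m
L_p            5.475e-11 mm s^-1 mPa^-1    vessel-wall hydraulic conductivity
p_v_bar        1.06e6 mPa                  mean blood-vessel pressure
S_tot          13.4 mm^2                   total vessel surface in the node
V_v_tot        0.0322 mm^3                 total vascular volume
v_in           0.22 mm/s                   afferent (inlet) lymph speed
p_out          6.18e5 mPa                  efferent (outlet) pressure
=============  ==========================  =====================================

Several parameters are published as physiological ranges (sigma 0.88-0.9,
delta_pi 3.41e5-2.08e6, L_p 5.475e-12-3.67e-8, p_v_bar 6.67e5-1.066e6); the
defaults above are the single documented working values, and parameter sweeps
are an explicit postprocessing feature rather than a parameter type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Union

import yaml

__all__ = [
    "FluidParams",
    "MicroCellSpec",
    "ExchangeParams",
    "EffectiveTransport",
    "BoundaryData",
    "GeometrySpec",
    "ParameterSet",
    "default_params",
    "default_parameter_set",
    "derive_exchange_coefficients",
    "load_config",
    "save_config",
]


class InvalidGeometryError(ValueError):
    """Raised when a geometry is physically inconsistent (e.g. V_LC <= V_v)."""


@dataclass
class FluidParams:
    """Fluid and porous-matrix constitutive constants."""

    mu: float = 1.0            # dynamic viscosity, mg mm^-1 s^-1
    phi: float = 0.75          # porosity, dimensionless
    mu_star: float = 4.0 / 3.0  # mu_e/mu, dimensionless (1/phi by default)
    rho0: float = 1.0          # density, mg mm^-3 (unused in the steady model)

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"viscosity must be positive, got {self.mu}")
        if not 0 < self.phi <= 1:
            raise ValueError(f"porosity must lie in (0, 1], got {self.phi}")


@dataclass
class MicroCellSpec:
    """Geometry and coefficients of the periodic microscale unit cell."""

    d: float = 2e-2            # cell side / vessel spacing, mm
    r_c: float = 1.7e-3        # micro cylinder radius, mm
    L: float = 1.0             # macroscale length, mm
    K_hat_m: float = 3.84e-9   # dimensional interstitial permeability, mm^2
    Kv_d2_over_mu: float = 1.1e-6  # K_v d^2/mu, mm^3 s/mg (Kozeny-Carman)
    alpha: float = 1.0         # micro Beavers-Joseph-Saffman slip parameter
    N_cells: int = 1310        # cell count (metadata only)

    def __post_init__(self) -> None:
        if not 0 < self.rbar < 0.5:
            raise ValueError(
                f"rbar = r_c/d = {self.rbar} must lie in (0, 0.5)")
        if self.K_m_nd <= 0 or self.K_v_nd <= 0:
            raise ValueError("cell conductivities must be positive")

    @property
    def rbar(self) -> float:
        """Nondimensional tricylinder radius r_c/d."""
        return self.r_c / self.d

    @property
    def epsilon(self) -> float:
        """Scale separation d/L (must be << 1 for homogenization)."""
        return self.d / self.L

    @property
    def K_m_nd(self) -> float:
        """Nondimensional interstitial hydraulic conductivity K_hat_m/d^2."""
        return self.K_hat_m / self.d**2

    @property
    def K_v_nd(self) -> float:
        """Nondimensional vascular conductivity K_v (so that (d^2/mu) K_v
        reproduces the tabulated K_v d^2/mu)."""
        return self.Kv_d2_over_mu / (self.d**2 / 1.0)  # mu enters via FluidParams


@dataclass
class ExchangeParams:
    """Starling-type transcapillary exchange coefficients.

    ``C_m`` and ``C_v`` are the lumped wall conductances per unit compartment
    volume, C_gamma = L_p S_tot / V_gamma_tot, that multiply the Starling
    bracket B = p_m - p_v + sigma*delta_pi in the two Darcy mass balances.
    They are populated by :func:`derive_exchange_coefficients`.
    """

    L_p: float = 5.475e-11     # wall hydraulic conductivity, mm s^-1 mPa^-1
    S_tot: float = 13.4        # total vessel surface, mm^2
    V_v_tot: float = 0.0322    # total vascular volume, mm^3
    sigma: float = 0.9         # Staverman reflection coefficient
    delta_pi: float = 1.02e6   # oncotic difference pi_v - pi_m, mPa
    p_v_bar: float = 1.06e6    # mean blood pressure, mPa
    V_m_tot: Optional[float] = None   # interstitial volume, mm^3 (derived)
    C_m: Optional[float] = None       # L_p S_tot / V_m_tot, s^-1 mPa^-1
    C_v: Optional[float] = None       # L_p S_tot / V_v_tot, s^-1 mPa^-1
    # which volume plays |Omega_m^tot| in the sink coefficient
    # L_p S_tot/|Omega_m^tot|: the full LC volume (default) or the LC volume
    # minus the vascular volume.  The sink is integrated over the whole LC,
    # so the full LC volume keeps the lumped wall conductance at exactly
    # L_p*S_tot; the partitioned option overshoots it by V_LC/V_m (~7%).
    interstitial_volume: str = "lc_total"

    def __post_init__(self) -> None:
        if self.L_p < 0:
            raise ValueError("L_p must be non-negative")
        if not 0 < self.sigma <= 1:
            raise ValueError(f"sigma must lie in (0, 1], got {self.sigma}")
        if self.S_tot <= 0 or self.V_v_tot <= 0:
            raise ValueError("vessel surface and volume must be positive")
        if self.interstitial_volume not in ("lc_minus_vascular", "lc_total"):
            raise ValueError(
                "interstitial_volume must be 'lc_minus_vascular' or 'lc_total'")

    @property
    def wall_conductance(self) -> float:
        """Total wall conductance L_p*S_tot, mm^3 s^-1 mPa^-1."""
        return self.L_p * self.S_tot


@dataclass
class EffectiveTransport:
    """Macroscopic hydraulic conductivities from the homogenization step."""

    Kbar_m: float = 3.65e-9    # interstitial conductivity, mm^3 s mg^-1
    Kbar_v: float = 4.12e-7    # vascular conductivity, mm^3 s mg^-1
    mu: float = 1.0            # viscosity used to form the permeability

    def __post_init__(self) -> None:
        if self.Kbar_m <= 0 or self.Kbar_v <= 0:
            raise ValueError("effective conductivities must be positive")

    @property
    def perm_m(self) -> float:
        """Macroscopic permeability mu*Kbar_m (mm^2), used in the BJS term."""
        return self.mu * self.Kbar_m


@dataclass
class BoundaryData:
    """Inlet/outlet data and the macroscale interface slip parameter."""

    v_in: float = 0.22         # uniform inlet speed, mm/s
    p_out: float = 6.18e5      # outlet pressure, mPa
    alpha_M: float = math.inf  # macro BJS slip parameter (inf => no slip)

    def __post_init__(self) -> None:
        if self.v_in < 0:
            raise ValueError("v_in must be non-negative")
        if self.p_out < 0:
            raise ValueError("p_out must be non-negative")
        if not self.alpha_M > 0:
            raise ValueError("alpha_M must be positive (possibly inf)")


@dataclass
class GeometrySpec:
    """Macroscale node shape parameters (consumed by lnflow.geometry)."""

    shape: str = "sphere"      # 'sphere' or 'oblate'
    R: float = 0.49            # sphere radius, mm
    a: float = 0.5             # spheroid major semiaxis, mm
    b: float = 0.35            # spheroid minor semiaxis, mm
    h: float = 0.01            # subcapsular sinus thickness, mm
    R_LV: float = 0.04         # afferent/efferent aperture radius, mm

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "oblate"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.h <= 0:
            raise ValueError("SCS thickness h must be positive")
        if self.R_LV < 0:
            raise ValueError("aperture radius must be non-negative")


@dataclass
class ParameterSet:
    """The full resolved configuration of one run."""

    fluid: FluidParams = field(default_factory=FluidParams)
    micro: MicroCellSpec = field(default_factory=MicroCellSpec)
    exchange: ExchangeParams = field(default_factory=ExchangeParams)
    bc: BoundaryData = field(default_factory=BoundaryData)
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    mesh_resolution: str = "medium"


def default_params():
    """Return the documented default parameter blocks.

    Returns the tuple ``(FluidParams, MicroCellSpec, ExchangeParams,
    BoundaryData)`` in the mm/s/mg/mPa unit system.
    """
    fluid = FluidParams()
    fluid.mu_star = 1.0 / fluid.phi
    return fluid, MicroCellSpec(), ExchangeParams(), BoundaryData()


def default_parameter_set() -> ParameterSet:
    """The full default configuration, exchange coefficients not yet derived."""
    fluid, micro, exchange, bc = default_params()
    return ParameterSet(fluid=fluid, micro=micro, exchange=exchange, bc=bc)


def derive_exchange_coefficients(
    ex: ExchangeParams, geometry: Union[float, "object"]
) -> ExchangeParams:
    """Fill in V_m_tot, C_m and C_v from the node geometry.

    ``geometry`` is either the LC volume in mm^3 or any object exposing an
    ``lc_volume()`` method (e.g. :class:`lnflow.geometry.NodeGeometry`).

    The interstitial volume is the LC volume minus the vascular volume by
    default (the two microscale phases partition the lymphoid compartment);
    set ``ex.interstitial_volume = 'lc_total'`` to use the full LC volume.
    """
    v_lc = geometry if isinstance(geometry, (int, float)) else geometry.lc_volume()
    if ex.interstitial_volume == "lc_minus_vascular":
        if v_lc <= ex.V_v_tot:
            raise InvalidGeometryError(
                f"LC volume {v_lc} mm^3 does not exceed the vascular volume "
                f"{ex.V_v_tot} mm^3")
        v_m = v_lc - ex.V_v_tot
    else:
        if v_lc <= 0:
            raise InvalidGeometryError("LC volume must be positive")
        v_m = v_lc
    out = replace(ex)
    out.V_m_tot = v_m
    out.C_m = ex.L_p * ex.S_tot / v_m
    out.C_v = ex.L_p * ex.S_tot / ex.V_v_tot
    return out


# ---------------------------------------------------------------------------
# flat key/value configuration files
# ---------------------------------------------------------------------------

_CONFIG_MAP = {
    "fluid.mu": ("fluid", "mu"),
    "fluid.phi": ("fluid", "phi"),
    "fluid.mu_star": ("fluid", "mu_star"),
    "fluid.rho0": ("fluid", "rho0"),
    "micro.d": ("micro", "d"),
    "micro.r_c": ("micro", "r_c"),
    "micro.L": ("micro", "L"),
    "micro.K_hat_m": ("micro", "K_hat_m"),
    "micro.Kv_d2_over_mu": ("micro", "Kv_d2_over_mu"),
    "micro.alpha": ("micro", "alpha"),
    "micro.N_cells": ("micro", "N_cells"),
    "exchange.L_p": ("exchange", "L_p"),
    "exchange.S_tot": ("exchange", "S_tot"),
    "exchange.V_v_tot": ("exchange", "V_v_tot"),
    "exchange.sigma": ("exchange", "sigma"),
    "exchange.delta_pi": ("exchange", "delta_pi"),
    "exchange.p_v_bar": ("exchange", "p_v_bar"),
    "exchange.interstitial_volume": ("exchange", "interstitial_volume"),
    "bc.v_in": ("bc", "v_in"),
    "bc.p_out": ("bc", "p_out"),
    "bc.alpha_M": ("bc", "alpha_M"),
    "geometry.shape": ("geometry", "shape"),
    "geometry.R": ("geometry", "R"),
    "geometry.a": ("geometry", "a"),
    "geometry.b": ("geometry", "b"),
    "geometry.h": ("geometry", "h"),
    "geometry.R_LV": ("geometry", "R_LV"),
    "mesh.resolution": (None, "mesh_resolution"),
}


def load_config(path) -> ParameterSet:
    """Load a flat key/value YAML config into a :class:`ParameterSet`.

    Unknown keys raise a ValueError listing every offending key, so schema
    violations are reported in one pass.  ``bc.alpha_M`` accepts the string
    ``"inf"``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    ps = default_parameter_set()
    bad = [k for k in raw if k not in _CONFIG_MAP]
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    for key, value in raw.items():
        block, attr = _CONFIG_MAP[key]
        if key == "bc.alpha_M" and isinstance(value, str):
            value = math.inf if value.lower() in ("inf", "infinity") else float(value)
        target = ps if block is None else getattr(ps, block)
        setattr(target, attr, value)
    # re-validate after mutation
    for blk in (ps.fluid, ps.micro, ps.exchange, ps.bc, ps.geometry):
        blk.__post_init__()
    return ps


def save_config(ps: ParameterSet, path) -> None:
    """Write a ParameterSet as a flat key/value YAML file (round-trips)."""
    flat = {}
    for key, (block, attr) in _CONFIG_MAP.items():
        target = ps if block is None else getattr(ps, block)
        val = getattr(target, attr)
        if isinstance(val, float) and math.isinf(val):
            val = "inf"
        flat[key] = val
    with open(path, "w") as fh:
        yaml.safe_dump(flat, fh, sort_keys=True)


def parameter_dict(ps: ParameterSet) -> dict:
    """A JSON-serializable snapshot of a parameter set (for run manifests)."""
    d = asdict(ps)
    bc = d["bc"]
    if math.isinf(bc["alpha_M"]):
        bc["alpha_M"] = "inf"
    return d
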