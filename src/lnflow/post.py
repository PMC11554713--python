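"""Derived quantities of a coupled solve: fluxes, profiles, sweeps, inversion.

Sign conventions: Q_in is the influx through the afferent aperture, Q_out
the outflux through the efferent one, Q_scs_to_lc the flux of u·n across
Gamma_M oriented from the SCS into the LC, and Q_lc_to_blood the volume
integral of the Starling sink C_m B (positive when lymph drains into the
blood).  All fluxes are in mm^3/s and include the 2*pi azimuthal factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fem.assemble2d import facet_flux, P2Space
from .geometry import NodeGeometry
from .macro import MacroSolution, SolverConfig, solve_coupled
from .params import (FluidParams, ExchangeParams, EffectiveTransport,
                     BoundaryData, derive_exchange_coefficients)

__all__ = ["FluxReport", "ProfileSeries", "mass_balance",
           "midline_velocity_profile", "interface_shear_stress", "sweep",
           "find_inversion_pressure"]


@dataclass
class FluxReport:
    """Boundary and exchange fluxes of one coupled solution (mm^3/s)."""

    Q_in: float
    Q_out: float
    Q_scs_to_lc: float
    Q_lc_to_blood: float

    @property
    def residual(self) -> float:
        """Discrete mass defect Q_in - Q_out - Q_scs_to_lc."""
        return self.Q_in - self.Q_out - self.Q_scs_to_lc

    def to_dict(self) -> dict:
        d = asdict(self)
        d["residual"] = self.residual
        return d


@dataclass
class ProfileSeries:
    """A quantity sampled along an arc-length coordinate (mm)."""

    s: np.ndarray
    values: np.ndarray
    quantity: str

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("arc length must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"s": self.s, self.quantity: self.values})


def mass_balance(sol: MacroSolution) -> FluxReport:
    """All four fluxes by boundary/volume quadrature of the solved fields."""
    mesh = sol.mesh
    su = sol.space_u
    for tag in ("inlet", "outlet", "interface"):
        if tag not in mesh.facets:
            raise ValueError(f"mesh is missing the facet tag {tag!r}")
    q_in = -facet_flux(su, mesh.facet_p2("inlet"),
                       mesh.facet_normals("inlet"), sol.u)
    q_out = facet_flux(su, mesh.facet_p2("outlet"),
                       mesh.facet_normals("outlet"), sol.u)
    q_iface = facet_flux(su, mesh.facet_p2("interface"),
                         mesh.facet_normals("interface"), sol.u)
    ex = sol.exchange
    sdp = ex.sigma * ex.delta_pi
    sl = sol.space_lc
    B = sol.p_m - sol.p_v + sdp
    q_blood = 2.0 * math.pi * ex.C_m * sl.integrate(B)
    return FluxReport(q_in, q_out, q_iface, q_blood)


def _midline_points(geom: NodeGeometry, n: int):
    th = np.linspace(0.0, math.pi, n)
    inner = geom.lc_point(th)
    outer = geom.outer_point(th)
    mid = 0.5 * (inner + outer)
    seg = np.linalg.norm(np.diff(mid, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return mid, s


def midline_velocity_profile(sol: MacroSolution, n: int = 400
                             ) -> ProfileSeries:
    """Velocity magnitude at the SCS mid-surface, by arc length from the
    inlet pole (parameter theta from 0 to pi)."""
    geom = sol.mesh.geom
    pts, s = _midline_points(geom, n)
    # nudge the polar endpoints off the axis for point location
    pts = pts.copy()
    pts[0, 0] = max(pts[0, 0], 1e-9)
    pts[-1, 0] = max(pts[-1, 0], 1e-9)
    uv = sol.velocity_at(pts)
    return ProfileSeries(s, np.hypot(uv[:, 0], uv[:, 1]),
                         "velocity_magnitude")


def interface_shear_stress(sol: MacroSolution, n: int = 400
                           ) -> ProfileSeries:
    """Magnitude of the tangential viscous traction mu (grad u + grad u^T) n
    on Gamma_M, sampled by arc length from the inlet pole."""
    geom = sol.mesh.geom
    mu = sol.fluid.mu
    th = np.linspace(0.0, math.pi, n)[1:-1]
    pts = geom.lc_point(th)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    # outward normal of the LC curve = from LC into the SCS; sample just
    # inside the SCS to keep point location unambiguous
    tang = np.gradient(pts, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    nrm = np.column_stack([-tang[:, 1], tang[:, 0]])
    # orient outward (away from the origin-ish LC interior)
    sgn = np.sign(np.einsum("ij,ij->i", nrm, pts))
    nrm *= sgn[:, None]
    sample = pts + 1e-7 * nrm
    Gr = sol.velocity_gradient_at(sample)
    E = 0.5 * (Gr + Gr.transpose(0, 2, 1))
    tr = np.einsum("pij,pj->pi", 2.0 * mu * E, -nrm)   # traction with the
    # SCS outward normal n^M = -nrm (pointing into the LC)
    t_n = np.einsum("pi,pi->p", tr, -nrm)
    shear = tr - t_n[:, None] * (-nrm)
    return ProfileSeries(s, np.linalg.norm(shear, axis=1), "shear_stress")


def _resolve(exchange: ExchangeParams, geom: NodeGeometry) -> ExchangeParams:
    return derive_exchange_coefficients(exchange, geom.lc_volume())


def sweep(mesh, fluid: FluidParams, exchange: ExchangeParams,
          transport: EffectiveTransport, bc: BoundaryData,
          parameter: str, values: Sequence[float],
          cfg: Optional[SolverConfig] = None) -> pd.DataFrame:
    """Flux table over a one-parameter family of coupled solves.

    `parameter` is one of 'L_p', 'p_v_bar', 'delta_pi', 'v_in', 'p_out'.
    For 'v_in' the outlet flow normalized by the analytic inlet flow
    pi R_LV^2 v_in is reported as well.  Failed solves are flagged in the
    'ok' column instead of aborting the table.
    """
    geom = mesh.geom
    rows = []
    for val in values:
        ex = replace(exchange)
        b = replace(bc)
        if parameter in ("L_p", "p_v_bar", "delta_pi"):
            setattr(ex, parameter, val)
        elif parameter in ("v_in", "p_out"):
            setattr(b, parameter, val)
        else:
            raise ValueError(f"unknown sweep parameter {parameter!r}")
        ex = _resolve(ex, geom)
        row = {"parameter": parameter, "value": val, "ok": True}
        try:
            sol = solve_coupled(mesh, fluid, ex, transport, b, cfg)
            row.update(mass_balance(sol).to_dict())
            if parameter == "v_in":
                q_ref = math.pi * geom.R_LV**2 * val
                row["Q_out_normalized"] = row["Q_out"] / q_ref
        except Exception as err:   # partial table with flags
            row["ok"] = False
            row["error"] = str(err)
        rows.append(row)
    return pd.DataFrame(rows)


def find_inversion_pressure(mesh, fluid: FluidParams,
                            exchange: ExchangeParams,
                            transport: EffectiveTransport, bc: BoundaryData,
                            bracket=(1.0e6, 1.8e6),
                            cfg: Optional[SolverConfig] = None,
                            tol: float = 1.0e3) -> float:
    """Mean blood pressure p_v_bar at which the net transmural exchange
    Q_lc_to_blood reverses sign.

    The discrete system is affine in p_v_bar, so the root follows exactly
    from two solves (secant); a bisection fallback guards against loss of
    affinity (e.g. user-modified configurations) to within `tol` mPa.
    """
    geom = mesh.geom

    def q_blood(pv):
        ex = replace(exchange, p_v_bar=pv)
        ex = _resolve(ex, geom)
        sol = solve_coupled(mesh, fluid, ex, transport, bc, cfg)
        return mass_balance(sol).Q_lc_to_blood

    a, b = bracket
    qa, qb = q_blood(a), q_blood(b)
    if qa == qb:
        raise RuntimeError("net exchange does not vary over the bracket")
    root = a - qa * (b - a) / (qb - qa)
    qr = q_blood(root)
    scale = max(abs(qa), abs(qb))
    if abs(qr) <= 1e-8 * scale:
        return float(root)
    # bisection fallback
    if qa * qb > 0:
        raise RuntimeError("no sign change of the net exchange in the bracket")
    lo, hi = (a, b) if qa < qb else (b, a)
    while abs(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        if q_blood(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))
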