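"""Coupled macroscale solver: Stokes in the SCS, double Darcy in the LC.

One monolithic sparse system couples four fields on the meridian mesh:

* u = (u_r, u_z): Taylor-Hood P2 velocity in the subcapsular sinus,
* p_f: P1 pressure in the SCS,
* p_m: P2 interstitial pressure in the LC,
* p_v: P2 vascular pressure in the LC.

Governing equations (axisymmetric weak forms, measure r dr dz):

  SCS:  2 mu div(e(u)) = grad p_f,  div u = 0
  LC:   -div(Kbar_m grad p_m) = -C_m B,   -div(Kbar_v grad p_v) = +C_v B,
        with the Starling bracket B = p_m - p_v + sigma*delta_pi.

Interface Gamma_M (normal n pointing from the SCS into the LC):
  u·n = -Kbar_m grad(p_m)·n       (normal-velocity continuity, via the
                                   -∫ (u·n) q coupling term)
  -(T n)·n = p_m                  (normal-stress balance, via +∫ p_m (v·n))
  tangential: Beavers-Joseph-Saffman Robin term with coefficient
  mu*alpha_M/sqrt(perm_m); alpha_M -> infinity (tangential no-slip) is taken
  as the large-coefficient limit of the same term.

Boundary conditions: uniform inflow -v_in e_z on the inlet aperture, traction
-p_out n with pinned tangential velocity on the outlet, no slip on the
capsule, symmetry on the axis, and p_v = p_v_bar on Gamma_M (the vascular
compartment communicates with the systemic circulation at its mean pressure;
the published flow-inversion thresholds pin this choice down).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem.mesh2d import TriMesh2D
from .fem.assemble2d import (P2Space, P1Space, stokes_viscous_axi,
                             stokes_divergence_axi, facet_directional_mass,
                             facet_pressure_coupling, facet_vector_load,
                             apply_dirichlet)
from .geometry import SCS_TAG, LC_TAG
from .params import (FluidParams, ExchangeParams, EffectiveTransport,
                     BoundaryData)

__all__ = ["SolverConfig", "MacroSolution", "solve_coupled",
           "assemble_interface_terms", "solve_lc_only"]

# effective slip parameter representing the alpha_M -> infinity limit
_ALPHA_M_INF = 1.0e6


@dataclass
class SolverConfig:
    """Discretization and solver options for the coupled system."""

    alpha_M: float = math.inf       # macro BJS slip parameter
    pv_dirichlet: bool = True       # p_v = p_v_bar on Gamma_M
    check_finite: bool = True

    def robin_coefficient(self, mu: float, perm_m: float) -> float:
        a = _ALPHA_M_INF if math.isinf(self.alpha_M) else self.alpha_M
        return mu * a / math.sqrt(perm_m)


def assemble_interface_terms(alpha_M: float, perm_m: float, mu: float = 1.0):
    """Tangential Robin coefficient of the BJS interface term.

    Returns ``(coefficient, is_no_slip_limit)``: the weak tangential term is
    coefficient * ∫ (u·tau)(v·tau) r ds; an infinite alpha_M is realised as
    the large-coefficient limit (tangential no-slip).  The normal-stress
    load +∫ p_m (v·n) r ds accompanies it in the momentum equation.
    """
    if not alpha_M > 0:
        raise ValueError("alpha_M must be positive")
    if perm_m <= 0:
        raise ValueError("perm_m must be positive")
    a = _ALPHA_M_INF if math.isinf(alpha_M) else alpha_M
    return mu * a / math.sqrt(perm_m), math.isinf(alpha_M)


@dataclass
class MacroSolution:
    """Coupled solution fields on one meridian mesh."""

    mesh: TriMesh2D
    space_u: P2Space
    space_pf: P1Space
    space_lc: P2Space
    u: np.ndarray                  # (2 n_u,) velocity [u_r; u_z]
    p_f: np.ndarray                # (n_pf,)
    p_m: np.ndarray                # (n_lc,)
    p_v: np.ndarray                # (n_lc,)
    fluid: FluidParams = None
    exchange: ExchangeParams = None
    transport: EffectiveTransport = None
    bc: BoundaryData = None
    diagnostics: Dict[str, float] = field(default_factory=dict)

    # -- field evaluation --------------------------------------------------

    def _finder(self):
        if not hasattr(self, "_tri_finder"):
            import matplotlib.tri as mtri
            scs = self.space_u.conn[:, :3]
            tri = mtri.Triangulation(self.mesh.verts[:, 0],
                                     self.mesh.verts[:, 1], scs)
            self._triangulation = tri
            self._tri_finder = tri.get_trifinder()
        return self._tri_finder

    def velocity_at(self, pts: np.ndarray) -> np.ndarray:
        """Evaluate (u_r, u_z) at points inside the SCS."""
        pts = np.atleast_2d(pts)
        finder = self._finder()
        t = finder(pts[:, 0], pts[:, 1])
        if np.any(t < 0):
            raise ValueError("sampling point outside the SCS subdomain")
        conn = self.space_u.lconn[t]
        verts = self.mesh.verts[self.space_u.conn[t][:, :3]]
        lam = _barycentric(verts, pts)
        N = _p2_from_bary(lam)
        ur = np.einsum("pi,pi->p", N, self.u[conn])
        uz = np.einsum("pi,pi->p", N, self.u[conn + self.space_u.ndof])
        return np.column_stack([ur, uz])

    def velocity_gradient_at(self, pts: np.ndarray) -> np.ndarray:
        """(du_i/dx_j) (p, 2, 2) at points inside the SCS, x = (r, z)."""
        pts = np.atleast_2d(pts)
        finder = self._finder()
        t = finder(pts[:, 0], pts[:, 1])
        if np.any(t < 0):
            raise ValueError("sampling point outside the SCS subdomain")
        conn = self.space_u.lconn[t]
        verts = self.mesh.verts[self.space_u.conn[t][:, :3]]
        lam = _barycentric(verts, pts)
        G = _p2_grad_phys(verts, lam)          # (p, 6, 2)
        out = np.empty((len(pts), 2, 2))
        out[:, 0, :] = np.einsum("pid,pi->pd", G, self.u[conn])
        out[:, 1, :] = np.einsum(
            "pid,pi->pd", G, self.u[conn + self.space_u.ndof])
        return out


def _barycentric(verts: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Barycentric coords of pts w.r.t. triangles verts (p, 3, 2)."""
    a, b, c = verts[:, 0], verts[:, 1], verts[:, 2]
    v0 = b - a
    v1 = c - a
    v2 = pts - a
    den = v0[:, 0] * v1[:, 1] - v1[:, 0] * v0[:, 1]
    l1 = (v2[:, 0] * v1[:, 1] - v1[:, 0] * v2[:, 1]) / den
    l2 = (v0[:, 0] * v2[:, 1] - v2[:, 0] * v0[:, 1]) / den
    return np.column_stack([1.0 - l1 - l2, l1, l2])


def _p2_from_bary(lam: np.ndarray) -> np.ndarray:
    N = np.empty((len(lam), 6))
    N[:, :3] = lam * (2.0 * lam - 1.0)
    N[:, 3] = 4.0 * lam[:, 1] * lam[:, 2]
    N[:, 4] = 4.0 * lam[:, 2] * lam[:, 0]
    N[:, 5] = 4.0 * lam[:, 0] * lam[:, 1]
    return N


def _p2_grad_phys(verts: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Physical gradients of the 6 P2 basis functions at given barycentric
    points of straight triangles (p, 3, 2)."""
    a, b, c = verts[:, 0], verts[:, 1], verts[:, 2]
    # gradients of barycentric coordinates
    den = ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
           - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))
    gl = np.empty((len(verts), 3, 2))
    gl[:, 0, 0] = (b[:, 1] - c[:, 1]) / den
    gl[:, 0, 1] = (c[:, 0] - b[:, 0]) / den
    gl[:, 1, 0] = (c[:, 1] - a[:, 1]) / den
    gl[:, 1, 1] = (a[:, 0] - c[:, 0]) / den
    gl[:, 2, 0] = (a[:, 1] - b[:, 1]) / den
    gl[:, 2, 1] = (b[:, 0] - a[:, 0]) / den
    G = np.empty((len(verts), 6, 2))
    for i in range(3):
        G[:, i] = (4.0 * lam[:, i] - 1.0)[:, None] * gl[:, i]
    pairs = ((1, 2), (2, 0), (0, 1))
    for k, (i, j) in enumerate(pairs):
        G[:, 3 + k] = 4.0 * (lam[:, i][:, None] * gl[:, j]
                             + lam[:, j][:, None] * gl[:, i])
    return G


def _dirichlet_table(mesh: TriMesh2D, space_u: P2Space, bc: BoundaryData):
    """Velocity Dirichlet dofs/values with the documented tie-breaks.

    Priority (later wins): inlet/outlet/axis, then capsule no-slip (the
    aperture rim vertex belongs to the wall).
    """
    n = space_u.ndof
    table: Dict[int, float] = {}

    def set_nodes(tag, comp, value):
        f = mesh.facet_p2(tag)
        nodes = np.unique(f)
        for g in nodes:
            table[int(comp * n + space_u.g2l[g])] = value

    set_nodes("inlet", 0, 0.0)
    set_nodes("inlet", 1, -bc.v_in)
    set_nodes("outlet", 0, 0.0)
    set_nodes("axis_scs", 0, 0.0)
    set_nodes("capsule", 0, 0.0)
    set_nodes("capsule", 1, 0.0)
    dofs = np.fromiter(table.keys(), dtype=np.int64)
    vals = np.fromiter(table.values(), dtype=float)
    return dofs, vals


def solve_coupled(mesh: TriMesh2D, fluid: FluidParams,
                  exchange: ExchangeParams, transport: EffectiveTransport,
                  bc: BoundaryData, cfg: Optional[SolverConfig] = None
                  ) -> MacroSolution:
    """Assemble and solve the monolithic coupled system on a tagged mesh.

    `exchange` must carry the derived coefficients C_m and C_v
    (see :func:`lnflow.params.derive_exchange_coefficients`).
    """
    if cfg is None:
        cfg = SolverConfig(alpha_M=bc.alpha_M)
    if exchange.C_m is None or exchange.C_v is None:
        raise ValueError("exchange coefficients not derived; call "
                         "derive_exchange_coefficients first")
    mu = fluid.mu
    scs_tris = np.flatnonzero(mesh.tri_tags == SCS_TAG)
    lc_tris = np.flatnonzero(mesh.tri_tags == LC_TAG)
    su = P2Space(mesh, scs_tris)
    spf = P1Space(su)
    sl = P2Space(mesh, lc_tris)
    n_u, n_pf, n_l = su.ndof, spf.ndof, sl.ndof

    A = stokes_viscous_axi(su, mu)
    B = stokes_divergence_axi(su, spf)

    fconn = mesh.facet_p2("interface")
    normals = mesh.facet_normals("interface")
    tangents = np.column_stack([-normals[:, 1], normals[:, 0]])
    c_t = cfg.robin_coefficient(mu, transport.perm_m)
    T = facet_directional_mass(su, fconn, tangents, c_t)
    G = facet_pressure_coupling(sl, su, fconn, normals)

    C_m, C_v = exchange.C_m, exchange.C_v
    S_m = sl.stiffness_axi(transport.Kbar_m)
    S_v = sl.stiffness_axi(transport.Kbar_v)
    M_l = sl.mass_axi(1.0)
    sdp = exchange.sigma * exchange.delta_pi

    K = sp.bmat([
        [A + T, -B.T, G.T, None],
        [B, None, None, None],
        [-G, None, S_m + C_m * M_l, -C_m * M_l],
        [None, None, -C_v * M_l, S_v + C_v * M_l],
    ], format="csr")

    rhs = np.zeros(K.shape[0])
    # outlet traction -p_out n (natural with the stress form)
    f_out = mesh.facet_p2("outlet")
    n_out = mesh.facet_normals("outlet")
    rhs[:2 * n_u] += facet_vector_load(su, f_out, -bc.p_out * n_out)
    ones_l = sl.load_axi(1.0)
    rhs[2 * n_u + n_pf:2 * n_u + n_pf + n_l] += -C_m * sdp * ones_l
    rhs[2 * n_u + n_pf + n_l:] += C_v * sdp * ones_l

    dofs_u, vals_u = _dirichlet_table(mesh, su, bc)
    dofs = [dofs_u]
    vals = [vals_u]
    if cfg.pv_dirichlet:
        iface_nodes = np.unique(fconn)
        pv_dofs = 2 * n_u + n_pf + n_l + sl.g2l[iface_nodes]
        dofs.append(pv_dofs)
        vals.append(np.full(len(iface_nodes), exchange.p_v_bar))
    dofs = np.concatenate(dofs)
    vals = np.concatenate(vals)
    K, rhs = apply_dirichlet(K, rhs, dofs, vals)

    x = spla.spsolve(K.tocsc(), rhs)
    if cfg.check_finite and not np.all(np.isfinite(x)):
        raise RuntimeError("linear solver returned non-finite values")
    u = x[:2 * n_u]
    p_f = x[2 * n_u:2 * n_u + n_pf]
    p_m = x[2 * n_u + n_pf:2 * n_u + n_pf + n_l]
    p_v = x[2 * n_u + n_pf + n_l:]
    sol = MacroSolution(mesh, su, spf, sl, u, p_f, p_m, p_v,
                        fluid=fluid, exchange=exchange, transport=transport,
                        bc=bc)
    sol.diagnostics = {
        "ndof": float(K.shape[0]),
        "robin_coefficient": c_t,
    }
    return sol


def solve_lc_only(mesh: TriMesh2D, exchange: ExchangeParams,
                  transport: EffectiveTransport, P_b: float
                  ) -> MacroSolution:
    """Solve only the two exchange-coupled Darcy fields in the LC with
    uniform Dirichlet data p_m = P_b and p_v = p_v_bar on Gamma_M.

    Used to verify the LC block against the closed-form sphere solution.
    """
    if exchange.C_m is None or exchange.C_v is None:
        raise ValueError("exchange coefficients not derived")
    lc_tris = np.flatnonzero(mesh.tri_tags == LC_TAG)
    sl = P2Space(mesh, lc_tris)
    n_l = sl.ndof
    C_m, C_v = exchange.C_m, exchange.C_v
    S_m = sl.stiffness_axi(transport.Kbar_m)
    S_v = sl.stiffness_axi(transport.Kbar_v)
    M_l = sl.mass_axi(1.0)
    sdp = exchange.sigma * exchange.delta_pi
    K = sp.bmat([[S_m + C_m * M_l, -C_m * M_l],
                 [-C_v * M_l, S_v + C_v * M_l]], format="csr")
    ones_l = sl.load_axi(1.0)
    rhs = np.concatenate([-C_m * sdp * ones_l, C_v * sdp * ones_l])
    iface_nodes = np.unique(mesh.facet_p2("interface"))
    loc = sl.g2l[iface_nodes]
    dofs = np.concatenate([loc, n_l + loc])
    vals = np.concatenate([np.full(len(loc), P_b),
                           np.full(len(loc), exchange.p_v_bar)])
    K, rhs = apply_dirichlet(K, rhs, dofs, vals)
    x = spla.spsolve(K.tocsc(), rhs)
    return MacroSolution(mesh, None, None, sl, None, None,
                         x[:n_l], x[n_l:], exchange=exchange,
                         transport=transport)
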