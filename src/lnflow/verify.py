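"""Independent verification oracles for the macroscale solver.

Three oracles, none of which shares code with the FEM path they check:

1. ``sphere_oracle`` -- the exchange-coupled double-Darcy system with
   constant coefficients in a sphere of radius R with uniform Dirichlet data
   has a closed-form solution.  The Starling bracket B = p_m - p_v +
   sigma*delta_pi satisfies a modified Helmholtz equation,

       Lap(B) = lambda^2 B,   lambda^2 = C_m/Kbar_m + C_v/Kbar_v,

   whose regular radial solution is B(r) = A sinh(lambda r)/r.  The
   conjugate combination (Kbar_m/C_m) p_m + (Kbar_v/C_v) p_v is harmonic,
   hence constant under uniform Dirichlet data, which closes the 2x2 system
   for p_m(r) and p_v(r).

2. ``lumped_balance`` -- the zero-dimensional Starling balance
   C_m V_m (p_m_mean - p_v_bar + sigma*delta_pi), an order-of-magnitude
   check on the net transmural exchange.

3. ``manufactured_stokes_check`` -- an axisymmetric manufactured solution
   (annular channel, non-polynomial velocity/pressure) exercising the
   Taylor-Hood Stokes block at its theoretical convergence rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem.mesh2d import TriMesh2D
from .fem.assemble2d import (P2Space, P1Space, stokes_viscous_axi,
                             stokes_divergence_axi, vector_load_axi,
                             apply_dirichlet)
from .params import ExchangeParams, EffectiveTransport

__all__ = ["SphereOracleSolution", "sphere_oracle", "lumped_balance",
           "manufactured_stokes_check"]


@dataclass
class SphereOracleSolution:
    """Closed-form double-Darcy fields in a sphere of radius R_LC."""

    R: float
    lam: float
    A: float                 # amplitude of B(r) = A sinh(lam r)/r
    H0: float                # value of the harmonic combination
    alpha: float             # Kbar_m / C_m
    beta: float              # Kbar_v / C_v
    sigma_dpi: float
    P_b: float
    p_v_bar: float
    decoupled: bool          # C_m = C_v = 0 limit

    def bracket(self, r):
        """Starling bracket B(r) = p_m - p_v + sigma*delta_pi."""
        r = np.asarray(r, dtype=float)
        if self.decoupled:
            return np.full_like(r, self.P_b - self.p_v_bar + self.sigma_dpi)
        lr = self.lam * r
        # sinh(x)/x, regular at 0
        s = np.where(np.abs(lr) < 1e-8, 1.0 + lr**2 / 6.0,
                     np.sinh(lr) / np.where(lr == 0.0, 1.0, lr))
        return self.A * self.lam * s

    def p_m(self, r):
        if self.decoupled:
            return np.full_like(np.asarray(r, dtype=float), self.P_b)
        B = self.bracket(r)
        pv = (self.H0 - self.alpha * (B - self.sigma_dpi)) / (self.alpha + self.beta)
        return pv + B - self.sigma_dpi

    def p_v(self, r):
        if self.decoupled:
            return np.full_like(np.asarray(r, dtype=float), self.p_v_bar)
        B = self.bracket(r)
        return (self.H0 - self.alpha * (B - self.sigma_dpi)) / (self.alpha + self.beta)

    def net_exchange(self, C_m: float) -> float:
        """∫ C_m B dV over the sphere (mm^3/s), closed form."""
        if self.decoupled:
            return 0.0
        lam, R = self.lam, self.R
        integral = 4.0 * math.pi * (R * math.cosh(lam * R) / lam
                                    - math.sinh(lam * R) / lam**2)
        return C_m * self.A * integral


def sphere_oracle(exchange: ExchangeParams, transport: EffectiveTransport,
                  P_b: float, R: float,
                  p_v_bar: float = None) -> SphereOracleSolution:
    """Closed-form solution with p_m = P_b, p_v = p_v_bar at r = R."""
    pv_bar = exchange.p_v_bar if p_v_bar is None else p_v_bar
    sdp = exchange.sigma * exchange.delta_pi
    C_m, C_v = exchange.C_m, exchange.C_v
    if C_m is None or C_v is None:
        raise ValueError("exchange coefficients not derived")
    Km, Kv = transport.Kbar_m, transport.Kbar_v
    if C_m == 0.0 and C_v == 0.0:
        return SphereOracleSolution(R, 0.0, 0.0, 0.0, math.inf, math.inf,
                                    sdp, P_b, pv_bar, decoupled=True)
    lam = math.sqrt(C_m / Km + C_v / Kv)
    B_b = P_b - pv_bar + sdp
    x = lam * R
    if x > 700.0:
        # asymptotic amplitude to avoid overflow; B decays like e^{lam(r-R)}
        A = B_b * R * 2.0 * math.exp(-x)
    else:
        A = B_b * R / math.sinh(x)
    alpha = Km / C_m if C_m > 0 else math.inf
    beta = Kv / C_v if C_v > 0 else math.inf
    H0 = (0.0 if math.isinf(alpha) or math.isinf(beta)
          else alpha * P_b + beta * pv_bar)
    return SphereOracleSolution(R, lam, A, H0, alpha, beta, sdp, P_b,
                                pv_bar, decoupled=False)


def lumped_balance(exchange: ExchangeParams, p_m_mean: float) -> float:
    """Zero-dimensional Starling balance C_m V_m (p_m_mean - p_v_bar +
    sigma*delta_pi) = L_p S_tot (...) in mm^3/s (positive into the blood)."""
    if exchange.C_m is None or exchange.V_m_tot is None:
        raise ValueError("exchange coefficients not derived")
    return exchange.C_m * exchange.V_m_tot * (
        p_m_mean - exchange.p_v_bar + exchange.sigma * exchange.delta_pi)


# ---------------------------------------------------------------------------
# manufactured axisymmetric Stokes solution
# ---------------------------------------------------------------------------

_R1, _R2 = 0.5, 1.0


def _mms_exact(pts: np.ndarray):
    """Exact (u_r, u_z, p) of the manufactured annular solution."""
    r, z = pts[..., 0], pts[..., 1]
    k = math.pi / (_R2 - _R1)
    u_r = np.zeros_like(r)
    u_z = np.sin(k * (r - _R1))
    p = np.cos(math.pi * z)
    return u_r, u_z, p


def _mms_force(pts: np.ndarray) -> np.ndarray:
    """Body force f = grad p - mu Lap u for the exact solution (mu = 1)."""
    r, z = pts[..., 0], pts[..., 1]
    k = math.pi / (_R2 - _R1)
    f_r = np.zeros_like(r)
    f_z = (k**2 * np.sin(k * (r - _R1)) - (k / r) * np.cos(k * (r - _R1))
           - math.pi * np.sin(math.pi * z))
    return np.stack([f_r, f_z], axis=-1)


def _annulus_mesh(n: int) -> TriMesh2D:
    """Structured annular-channel mesh on [_R1, _R2] x [0, 1]."""
    rs = np.linspace(_R1, _R2, n + 1)
    zs = np.linspace(0.0, 1.0, n + 1)
    R, Z = np.meshgrid(rs, zs, indexing="ij")
    verts = np.column_stack([R.ravel(), Z.ravel()])
    nv = n + 1

    def vid(i, j):
        return i * nv + j

    tris = []
    bfacets = []
    for i in range(n):
        for j in range(n):
            tris.append([vid(i, j), vid(i + 1, j), vid(i + 1, j + 1)])
            tris.append([vid(i, j), vid(i + 1, j + 1), vid(i, j + 1)])
    for i in range(n):
        bfacets.append([vid(i, 0), vid(i + 1, 0)])
        bfacets.append([vid(i + 1, n), vid(i, n)])
    for j in range(n):
        bfacets.append([vid(0, j + 1), vid(0, j)])
        bfacets.append([vid(n, j), vid(n, j + 1)])
    return TriMesh2D(verts, np.asarray(tris), np.zeros(len(tris), dtype=int),
                     {"wall": np.asarray(bfacets, dtype=np.int64)})


def _solve_mms(n: int):
    mesh = _annulus_mesh(n)
    su = P2Space(mesh, np.arange(len(mesh.tris)))
    spf = P1Space(su)
    A = stokes_viscous_axi(su, 1.0)
    B = stokes_divergence_axi(su, spf)
    K = sp.bmat([[A, -B.T], [B, None]], format="csr")
    rhs = np.concatenate([vector_load_axi(su, _mms_force),
                          np.zeros(spf.ndof)])
    # Dirichlet from the exact velocity on the whole boundary
    bnodes = np.unique(mesh.facet_p2("wall"))
    loc = su.g2l[bnodes]
    ur, uz, _ = _mms_exact(mesh.p2_coords[bnodes])
    dofs = np.concatenate([loc, loc + su.ndof])
    vals = np.concatenate([ur, uz])
    K, rhs = apply_dirichlet(K, rhs, dofs, vals)
    # pin one pressure dof (pure Dirichlet problem)
    pin = 2 * su.ndof
    K = K.tolil()
    K[pin, :] = 0.0
    K[pin, pin] = 1.0
    rhs[pin] = 0.0
    x = spla.spsolve(K.tocsr().tocsc(), rhs)
    u = x[:2 * su.ndof]
    p = x[2 * su.ndof:]

    # L2 errors by quadrature (pressure compared up to its mean)
    X, w = su.quad_points()
    wq = w * X[..., 0]
    ur_ex, uz_ex, p_ex = _mms_exact(X)
    N2 = su._qd.N2
    N1 = su._qd.N1
    ur_h = np.einsum("qi,ti->tq", N2, u[su.lconn])
    uz_h = np.einsum("qi,ti->tq", N2, u[su.lconn + su.ndof])
    p_h = np.einsum("qi,ti->tq", N1, p[spf.lconn])
    area = np.sum(wq)
    dp = (np.sum((p_h - p_ex) * wq) / area)
    err_u = np.sqrt(np.sum(((ur_h - ur_ex)**2 + (uz_h - uz_ex)**2) * wq))
    err_p = np.sqrt(np.sum((p_h - p_ex - dp)**2 * wq))
    return err_u, err_p


def manufactured_stokes_check(levels: Sequence[int] = (4, 8, 16)) -> dict:
    """Convergence study of the axisymmetric Taylor-Hood Stokes block.

    Solves the manufactured annular-channel problem on nested meshes and
    returns the L2 errors and observed convergence rates (expected: 3 for
    velocity, 2 for pressure).
    """
    errs = [_solve_mms(n) for n in levels]
    eu = np.array([e[0] for e in errs])
    ep = np.array([e[1] for e in errs])
    hs = 1.0 / np.asarray(levels, dtype=float)
    rate_u = np.polyfit(np.log(hs), np.log(eu), 1)[0]
    rate_p = np.polyfit(np.log(hs), np.log(ep), 1)[0]
    return {"levels": list(levels), "err_u": eu.tolist(),
            "err_p": ep.tolist(), "rate_u": float(rate_u),
            "rate_p": float(rate_p)}
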