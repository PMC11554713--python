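"""Axisymmetric P2/P1 assembly kernels in the meridian (r, z) plane.

All volume integrals carry the axisymmetric measure r dr dz (the 2*pi factor
is applied by postprocessing when fluxes are reported), and all boundary
integrals carry r ds.  Velocity uses the symmetric-gradient (Cauchy stress)
form, so prescribed-traction conditions are natural.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .quadrature import tri_rule, gauss1d
from .mesh2d import TriMesh2D

__all__ = ["P2Space", "P1Space", "apply_dirichlet"]


# P2 reference shape functions; local nodes 0,1,2 vertices, 3=mid(1,2),
# 4=mid(2,0), 5=mid(0,1)
def _p2_shape(xi, eta):
    lam = np.array([1.0 - xi - eta, xi, eta])
    n = np.empty(6)
    n[:3] = lam * (2.0 * lam - 1.0)
    n[3] = 4.0 * lam[1] * lam[2]
    n[4] = 4.0 * lam[2] * lam[0]
    n[5] = 4.0 * lam[0] * lam[1]
    return n


def _p2_grad(xi, eta):
    lam = np.array([1.0 - xi - eta, xi, eta])
    dlam = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])  # d lam_i / d(xi,eta)
    g = np.empty((6, 2))
    for i in range(3):
        g[i] = (4.0 * lam[i] - 1.0) * dlam[i]
    g[3] = 4.0 * (lam[1] * dlam[2] + lam[2] * dlam[1])
    g[4] = 4.0 * (lam[2] * dlam[0] + lam[0] * dlam[2])
    g[5] = 4.0 * (lam[0] * dlam[1] + lam[1] * dlam[0])
    return g


def _p1_shape(xi, eta):
    return np.array([1.0 - xi - eta, xi, eta])


@dataclass
class _QData:
    """Per-quadrature-point data shared by all kernels on one tri subset."""

    N2: np.ndarray        # (Q, 6) P2 values
    G2ref: np.ndarray     # (Q, 6, 2) P2 reference gradients
    N1: np.ndarray        # (Q, 3) P1 values
    w: np.ndarray         # (Q,)
    pts: np.ndarray       # (Q, 2)


def _quad_data(degree: int = 5) -> _QData:
    pts, w = tri_rule(degree)
    N2 = np.array([_p2_shape(x, y) for x, y in pts])
    G2 = np.array([_p2_grad(x, y) for x, y in pts])
    N1 = np.array([_p1_shape(x, y) for x, y in pts])
    return _QData(N2, G2, N1, w, pts)


class P2Space:
    """Scalar P2 space restricted to a triangle subset of a TriMesh2D."""

    def __init__(self, mesh: TriMesh2D, tri_idx: np.ndarray):
        mesh.build_p2()
        self.mesh = mesh
        self.tri_idx = np.asarray(tri_idx, dtype=np.int64)
        self.conn = mesh.tri_p2()[self.tri_idx]          # (T, 6) global P2 ids
        self.nodes = np.unique(self.conn)
        self.g2l = -np.ones(mesh.n_p2, dtype=np.int64)
        self.g2l[self.nodes] = np.arange(len(self.nodes))
        self.lconn = self.g2l[self.conn]
        self.ndof = len(self.nodes)
        self.coords = mesh.p2_coords[self.nodes]
        self._geom = None
        self._qd = _quad_data()

    # -- element geometry --------------------------------------------------

    def _geometry(self):
        if self._geom is None:
            v = self.mesh.verts
            t = self.conn[:, :3]
            x0 = v[t[:, 0]]
            j11 = v[t[:, 1], 0] - x0[:, 0]
            j21 = v[t[:, 1], 1] - x0[:, 1]
            j12 = v[t[:, 2], 0] - x0[:, 0]
            j22 = v[t[:, 2], 1] - x0[:, 1]
            det = j11 * j22 - j12 * j21
            # invT = J^{-T}: physical gradient = J^{-T} @ reference gradient
            invT = np.empty((len(t), 2, 2))
            invT[:, 0, 0] = j22 / det
            invT[:, 0, 1] = -j21 / det
            invT[:, 1, 0] = -j12 / det
            invT[:, 1, 1] = j11 / det
            self._geom = (x0, np.stack([j11, j12, j21, j22], axis=1), det, invT)
        return self._geom

    def quad_points(self):
        """Physical coordinates (T, Q, 2) and weights*|J| (T, Q)."""
        x0, jj, det, _ = self._geometry()
        qp = self._qd.pts
        X = (x0[:, None, 0] + np.outer(jj[:, 0], qp[:, 0]).reshape(len(det), -1)
             + np.outer(jj[:, 1], qp[:, 1]).reshape(len(det), -1))
        Z = (x0[:, None, 1] + np.outer(jj[:, 2], qp[:, 0]).reshape(len(det), -1)
             + np.outer(jj[:, 3], qp[:, 1]).reshape(len(det), -1))
        w = np.outer(det, self._qd.w)
        return np.stack([X, Z], axis=-1), w

    def phys_grads(self):
        """Physical P2 gradients, shape (T, Q, 6, 2)."""
        _, _, _, invT = self._geometry()
        Gref = self._qd.G2ref                      # (Q, 6, 2)
        return np.einsum("tij,qnj->tqni", invT, Gref)

    # -- volume kernels (axisymmetric, weight r) ---------------------------

    def stiffness_axi(self, coeff: float = 1.0) -> sp.csr_matrix:
        X, w = self.quad_points()
        r = X[..., 0]
        G = self.phys_grads()
        wloc = coeff * w * r                             # (T, Q)
        ke = np.einsum("tq,tqid,tqjd->tij", wloc, G, G)
        return self._scatter(ke, self.lconn, self.lconn,
                             (self.ndof, self.ndof))

    def mass_axi(self, coeff: float = 1.0) -> sp.csr_matrix:
        X, w = self.quad_points()
        r = X[..., 0]
        N = self._qd.N2
        wloc = coeff * w * r
        ke = np.einsum("tq,qi,qj->tij", wloc, N, N)
        return self._scatter(ke, self.lconn, self.lconn,
                             (self.ndof, self.ndof))

    def load_axi(self, f) -> np.ndarray:
        """RHS vector of ∫ f v r; f is a constant or callable f(x) on (.., 2)."""
        X, w = self.quad_points()
        r = X[..., 0]
        fv = f(X) if callable(f) else float(f) * np.ones_like(r)
        wloc = fv * w * r
        fe = np.einsum("tq,qi->ti", wloc, self._qd.N2)
        out = np.zeros(self.ndof)
        np.add.at(out, self.lconn.ravel(), fe.ravel())
        return out

    def integrate(self, vals: np.ndarray) -> float:
        """∫ u r over the subset for a P2 coefficient vector `vals`."""
        X, w = self.quad_points()
        r = X[..., 0]
        u = np.einsum("qi,ti->tq", self._qd.N2, vals[self.lconn])
        return float(np.sum(u * w * r))

    def volume(self) -> float:
        """Revolved volume 2*pi*∫ r dA of the subset (Pappus)."""
        X, w = self.quad_points()
        return float(2.0 * np.pi * np.sum(w * X[..., 0]))

    @staticmethod
    def _scatter(ke, rows_conn, cols_conn, shape) -> sp.csr_matrix:
        T, ni, nj = ke.shape
        rows = np.repeat(rows_conn, nj, axis=1).ravel()
        cols = np.tile(cols_conn, (1, ni)).ravel()
        return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=shape).tocsr()


class P1Space:
    """Scalar P1 space (vertex dofs) on the same triangle subset as a P2Space."""

    def __init__(self, p2: P2Space):
        self.p2 = p2
        conn = p2.conn[:, :3]
        self.nodes = np.unique(conn)
        self.g2l = -np.ones(p2.mesh.n_p2, dtype=np.int64)
        self.g2l[self.nodes] = np.arange(len(self.nodes))
        self.lconn = self.g2l[conn]
        self.ndof = len(self.nodes)
        self.coords = p2.mesh.verts[self.nodes]


# ---------------------------------------------------------------------------
# Stokes blocks (vector P2 velocity = [u_r; u_z] stacked scalar spaces)
# ---------------------------------------------------------------------------

def stokes_viscous_axi(space: P2Space, mu: float) -> sp.csr_matrix:
    """2*mu*∫ e(u):e(v) r with the axisymmetric strain (includes u_r/r hoop).

    Velocity dof layout: [u_r (ndof); u_z (ndof)].
    """
    X, w = space.quad_points()
    r = X[..., 0]
    G = space.phys_grads()           # (T,Q,6,2): columns d/dr, d/dz
    N = space._qd.N2                 # (Q,6)
    wq = w * r
    dr = G[..., 0]                   # (T,Q,6)
    dz = G[..., 1]
    Nq = np.broadcast_to(N, dr.shape)
    # blocks: rr, rz, zr, zz of the viscous operator
    # e_rr = du_r/dr ; e_zz = du_z/dz ; e_qq = u_r/r ; e_rz = (u_r,z+u_z,r)/2
    # 2 mu [e_rr(u)e_rr(v) + e_zz e_zz + e_qq e_qq + 2 e_rz e_rz]
    hoop = Nq / np.maximum(r[..., None], 1e-300)   # u_r/r factor; r>0 at quad pts
    k_rr = (2.0 * np.einsum("tq,tqi,tqj->tij", wq, dr, dr)
            + 2.0 * np.einsum("tq,tqi,tqj->tij", wq, hoop, hoop)
            + np.einsum("tq,tqi,tqj->tij", wq, dz, dz))
    k_rz = np.einsum("tq,tqi,tqj->tij", wq, dz, dr)
    k_zr = k_rz.transpose(0, 2, 1)
    k_zz = (2.0 * np.einsum("tq,tqi,tqj->tij", wq, dz, dz)
            + np.einsum("tq,tqi,tqj->tij", wq, dr, dr))
    n = space.ndof
    lc = space.lconn

    def block(ke, roff, coff):
        T, ni, nj = ke.shape
        rows = np.repeat(lc, nj, axis=1).ravel() + roff
        cols = np.tile(lc, (1, ni)).ravel() + coff
        return rows, cols, ke.ravel()

    parts = [block(mu * k_rr, 0, 0), block(mu * k_rz, 0, n),
             block(mu * k_zr, n, 0), block(mu * k_zz, n, n)]
    rows = np.concatenate([p[0] for p in parts])
    cols = np.concatenate([p[1] for p in parts])
    vals = np.concatenate([p[2] for p in parts])
    return sp.coo_matrix((vals, (rows, cols)), shape=(2 * n, 2 * n)).tocsr()


def stokes_divergence_axi(space_u: P2Space, space_p: P1Space) -> sp.csr_matrix:
    """B with B[q, v] = ∫ q (dv_r/dr + v_r/r + dv_z/dz) r = ∫ q div_axi(v) r."""
    X, w = space_u.quad_points()
    r = X[..., 0]
    G = space_u.phys_grads()
    N2 = space_u._qd.N2
    N1 = space_u._qd.N1
    wq = w * r
    dr = G[..., 0]
    dz = G[..., 1]
    hoop = np.broadcast_to(N2, dr.shape) / np.maximum(r[..., None], 1e-300)
    b_r = np.einsum("tq,qi,tqj->tij", wq, N1, dr + hoop)
    b_z = np.einsum("tq,qi,tqj->tij", wq, N1, dz)
    n_u = space_u.ndof
    rows = np.concatenate([
        np.repeat(space_p.lconn, 6, axis=1).ravel(),
        np.repeat(space_p.lconn, 6, axis=1).ravel(),
    ])
    cols = np.concatenate([
        np.tile(space_u.lconn, (1, 3)).ravel(),
        np.tile(space_u.lconn, (1, 3)).ravel() + n_u,
    ])
    vals = np.concatenate([b_r.ravel(), b_z.ravel()])
    return sp.coo_matrix((vals, (rows, cols)),
                         shape=(space_p.ndof, 2 * n_u)).tocsr()


def vector_load_axi(space: P2Space, f) -> np.ndarray:
    """RHS ∫ f·v r for body force f(x) -> (..., 2) (or constant pair)."""
    X, w = space.quad_points()
    r = X[..., 0]
    if callable(f):
        fv = f(X)
    else:
        fv = np.broadcast_to(np.asarray(f, dtype=float), X.shape)
    wq = w * r
    fe_r = np.einsum("tq,qi->ti", fv[..., 0] * wq, space._qd.N2)
    fe_z = np.einsum("tq,qi->ti", fv[..., 1] * wq, space._qd.N2)
    out = np.zeros(2 * space.ndof)
    np.add.at(out, space.lconn.ravel(), fe_r.ravel())
    np.add.at(out, space.lconn.ravel() + space.ndof, fe_z.ravel())
    return out


# ---------------------------------------------------------------------------
# facet kernels
# ---------------------------------------------------------------------------

def _facet_quad(mesh: TriMesh2D, fconn: np.ndarray, npts: int = 4):
    """Gauss data on straight facets: points (F,Q,2), weights*|ds| (F,Q),
    P2 facet shape values (Q,3) in local order (v0, v1, mid)."""
    xq, wq = gauss1d(npts)
    v0 = mesh.verts[fconn[:, 0]]
    v1 = mesh.verts[fconn[:, 1]]
    d = v1 - v0
    L = np.hypot(d[:, 0], d[:, 1])
    pts = v0[:, None, :] + d[:, None, :] * xq[None, :, None]
    w = np.outer(L, wq)
    # 1D quadratic shape functions on [0,1] for nodes (0, 1, 1/2)
    N = np.column_stack([
        (1.0 - xq) * (1.0 - 2.0 * xq),
        xq * (2.0 * xq - 1.0),
        4.0 * xq * (1.0 - xq),
    ])
    return pts, w, N


def facet_directional_mass(space: P2Space, fconn: np.ndarray,
                           dirs: np.ndarray, coeff) -> sp.csr_matrix:
    """∫ c (u·d)(v·d) r ds on facets, d a unit direction per facet.

    Returns a (2n, 2n) matrix on the velocity layout of `space`.
    `coeff` is a scalar or per-facet array.
    """
    mesh = space.mesh
    pts, w, N = _facet_quad(mesh, fconn)
    r = pts[..., 0]
    c = np.asarray(coeff, dtype=float)
    if c.ndim == 0:
        c = np.full(len(fconn), float(c))
    wq = w * r * c[:, None]
    ke = np.einsum("fq,qi,qj->fij", wq, N, N)        # (F,3,3) scalar part
    lc = space.g2l[fconn]
    if np.any(lc < 0):
        raise ValueError("facet nodes outside the velocity space")
    n = space.ndof
    rows, cols, vals = [], [], []
    for a in range(2):
        for b in range(2):
            fac = dirs[:, a] * dirs[:, b]
            keab = ke * fac[:, None, None]
            rows.append((np.repeat(lc, 3, axis=1) + a * n).ravel())
            cols.append((np.tile(lc, (1, 3)) + b * n).ravel())
            vals.append(keab.ravel())
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(2 * n, 2 * n)).tocsr()


def facet_pressure_coupling(space_scalar: P2Space, space_u: P2Space,
                            fconn: np.ndarray, normals: np.ndarray
                            ) -> sp.csr_matrix:
    """G[q, v] = ∫ q (v·n) r ds on facets shared by both spaces."""
    mesh = space_u.mesh
    pts, w, N = _facet_quad(mesh, fconn)
    r = pts[..., 0]
    wq = w * r
    ke = np.einsum("fq,qi,qj->fij", wq, N, N)
    lc_s = space_scalar.g2l[fconn]
    lc_u = space_u.g2l[fconn]
    if np.any(lc_s < 0) or np.any(lc_u < 0):
        raise ValueError("facet nodes outside a coupling space")
    n_u = space_u.ndof
    rows, cols, vals = [], [], []
    for b in range(2):
        keb = ke * normals[:, b][:, None, None]
        rows.append(np.repeat(lc_s, 3, axis=1).ravel())
        cols.append((np.tile(lc_u, (1, 3)) + b * n_u).ravel())
        vals.append(keb.ravel())
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(space_scalar.ndof, 2 * n_u)).tocsr()


def facet_vector_load(space: P2Space, fconn: np.ndarray,
                      traction: np.ndarray) -> np.ndarray:
    """RHS ∫ t·v r ds for a constant traction per facet, shape (F, 2)."""
    mesh = space.mesh
    pts, w, N = _facet_quad(mesh, fconn)
    r = pts[..., 0]
    wq = w * r
    fe = np.einsum("fq,qi->fi", wq, N)
    lc = space.g2l[fconn]
    out = np.zeros(2 * space.ndof)
    np.add.at(out, lc.ravel(), (fe * traction[:, 0][:, None]).ravel())
    np.add.at(out, (lc + space.ndof).ravel(),
              (fe * traction[:, 1][:, None]).ravel())
    return out


def facet_flux(space: P2Space, fconn: np.ndarray, normals: np.ndarray,
               u: np.ndarray) -> float:
    """2*pi*∫ (u·n) r ds for a velocity vector on the space layout."""
    mesh = space.mesh
    pts, w, N = _facet_quad(mesh, fconn)
    r = pts[..., 0]
    lc = space.g2l[fconn]
    ur = np.einsum("qi,fi->fq", N, u[lc])
    uz = np.einsum("qi,fi->fq", N, u[lc + space.ndof])
    un = ur * normals[:, 0][:, None] + uz * normals[:, 1][:, None]
    return float(2.0 * np.pi * np.sum(un * w * r))


def facet_scalar_values(space: P2Space, fconn: np.ndarray,
                        vals: np.ndarray):
    """Scalar P2 field sampled at facet quadrature points: (F, Q) + weights."""
    mesh = space.mesh
    pts, w, N = _facet_quad(mesh, fconn)
    lc = space.g2l[fconn]
    v = np.einsum("qi,fi->fq", N, vals[lc])
    return v, w, pts


# ---------------------------------------------------------------------------
# boundary conditions
# ---------------------------------------------------------------------------

def apply_dirichlet(A: sp.spmatrix, b: np.ndarray, dofs: np.ndarray,
                    values: np.ndarray):
    """Impose u[dofs] = values by row/column elimination (returns csr, rhs)."""
    A = A.tocsr()
    n = A.shape[0]
    dofs = np.asarray(dofs, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    x0 = np.zeros(n)
    x0[dofs] = values
    b = b - A @ x0
    keep = np.ones(n, dtype=bool)
    keep[dofs] = False
    # zero rows and columns, set identity on the diagonal
    D = sp.diags(keep.astype(float))
    A = D @ A @ D + sp.diags((~keep).astype(float))
    b[dofs] = values
    return A.tocsr(), b
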