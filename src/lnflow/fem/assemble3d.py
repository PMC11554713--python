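"""P2/P1 assembly on straight tetrahedral meshes (microscale cell problems).

Kernels accumulate per quadrature point to keep the working set small on
meshes with ~1e5 elements.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .quadrature import tet_rule, tri_rule
from .mesh3d import TetMesh3D, _TET_EDGES

__all__ = ["P2Space3D", "P1Space3D"]


def _p2_shape3(lam: np.ndarray) -> np.ndarray:
    """P2 values for barycentric coords lam (4,); node order: 4 verts + 6 edges."""
    n = np.empty(10)
    n[:4] = lam * (2.0 * lam - 1.0)
    for k, (a, b) in enumerate(_TET_EDGES):
        n[4 + k] = 4.0 * lam[a] * lam[b]
    return n


def _p2_grad3(lam: np.ndarray) -> np.ndarray:
    """Reference gradients (10, 3) w.r.t. (xi, eta, zeta)."""
    dlam = np.array([[-1.0, -1.0, -1.0],
                     [1.0, 0.0, 0.0],
                     [0.0, 1.0, 0.0],
                     [0.0, 0.0, 1.0]])
    g = np.empty((10, 3))
    for i in range(4):
        g[i] = (4.0 * lam[i] - 1.0) * dlam[i]
    for k, (a, b) in enumerate(_TET_EDGES):
        g[4 + k] = 4.0 * (lam[a] * dlam[b] + lam[b] * dlam[a])
    return g


class P2Space3D:
    """Scalar P2 space over a whole TetMesh3D."""

    def __init__(self, mesh: TetMesh3D, quad_degree: int = 4):
        mesh.build_p2()
        self.mesh = mesh
        self.conn = mesh.tet_p2()
        self.ndof = mesh.n_p2
        self.coords = mesh.p2_coords
        pts, w = tet_rule(quad_degree)
        lam = np.column_stack([1.0 - pts.sum(axis=1), pts])
        self._N = np.array([_p2_shape3(l) for l in lam])       # (Q, 10)
        self._Gref = np.array([_p2_grad3(l) for l in lam])     # (Q, 10, 3)
        self._N1 = lam                                          # (Q, 4)
        self._wref = w
        self._geom = None

    @property
    def nq(self) -> int:
        return len(self._wref)

    def _geometry(self):
        if self._geom is None:
            v = self.mesh.verts
            t = self.conn[:, :4]
            J = np.stack([v[t[:, i + 1]] - v[t[:, 0]] for i in range(3)],
                         axis=2)                                # (T, 3, 3)
            det = np.linalg.det(J)
            invT = np.linalg.inv(J).transpose(0, 2, 1)
            self._geom = (np.abs(det), invT)
        return self._geom

    def _grad_at(self, q: int) -> np.ndarray:
        """Physical gradients at quadrature point q: (T, 10, 3)."""
        _, invT = self._geometry()
        return np.einsum("tij,nj->tni", invT, self._Gref[q])

    # -- volume kernels ----------------------------------------------------

    def stiffness(self, coeff: float = 1.0) -> sp.csr_matrix:
        det, _ = self._geometry()
        T = len(self.conn)
        ke = np.zeros((T, 10, 10))
        for q in range(self.nq):
            G = self._grad_at(q)
            w = coeff * self._wref[q] * det
            ke += w[:, None, None] * np.einsum("tid,tjd->tij", G, G)
        return _scatter(ke, self.conn, self.conn, (self.ndof, self.ndof))

    def mass(self, coeff: float = 1.0) -> sp.csr_matrix:
        det, _ = self._geometry()
        base = np.einsum("q,qi,qj->ij", self._wref, self._N, self._N)
        ke = coeff * det[:, None, None] * base[None, :, :]
        return _scatter(ke, self.conn, self.conn, (self.ndof, self.ndof))

    def load_const(self, c: float = 1.0) -> np.ndarray:
        det, _ = self._geometry()
        base = np.einsum("q,qi->i", self._wref, self._N)
        fe = c * det[:, None] * base[None, :]
        out = np.zeros(self.ndof)
        np.add.at(out, self.conn.ravel(), fe.ravel())
        return out

    def integrate(self, vals: np.ndarray) -> float:
        det, _ = self._geometry()
        base = np.einsum("q,qi->i", self._wref, self._N)
        return float(np.sum(det[:, None] * base[None, :] * vals[self.conn]))

    def integrate_grad(self, vals: np.ndarray, comp: int) -> float:
        """∫ du/dx_comp over the mesh."""
        det, _ = self._geometry()
        total = 0.0
        for q in range(self.nq):
            G = self._grad_at(q)[..., comp]
            du = np.einsum("ti,ti->t", G, vals[self.conn])
            total += float(np.sum(self._wref[q] * det * du))
        return total

    def mean(self, vals: np.ndarray) -> float:
        return self.integrate(vals) / self.mesh.total_volume()

    # -- face helpers --------------------------------------------------------

    def face_data(self, tri: np.ndarray, degree: int = 4):
        """Quadrature on straight boundary triangles.

        Returns (fconn (F,6), N (Q,6), weights (F,Q), normals (F,3)).
        Triangles must be outward oriented (as from boundary_faces).
        """
        mesh = self.mesh
        fconn = mesh.face_p2(tri)
        v = mesh.verts
        e1 = v[tri[:, 1]] - v[tri[:, 0]]
        e2 = v[tri[:, 2]] - v[tri[:, 0]]
        nvec = np.cross(e1, e2)
        area2 = np.linalg.norm(nvec, axis=1)
        normals = nvec / area2[:, None]
        pts, w = tri_rule(degree)
        lam = np.column_stack([1.0 - pts.sum(axis=1), pts])    # (Q, 3)
        # face P2 shape functions: verts lam(2lam-1); edge mids (01),(12),(20)
        N = np.empty((len(lam), 6))
        N[:, :3] = lam * (2.0 * lam - 1.0)
        N[:, 3] = 4.0 * lam[:, 0] * lam[:, 1]
        N[:, 4] = 4.0 * lam[:, 1] * lam[:, 2]
        N[:, 5] = 4.0 * lam[:, 2] * lam[:, 0]
        # tri_rule weights sum to 1/2; |e1 x e2| is twice the triangle area
        weights = np.outer(area2, w)
        return fconn, N, weights, normals

    def face_scalar_load(self, tri: np.ndarray, g_per_face: np.ndarray
                         ) -> np.ndarray:
        """RHS ∫ g q dS with a constant value per face."""
        fconn, N, w, _ = self.face_data(tri)
        fe = np.einsum("fq,qi->fi", w * np.asarray(g_per_face)[:, None], N)
        out = np.zeros(self.ndof)
        np.add.at(out, fconn.ravel(), fe.ravel())
        return out

    def face_normal_penalty(self, tri: np.ndarray, coeff: float
                            ) -> sp.csr_matrix:
        """(3n x 3n) matrix coeff*∫ (u·n)(v·n) dS on the vector layout."""
        fconn, N, w, nrm = self.face_data(tri)
        ke = np.einsum("fq,qi,qj->fij", w, N, N)
        n = self.ndof
        rows, cols, vals = [], [], []
        for a in range(3):
            for b in range(3):
                fac = nrm[:, a] * nrm[:, b]
                rows.append((np.repeat(fconn, 6, axis=1) + a * n).ravel())
                cols.append((np.tile(fconn, (1, 6)) + b * n).ravel())
                vals.append((coeff * ke * fac[:, None, None]).ravel())
        return sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(3 * n, 3 * n)).tocsr()

    def face_vector_mass(self, tri: np.ndarray, coeff: float) -> sp.csr_matrix:
        """(3n x 3n) matrix coeff*∫ u·v dS (component-wise)."""
        fconn, N, w, _ = self.face_data(tri)
        ke = coeff * np.einsum("fq,qi,qj->fij", w, N, N)
        n = self.ndof
        rows, cols, vals = [], [], []
        for a in range(3):
            rows.append((np.repeat(fconn, 6, axis=1) + a * n).ravel())
            cols.append((np.tile(fconn, (1, 6)) + a * n).ravel())
            vals.append(ke.ravel())
        return sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(3 * n, 3 * n)).tocsr()

    def divergence_residual(self, u: np.ndarray) -> float:
        """L2 norm of div(u) for a 3-component velocity vector."""
        det, _ = self._geometry()
        n = self.ndof
        total = 0.0
        for q in range(self.nq):
            G = self._grad_at(q)
            div = np.zeros(len(self.conn))
            for comp in range(3):
                div += np.einsum("ti,ti->t",
                                 G[..., comp],
                                 u[comp * n + self.conn])
            total += float(np.sum(self._wref[q] * det * div ** 2))
        return float(np.sqrt(total))


class P1Space3D:
    """Scalar P1 (vertex) space over a TetMesh3D, matched to a P2Space3D."""

    def __init__(self, p2: P2Space3D):
        self.p2 = p2
        self.conn = p2.conn[:, :4]
        self.ndof = p2.mesh.n_verts

    def stiffness(self, coeff: float = 1.0) -> sp.csr_matrix:
        """P1 stiffness matrix (used as a pressure-Schur preconditioner)."""
        p2 = self.p2
        det, invT = p2._geometry()
        G1 = np.array([[-1.0, -1.0, -1.0],
                       [1.0, 0.0, 0.0],
                       [0.0, 1.0, 0.0],
                       [0.0, 0.0, 1.0]])
        Gp = np.einsum("tij,nj->tni", invT, G1)
        ke = coeff * np.einsum("t,tid,tjd->tij", det / 6.0, Gp, Gp)
        return _scatter(ke, self.conn, self.conn, (self.ndof, self.ndof))

    def lumped_mass_diag(self) -> np.ndarray:
        det, _ = self.p2._geometry()
        out = np.zeros(self.ndof)
        np.add.at(out, self.conn.ravel(), np.repeat(det / 24.0, 4))
        return out

    def divergence(self) -> sp.csr_matrix:
        """B with B[q, v] = ∫ q div(v), v on the 3-component P2 layout."""
        p2 = self.p2
        det, _ = p2._geometry()
        T = len(self.conn)
        n_u = p2.ndof
        rows, cols, vals = [], [], []
        for comp in range(3):
            be = np.zeros((T, 4, 10))
            for q in range(p2.nq):
                G = p2._grad_at(q)[..., comp]
                w = p2._wref[q] * det
                be += w[:, None, None] * np.einsum(
                    "i,tj->tij", p2._N1[q], G)
            rows.append(np.repeat(self.conn, 10, axis=1).ravel())
            cols.append((np.tile(p2.conn, (1, 4)) + comp * n_u).ravel())
            vals.append(be.ravel())
        return sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ndof, 3 * n_u)).tocsr()


def _scatter(ke, rows_conn, cols_conn, shape) -> sp.csr_matrix:
    T, ni, nj = ke.shape
    rows = np.repeat(rows_conn, nj, axis=1).ravel()
    cols = np.tile(cols_conn, (1, ni)).ravel()
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=shape).tocsr()
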