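"""Tetrahedral meshes for the microscale cell problems.

Meshes are built from graded tensor-product hexahedral grids split into six
Kuhn tetrahedra per cell (a conforming subdivision on stretched grids).
Vertices close to an implicit surface are projected onto it ("warp"), after
which tetrahedra are classified by the sign of the level set at their
centroid ("filter").  The result is a pair of body-fitted straight-sided
meshes sharing the interface triangulation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np

__all__ = ["TetMesh3D", "tensor_tet_grid", "warp_to_surface", "split_by_levelset"]

# six Kuhn tetrahedra of the unit hex, as corner indices of the
# (i,j,k)-ordered 8 corners: corner id = 4*dz + 2*dy + dx
_KUHN = np.array([
    [0, 1, 3, 7],
    [0, 1, 5, 7],
    [0, 2, 3, 7],
    [0, 2, 6, 7],
    [0, 4, 5, 7],
    [0, 4, 6, 7],
], dtype=np.int64)

# faces of a tet (v0..v3) ordered with outward normals
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]],
                      dtype=np.int64)

# P2 edge order: nodes 4..9 are midpoints of these vertex pairs
_TET_EDGES = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]],
                      dtype=np.int64)


@dataclass
class TetMesh3D:
    """Straight-sided tetrahedral mesh with tagged boundary triangles."""

    verts: np.ndarray                      # (N, 3)
    tets: np.ndarray                       # (T, 4)
    faces: Dict[str, np.ndarray] = field(default_factory=dict)  # tag -> (F, 3)

    _p2_built: bool = False
    edges: Optional[np.ndarray] = None
    tet_edges: Optional[np.ndarray] = None
    p2_coords: Optional[np.ndarray] = None

    def __post_init__(self):
        self.verts = np.asarray(self.verts, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        vol = self.volumes()
        neg = vol < 0
        if np.any(neg):
            self.tets[neg, 2], self.tets[neg, 3] = (
                self.tets[neg, 3].copy(), self.tets[neg, 2].copy())
        if np.any(np.abs(vol) <= 0.0):
            raise ValueError("mesh contains degenerate tetrahedra")

    def volumes(self) -> np.ndarray:
        v = self.verts
        t = self.tets
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        c = v[t[:, 3]] - v[t[:, 0]]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def total_volume(self) -> float:
        return float(self.volumes().sum())

    def build_p2(self) -> None:
        if self._p2_built:
            return
        t = self.tets
        raw = np.concatenate([t[:, pair] for pair in _TET_EDGES])
        raw_sorted = np.sort(raw, axis=1)
        self.edges, inv = np.unique(raw_sorted, axis=0, return_inverse=True)
        self.tet_edges = inv.reshape(6, len(t)).T
        mids = 0.5 * (self.verts[self.edges[:, 0]] + self.verts[self.edges[:, 1]])
        self.p2_coords = np.vstack([self.verts, mids])
        self._p2_built = True

    @property
    def n_verts(self) -> int:
        return len(self.verts)

    @property
    def n_p2(self) -> int:
        self.build_p2()
        return len(self.p2_coords)

    def tet_p2(self) -> np.ndarray:
        self.build_p2()
        return np.hstack([self.tets, self.tet_edges + self.n_verts])

    def face_p2(self, tri: np.ndarray) -> np.ndarray:
        """(F, 6) P2 connectivity of boundary triangles: 3 vertices + the
        midside node of edges (0,1), (1,2), (2,0)."""
        self.build_p2()
        out = np.empty((len(tri), 6), dtype=np.int64)
        out[:, :3] = tri
        for k, (a, b) in enumerate(((0, 1), (1, 2), (2, 0))):
            key = np.sort(tri[:, [a, b]], axis=1)
            out[:, 3 + k] = self._edge_index(key) + self.n_verts
        return out

    def _edge_index(self, key: np.ndarray) -> np.ndarray:
        e = self.edges
        m = self.n_verts + 1
        tab = e[:, 0] * m + e[:, 1]
        order = np.argsort(tab)
        pos = np.searchsorted(tab[order], key[:, 0] * m + key[:, 1])
        idx = order[pos]
        if not np.all((e[idx] == key).all(axis=1)):
            raise KeyError("face edge not present in mesh")
        return idx

    def boundary_faces(self) -> np.ndarray:
        """All faces belonging to exactly one tet, outward oriented."""
        t = self.tets
        tri = np.concatenate([t[:, f] for f in _TET_FACES])
        key = np.sort(tri, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                                   return_counts=True)
        return tri[counts[inv] == 1]


def tensor_tet_grid(xs: np.ndarray, ys: np.ndarray, zs: np.ndarray
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Vertices and Kuhn tets of the tensor grid xs x ys x zs."""
    xs, ys, zs = (np.asarray(a, dtype=float) for a in (xs, ys, zs))
    nx, ny, nz = len(xs), len(ys), len(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j, k):
        return (i * ny + j) * nz + k

    i, j, k = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1),
                          np.arange(nz - 1), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corners = np.stack([vid(i + dx, j + dy, k + dz)
                        for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)],
                       axis=1)                      # (C, 8) in _KUHN order
    tets = corners[:, _KUHN].reshape(-1, 4)
    return verts, tets


def warp_to_surface(verts: np.ndarray, sdf: Callable, project: Callable,
                    h_local: np.ndarray, frac: float = 0.35) -> np.ndarray:
    """Move vertices within frac*h of the zero level set onto it.

    `project(points)` must return the closest-point projection onto the
    surface; moves larger than 0.45*h are suppressed to protect element
    quality.
    """
    phi = sdf(verts)
    near = np.abs(phi) < frac * h_local
    out = verts.copy()
    if not np.any(near):
        return out
    proj = project(verts[near])
    move = np.linalg.norm(proj - verts[near], axis=1)
    ok = move <= 0.45 * h_local[near]
    idx = np.flatnonzero(near)[ok]
    out[idx] = proj[ok]
    return out


def split_by_levelset(verts: np.ndarray, tets: np.ndarray, sdf: Callable
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Classify tets by the level-set sign at their centroid.

    Returns (tets_outside, tets_inside) for phi > 0 / phi <= 0.
    """
    cent = verts[tets].mean(axis=1)
    phi = sdf(cent)
    return tets[phi > 0.0], tets[phi <= 0.0]


def compact_submesh(verts: np.ndarray, tets: np.ndarray
                    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop unused vertices; returns (verts, tets, old_vertex_ids)."""
    used = np.unique(tets)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return verts[used], remap[tets], used
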