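"""Tagged triangle meshes in the meridian (r, z) plane with P2 support."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

__all__ = ["TriMesh2D", "merge_tri_meshes"]


@dataclass
class TriMesh2D:
    """A conforming triangle mesh with subdomain and boundary-facet tags.

    Attributes
    ----------
    verts : (N, 2) float array of vertex coordinates (r, z)
    tris : (T, 3) int array, counter-clockwise vertex triples
    tri_tags : (T,) int array of subdomain labels
    facets : mapping tag -> (F, 2) int array of boundary/interface edges,
        ordered so the *reference* subdomain lies on the left of v0->v1
        (outward normal of that subdomain is then (t_z, -t_r)/|t|).
    """

    verts: np.ndarray
    tris: np.ndarray
    tri_tags: np.ndarray
    facets: Dict[str, np.ndarray] = field(default_factory=dict)

    # P2 data, built lazily
    _p2_built: bool = False
    edges: Optional[np.ndarray] = None          # (E, 2) sorted vertex pairs
    tri_edges: Optional[np.ndarray] = None      # (T, 3) edge index per local edge
    p2_coords: Optional[np.ndarray] = None      # (N + E, 2)

    def __post_init__(self):
        self.verts = np.asarray(self.verts, dtype=float)
        self.tris = np.asarray(self.tris, dtype=np.int64)
        self.tri_tags = np.asarray(self.tri_tags, dtype=np.int64)
        self._orient_ccw()

    def _orient_ccw(self) -> None:
        p = self.verts
        t = self.tris
        a = p[t[:, 1]] - p[t[:, 0]]
        b = p[t[:, 2]] - p[t[:, 0]]
        det = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        flip = det < 0
        if np.any(flip):
            self.tris[flip, 1], self.tris[flip, 2] = (
                self.tris[flip, 2].copy(), self.tris[flip, 1].copy())
        det = np.abs(det)
        if np.any(det <= 0):
            raise ValueError("mesh contains degenerate triangles")

    # -- P2 ---------------------------------------------------------------

    def build_p2(self) -> None:
        """Enumerate unique edges and create midside nodes.

        Local P2 node order per triangle: vertices 0,1,2 then midside nodes
        opposite each vertex: 3=mid(1,2), 4=mid(2,0), 5=mid(0,1).
        """
        if self._p2_built:
            return
        t = self.tris
        # local edge e_i is opposite vertex i
        raw = np.concatenate([t[:, [1, 2]], t[:, [2, 0]], t[:, [0, 1]]])
        raw_sorted = np.sort(raw, axis=1)
        self.edges, inv = np.unique(raw_sorted, axis=0, return_inverse=True)
        T = len(t)
        self.tri_edges = inv.reshape(3, T).T
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

    def tri_p2(self) -> np.ndarray:
        """(T, 6) global P2 connectivity."""
        self.build_p2()
        return np.hstack([self.tris, self.tri_edges + self.n_verts])

    def facet_p2(self, tag: str) -> np.ndarray:
        """(F, 3) P2 connectivity of a facet set: v0, v1, midside."""
        self.build_p2()
        f = self.facets[tag]
        key = np.sort(f, axis=1)
        # locate edge indices by searchsorted on the lexicographically
        # sorted unique edge table
        order = np.lexsort((self.edges[:, 1], self.edges[:, 0]))
        tab = self.edges[order]
        pos = np.searchsorted(
            tab[:, 0] * (self.n_verts + 1) + tab[:, 1],
            key[:, 0] * (self.n_verts + 1) + key[:, 1],
        )
        eidx = order[pos]
        if not np.all((self.edges[eidx] == key).all(axis=1)):
            raise KeyError(f"facet set {tag!r} contains edges not in the mesh")
        return np.column_stack([f, eidx + self.n_verts])

    def subdomain_tris(self, tag: int) -> np.ndarray:
        return self.tris[self.tri_tags == tag]

    def facet_lengths(self, tag: str) -> np.ndarray:
        f = self.facets[tag]
        d = self.verts[f[:, 1]] - self.verts[f[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    def facet_normals(self, tag: str) -> np.ndarray:
        """Unit outward normals of the reference subdomain, per facet."""
        f = self.facets[tag]
        d = self.verts[f[:, 1]] - self.verts[f[:, 0]]
        n = np.column_stack([d[:, 1], -d[:, 0]])
        return n / np.linalg.norm(n, axis=1)[:, None]


def merge_tri_meshes(mesh_a: TriMesh2D, mesh_b: TriMesh2D,
                     tol: float = 1e-12) -> TriMesh2D:
    """Merge two meshes, gluing vertices that coincide within `tol`.

    Facet tag dictionaries are merged; tags present in both are concatenated.
    Subdomain tags are kept as-is (callers choose distinct labels).
    """
    pa, pb = mesh_a.verts, mesh_b.verts
    allv = np.vstack([pa, pb])
    # quantize for exact matching of identically computed coordinates
    key = np.round(allv / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True,
                                  return_inverse=True)
    new_verts = allv[first]
    remap = inverse
    tris = np.vstack([remap[mesh_a.tris], remap[mesh_b.tris + len(pa)]])
    tags = np.concatenate([mesh_a.tri_tags, mesh_b.tri_tags])
    facets: Dict[str, np.ndarray] = {}
    for tag, f in mesh_a.facets.items():
        facets[tag] = remap[f]
    for tag, f in mesh_b.facets.items():
        fb = remap[f + len(pa)]
        facets[tag] = np.vstack([facets[tag], fb]) if tag in facets else fb
    return TriMesh2D(new_verts, tris, tags, facets)
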