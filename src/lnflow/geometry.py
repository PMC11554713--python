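"""Macroscale lymph-node geometry and its axisymmetric meridian mesh.

The node is a body of revolution: a sphere (radius R) or an oblate spheroid
(semiaxes a >= b) whose outer surface is the capsule.  The lymphoid
compartment (LC) is the inner body obtained by offsetting the capsule inward
by the subcapsular sinus thickness h along the local normal; the thin shell
between the two surfaces is the SCS free-fluid channel.  Afferent/efferent
lymphatic vessels are modelled as flat circular apertures of radius R_LV
truncating the capsule at the two poles.

The flow problem is rotationally invariant about the polar axis, so the
geometry is meshed in the meridian (r, z) half-plane: a structured
quadrilateral-split shell for the SCS (several element layers across the
gap) and an unstructured Delaunay triangulation for the LC interior, glued
conformally along the interface Gamma_M.

Subdomain labels: 0 = SCS, 1 = LC.  Facet tags: 'inlet', 'outlet',
'capsule', 'axis_scs', 'axis_lc', 'interface' (ordered from the inlet pole,
with the SCS on the left of each interface facet so the facet normals point
from the SCS into the LC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .fem.mesh2d import TriMesh2D, merge_tri_meshes
from .params import GeometrySpec

__all__ = ["NodeGeometry", "lc_profile", "build_node_mesh",
           "SCS_TAG", "LC_TAG"]

SCS_TAG = 0
LC_TAG = 1

_MACRO_RESOLUTIONS = {
    # n_theta: meridian subdivisions of the capsule arc;
    # n_layers: element layers across the SCS gap;
    # lc_growth: ring-to-ring size growth into the LC interior
    "coarse": dict(n_theta=96, n_layers=3, lc_growth=1.35),
    "medium": dict(n_theta=192, n_layers=4, lc_growth=1.25),
    "fine": dict(n_theta=320, n_layers=5, lc_growth=1.18),
}


class OffsetSelfIntersectionError(ValueError):
    """The inward offset exceeds the minimum radius of curvature."""


@dataclass
class NodeGeometry:
    """Node shape: capsule surface, LC offset surface, pole apertures."""

    shape: str = "sphere"     # 'sphere' | 'oblate'
    R: float = 0.49           # sphere radius (mm)
    a: float = 0.5            # spheroid equatorial semiaxis (mm)
    b: float = 0.35           # spheroid polar semiaxis (mm)
    h: float = 0.01           # SCS thickness (mm)
    R_LV: float = 0.04        # aperture radius (mm)

    def __post_init__(self):
        if self.shape == "sphere":
            self.a = self.b = self.R
        elif self.shape != "oblate":
            raise ValueError(f"unknown shape {self.shape!r}")
        # inner offset exists iff h < minimum radius of curvature = b^2/a
        if self.h >= min(self.b, self.b**2 / self.a):
            raise OffsetSelfIntersectionError(
                f"SCS thickness h={self.h} exceeds the minimum curvature "
                f"radius {self.b**2 / self.a:.4g} of the capsule")
        if self.R_LV >= self.a:
            raise ValueError("aperture radius must be smaller than the node")

    @classmethod
    def from_spec(cls, spec: GeometrySpec) -> "NodeGeometry":
        return cls(shape=spec.shape, R=spec.R, a=spec.a, b=spec.b,
                   h=spec.h, R_LV=spec.R_LV)

    # the meridian curves are parametrized by the ellipse parameter
    # theta in [0, pi], measured from the inlet (+z) pole:
    # capsule point = (a sin th, b cos th)

    def capsule_point(self, theta):
        theta = np.asarray(theta, dtype=float)
        return np.stack([self.a * np.sin(theta), self.b * np.cos(theta)],
                        axis=-1)

    def lc_point(self, theta):
        """Inner (LC) surface point: capsule offset inward by h along the
        outward unit normal of the ellipse."""
        theta = np.asarray(theta, dtype=float)
        s, c = np.sin(theta), np.cos(theta)
        nr = s / self.a
        nz = c / self.b
        nn = np.sqrt(nr**2 + nz**2)
        return np.stack([self.a * s - self.h * nr / nn,
                         self.b * c - self.h * nz / nn], axis=-1)

    @property
    def theta_rim(self) -> float:
        """Parameter of the aperture rim (capsule truncated at r = R_LV)."""
        return math.asin(self.R_LV / self.a)

    @property
    def z_rim(self) -> float:
        return self.b * math.cos(self.theta_rim)

    def outer_point(self, theta):
        """Outer boundary of the SCS in the meridian plane: the capsule arc
        for theta beyond the rim, the flat aperture disk at |z| = z_rim
        near the poles."""
        theta = np.asarray(theta, dtype=float)
        p = self.capsule_point(theta)
        tr = self.theta_rim
        top = theta < tr
        bot = theta > math.pi - tr
        p = np.array(p, dtype=float)
        p[..., 1] = np.where(top, self.z_rim, p[..., 1])
        p[..., 1] = np.where(bot, -self.z_rim, p[..., 1])
        return p

    def lc_volume(self, n: int = 20001) -> float:
        """Volume of revolution of the LC meridian section (Pappus)."""
        th = np.linspace(0.0, math.pi, n)
        p = self.lc_point(th)
        x, z = p[:, 0], p[:, 1]
        return float(-math.pi * np.trapezoid(x**2, z))

    def capsule_volume(self, n: int = 20001) -> float:
        th = np.linspace(0.0, math.pi, n)
        p = self.capsule_point(th)
        return float(-math.pi * np.trapezoid(p[:, 0]**2, p[:, 1]))


def lc_profile(geom: NodeGeometry, theta):
    """LC boundary point at ellipse parameter theta (equatorial convention).

    The capsule meridian is (x, z) = (a cos(theta), b sin(theta)) and the LC
    point is its inward offset by h along the unit normal
    (cos(theta)/a^2, sin(theta)/b^2)/|...|.  The sphere is the special case
    a = b = R, for which the offset is radial and the LC boundary is the
    sphere of radius R - h.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < -1e-12) or np.any(theta > math.pi + 1e-12):
        raise ValueError("theta must lie in [0, pi]")
    a, b, h = geom.a, geom.b, geom.h
    c, s = np.cos(theta), np.sin(theta)
    nx = c / a**2
    nz = s / b**2
    nn = np.sqrt(nx**2 + nz**2)
    return np.stack([a * c - h * nx / nn, b * s - h * nz / nn], axis=-1)


def _theta_grid(geom: NodeGeometry, n_theta: int) -> np.ndarray:
    """Meridian parameter grid containing the rim parameters exactly.

    The aperture segments are geometrically clustered toward the rim so
    that the no-slip rim vertex (tie-break: the rim belongs to the capsule
    wall) removes only a negligible fraction of the prescribed inlet flux.
    """
    tr = geom.theta_rim
    if tr == 0.0:                      # closed capsule, no apertures
        return np.linspace(0.0, math.pi, n_theta + 1)
    n_pole = max(8, n_theta // 16)
    ratio = 0.5
    w = ratio ** np.arange(n_pole)
    s = np.concatenate([[0.0], np.cumsum(w)]) / np.sum(w)
    top = tr * s                       # clustered toward theta = tr
    n_mid = n_theta
    mid = np.linspace(tr, math.pi - tr, n_mid + 1)
    bot = math.pi - (tr * s)[::-1]     # clustered toward pi - tr
    return np.concatenate([top[:-1], mid[:-1], bot])


def _structured_shell(geom: NodeGeometry, thetas: np.ndarray,
                      n_layers: int):
    """Structured SCS shell mesh between the LC curve and the outer boundary.

    Returns (verts, tris, facet dict with index pairs local to `verts`,
    inner-boundary vertex ids ordered by theta).
    """
    nt = len(thetas)
    nl = n_layers + 1
    inner = geom.lc_point(thetas)                 # (nt, 2)
    outer = geom.outer_point(thetas)
    t = np.linspace(0.0, 1.0, nl)
    pts = (inner[:, None, :] * (1.0 - t[None, :, None])
           + outer[:, None, :] * t[None, :, None])      # (nt, nl, 2)
    pts[np.abs(pts[..., 0]) < 1e-14, 0] = 0.0
    verts = pts.reshape(-1, 2)

    def vid(i, j):
        return i * nl + j

    tris = []
    for i in range(nt - 1):
        for j in range(n_layers):
            v00, v10 = vid(i, j), vid(i + 1, j)
            v01, v11 = vid(i, j + 1), vid(i + 1, j + 1)
            tris.append([v00, v10, v11])
            tris.append([v00, v11, v01])
    tris = np.asarray(tris, dtype=np.int64)

    tr = geom.theta_rim
    facets = {"interface": [], "inlet": [], "outlet": [], "capsule": [],
              "axis_scs": []}
    # facet normals are (t_z, -t_r) for the edge direction t = v1 - v0
    # (see TriMesh2D.facet_normals), i.e. the domain must lie on the LEFT
    # of v0 -> v1 for the normal to point outward.
    # interface: inner row walked with increasing theta; the SCS (outside
    # the LC curve) is on the left, so the normal points into the LC.
    for i in range(nt - 1):
        facets["interface"].append([vid(i, 0), vid(i + 1, 0)])
    # outer row walked with decreasing theta: SCS on the left, normal
    # outward (through capsule/apertures)
    for i in range(nt - 1):
        mid = 0.5 * (thetas[i] + thetas[i + 1])
        if mid < tr:
            tag = "inlet"
        elif mid > math.pi - tr:
            tag = "outlet"
        else:
            tag = "capsule"
        facets[tag].append([vid(i + 1, n_layers), vid(i, n_layers)])
    # axis columns at theta = 0 (top) and theta = pi (bottom)
    for j in range(n_layers):
        facets["axis_scs"].append([vid(0, j + 1), vid(0, j)])
        facets["axis_scs"].append([vid(nt - 1, j), vid(nt - 1, j + 1)])
    facets = {k: np.asarray(v, dtype=np.int64) for k, v in facets.items()}
    inner_ids = np.array([vid(i, 0) for i in range(nt)], dtype=np.int64)
    return verts, tris, facets, inner_ids


def _lc_interior_points(geom: NodeGeometry, thetas: np.ndarray,
                        growth: float):
    """Graded interior point cloud for the LC: shrunken copies of the
    boundary curve with angular thinning, plus axis points."""
    bnd = geom.lc_point(thetas)
    arc = np.linalg.norm(np.diff(bnd, axis=0), axis=1)
    h0 = float(np.median(arc))            # boundary spacing
    pts = []
    lam = 1.0
    h = h0
    scale = min(geom.b - geom.h, geom.b**2 / geom.a)   # radial depth scale
    while lam > 0.05:
        lam = lam - h / scale
        if lam <= 0.05:
            break
        h = min(h * growth, 0.35 * scale)
        step = max(1, int(round((h / h0) / lam)))
        idx = np.arange(0, len(thetas), step)
        ring = lam * geom.lc_point(thetas[idx])
        # drop ring points hugging the axis; axis handled separately
        keep = ring[:, 0] > 0.4 * h * lam
        pts.append(ring[keep])
        n_ax = max(2, int(round(2.0 * lam * geom.b / h)))
        zax = np.linspace(-lam * (geom.b - geom.h), lam * (geom.b - geom.h),
                          n_ax)
        pts.append(np.column_stack([np.zeros(n_ax), zax]))
    pts.append(np.array([[0.0, 0.0]]))
    allpts = np.vstack(pts)
    # dedupe
    key = np.round(allpts / 1e-9).astype(np.int64)
    _, first = np.unique(key, axis=0, return_index=True)
    return allpts[np.sort(first)]


def _lc_mesh(geom: NodeGeometry, boundary_pts: np.ndarray,
             thetas: np.ndarray, growth: float):
    """Delaunay mesh of the LC (convex meridian section)."""
    interior = _lc_interior_points(geom, thetas, growth)
    pts = np.vstack([boundary_pts, interior])
    dt = Delaunay(pts)
    tris = dt.simplices
    # remove zero-area slivers on the boundary (collinear points)
    p = pts
    a = p[tris[:, 1]] - p[tris[:, 0]]
    b = p[tris[:, 2]] - p[tris[:, 0]]
    det = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    area_tol = 1e-12 * float(np.max(np.abs(det)))
    tris = tris[np.abs(det) > area_tol]
    facets = {}
    nb = len(boundary_pts)
    facets["interface_lc"] = np.column_stack(
        [np.arange(nb - 1), np.arange(1, nb)])
    # axis facets: hull edges with r = 0 (informational; natural BC)
    return pts, tris, facets


def build_node_mesh(geom: NodeGeometry, resolution: str = "medium"
                    ) -> TriMesh2D:
    """Tagged conforming meridian mesh of the SCS shell and the LC."""
    opts = _MACRO_RESOLUTIONS[resolution]
    thetas = _theta_grid(geom, opts["n_theta"])
    s_verts, s_tris, s_facets, inner_ids = _structured_shell(
        geom, thetas, opts["n_layers"])
    scs = TriMesh2D(s_verts, s_tris, np.full(len(s_tris), SCS_TAG),
                    s_facets)
    boundary_pts = s_verts[inner_ids]
    l_verts, l_tris, l_facets = _lc_mesh(geom, boundary_pts, thetas,
                                         opts["lc_growth"])
    lc = TriMesh2D(l_verts, l_tris, np.full(len(l_tris), LC_TAG), {})
    mesh = merge_tri_meshes(scs, lc)
    mesh.geom = geom
    mesh.resolution = resolution
    return mesh
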