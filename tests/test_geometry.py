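"""Node geometry: offset profiles, meshing, tags, revolved volumes."""

import math

import numpy as np
import pytest

from lnflow.geometry import (NodeGeometry, lc_profile, build_node_mesh,
                             OffsetSelfIntersectionError, SCS_TAG, LC_TAG)
from lnflow.fem.assemble2d import P2Space


def test_sphere_offset_is_radial():
    g = NodeGeometry(shape="sphere")
    for th in (0.1, 0.8, 2.0, 3.0):
        p = lc_profile(g, th)
        assert np.linalg.norm(p) == pytest.approx(0.48, rel=1e-12)


def test_oblate_offset_examples():
    g = NodeGeometry(shape="oblate")
    p0 = lc_profile(g, 0.0)             # equator: normal along x
    assert p0 == pytest.approx([0.49, 0.0], abs=1e-12)
    p1 = lc_profile(g, math.pi / 2)     # pole: normal along z
    assert p1 == pytest.approx([0.0, 0.34], abs=1e-12)


def test_offset_self_intersection_rejected():
    with pytest.raises(OffsetSelfIntersectionError):
        NodeGeometry(shape="oblate", a=0.5, b=0.1, h=0.05)


def test_revolved_volumes_match_closed_forms():
    gs = NodeGeometry(shape="sphere")
    assert gs.lc_volume() == pytest.approx(4 / 3 * math.pi * 0.48**3,
                                           rel=1e-8)
    go = NodeGeometry(shape="oblate")
    assert go.capsule_volume() == pytest.approx(
        4 / 3 * math.pi * 0.5**2 * 0.35, rel=1e-8)


@pytest.mark.parametrize("shape", ["sphere", "oblate"])
def test_mesh_volumes_and_tags(shape):
    geom = NodeGeometry(shape=shape)
    mesh = build_node_mesh(geom, "coarse")
    lc = P2Space(mesh, np.flatnonzero(mesh.tri_tags == LC_TAG))
    scs = P2Space(mesh, np.flatnonzero(mesh.tri_tags == SCS_TAG))
    assert lc.volume() == pytest.approx(geom.lc_volume(), rel=5e-3)
    # the SCS shell plus the LC fills the truncated capsule
    total = lc.volume() + scs.volume()
    assert total == pytest.approx(geom.capsule_volume(), rel=5e-3)
    for tag in ("inlet", "outlet", "capsule", "interface", "axis_scs"):
        assert len(mesh.facets[tag]) > 0
    # interface facets trace the LC boundary: all their nodes at the offset
    # surface
    iface = mesh.facets["interface"]
    pts = mesh.verts[np.unique(iface)]
    if shape == "sphere":
        assert np.allclose(np.linalg.norm(pts, axis=1), 0.48, atol=1e-9)


def test_interface_normals_point_into_lc(sphere_mesh_coarse):
    mesh = sphere_mesh_coarse
    f = mesh.facets["interface"]
    mids = 0.5 * (mesh.verts[f[:, 0]] + mesh.verts[f[:, 1]])
    n = mesh.facet_normals("interface")
    # pointing toward the node centre
    assert np.all(np.einsum("ij,ij->i", n, mids) < 0)


def test_outer_normals_point_outward(sphere_mesh_coarse):
    mesh = sphere_mesh_coarse
    for tag, direction in (("capsule", +1), ):
        f = mesh.facets[tag]
        mids = 0.5 * (mesh.verts[f[:, 0]] + mesh.verts[f[:, 1]])
        n = mesh.facet_normals(tag)
        assert np.all(direction * np.einsum("ij,ij->i", n, mids) > 0)
    n_in = mesh.facet_normals("inlet")
    assert np.all(n_in[:, 1] > 0.99)      # up through the top disk
    n_out = mesh.facet_normals("outlet")
    assert np.all(n_out[:, 1] < -0.99)


def test_closed_capsule_has_no_aperture():
    geom = NodeGeometry(shape="sphere", R_LV=0.0)
    mesh = build_node_mesh(geom, "coarse")
    assert len(mesh.facets["inlet"]) == 0
    assert len(mesh.facets["outlet"]) == 0
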