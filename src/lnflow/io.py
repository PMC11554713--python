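"""Serialization: Gmsh MSH v2.2 and VTU (ascii XML) writers, run manifests.

The writers cover exactly what the pipeline produces - tagged triangle
meshes of the meridian plane, tetrahedral cell meshes, and nodal fields -
in the plain-text flavours of the two formats so results can be inspected
in standard viewers.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Dict, Optional

import numpy as np

from .fem.mesh2d import TriMesh2D
from .fem.mesh3d import TetMesh3D

__all__ = ["write_msh2", "read_msh2", "write_vtu", "RunManifest"]


def _facet_tag_ids(mesh: TriMesh2D):
    return {name: i + 100 for i, name in enumerate(sorted(mesh.facets))}


def write_msh2(mesh: TriMesh2D, path) -> None:
    """Write a tagged meridian mesh as ascii Gmsh MSH 2.2.

    Subdomain labels become surface physical groups (id = label + 1);
    facet tags become line physical groups (ids from 100, listed in
    $PhysicalNames).
    """
    tags = _facet_tag_ids(mesh)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines.append("$PhysicalNames")
    names = [(1, tid, name) for name, tid in tags.items()]
    names += [(2, int(lbl) + 1, f"subdomain_{lbl}")
              for lbl in np.unique(mesh.tri_tags)]
    lines.append(str(len(names)))
    for dim, tid, name in names:
        lines.append(f'{dim} {tid} "{name}"')
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(len(mesh.verts)))
    for i, (x, y) in enumerate(mesh.verts, start=1):
        lines.append(f"{i} {x:.17g} {y:.17g} 0")
    lines.append("$EndNodes")
    lines.append("$Elements")
    n_elem = len(mesh.tris) + sum(len(f) for f in mesh.facets.values())
    lines.append(str(n_elem))
    eid = 1
    for name, fac in sorted(mesh.facets.items()):
        tid = tags[name]
        for a, b in fac:
            lines.append(f"{eid} 1 2 {tid} {tid} {a + 1} {b + 1}")
            eid += 1
    for t, lbl in zip(mesh.tris, mesh.tri_tags):
        tid = int(lbl) + 1
        lines.append(f"{eid} 2 2 {tid} {tid} {t[0] + 1} {t[1] + 1} {t[2] + 1}")
        eid += 1
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh2(path) -> TriMesh2D:
    """Read an ascii MSH 2.2 file produced by :func:`write_msh2`."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    it = iter(tokens)
    names: Dict[int, str] = {}
    verts = None
    tris, tri_tags = [], []
    facets: Dict[str, list] = {}
    line = next(it, None)
    while line is not None:
        if line.strip() == "$PhysicalNames":
            n = int(next(it))
            for _ in range(n):
                dim, tid, name = next(it).split(maxsplit=2)
                names[int(tid)] = name.strip('"')
            next(it)  # $End
        elif line.strip() == "$Nodes":
            n = int(next(it))
            verts = np.empty((n, 2))
            for _ in range(n):
                parts = next(it).split()
                verts[int(parts[0]) - 1] = (float(parts[1]), float(parts[2]))
            next(it)
        elif line.strip() == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                tid = int(parts[3])
                conn = [int(p) - 1 for p in parts[3 + ntags:]]
                if etype == 1:
                    facets.setdefault(names.get(tid, str(tid)), []).append(conn)
                elif etype == 2:
                    tris.append(conn)
                    name = names.get(tid, f"subdomain_{tid - 1}")
                    tri_tags.append(int(name.rsplit("_", 1)[1])
                                    if name.startswith("subdomain_") else tid - 1)
            next(it)
        line = next(it, None)
    facets_np = {k: np.asarray(v, dtype=np.int64) for k, v in facets.items()}
    return TriMesh2D(verts, np.asarray(tris, dtype=np.int64),
                     np.asarray(tri_tags, dtype=np.int64), facets_np)


def write_vtu(path, mesh, point_data: Optional[Dict[str, np.ndarray]] = None,
              cell_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Write a TriMesh2D or TetMesh3D with nodal/cell fields as ascii VTU.

    2D meshes are embedded in the z=0 plane.  Point data arrays are given on
    the mesh vertices; (n, 2) vectors are padded to three components.
    """
    if isinstance(mesh, TriMesh2D):
        pts3 = np.column_stack([mesh.verts, np.zeros(len(mesh.verts))])
        conn = mesh.tris
        vtk_type = 5
    elif isinstance(mesh, TetMesh3D):
        pts3 = mesh.verts
        conn = mesh.tets
        vtk_type = 10
    else:
        raise TypeError("unsupported mesh type")
    npts, ncell = len(pts3), len(conn)
    k = conn.shape[1]
    out = []
    out.append('<?xml version="1.0"?>')
    out.append('<VTKFile type="UnstructuredGrid" version="0.1" '
               'byte_order="LittleEndian">')
    out.append("<UnstructuredGrid>")
    out.append(f'<Piece NumberOfPoints="{npts}" NumberOfCells="{ncell}">')
    out.append("<Points>")
    out.append('<DataArray type="Float64" NumberOfComponents="3" '
               'format="ascii">')
    out.append("\n".join(" ".join(f"{v:.12g}" for v in p) for p in pts3))
    out.append("</DataArray></Points>")
    out.append("<Cells>")
    out.append('<DataArray type="Int64" Name="connectivity" format="ascii">')
    out.append("\n".join(" ".join(str(i) for i in c) for c in conn))
    out.append("</DataArray>")
    out.append('<DataArray type="Int64" Name="offsets" format="ascii">')
    out.append(" ".join(str(k * (i + 1)) for i in range(ncell)))
    out.append("</DataArray>")
    out.append('<DataArray type="UInt8" Name="types" format="ascii">')
    out.append(" ".join(str(vtk_type) for _ in range(ncell)))
    out.append("</DataArray></Cells>")

    def data_block(data, n_expected):
        blk = []
        for name, arr in (data or {}).items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                arr = arr[:, None]
            if arr.shape[0] != n_expected:
                raise ValueError(f"field {name!r} has wrong length")
            if arr.shape[1] == 2:
                arr = np.column_stack([arr, np.zeros(len(arr))])
            blk.append(f'<DataArray type="Float64" Name="{name}" '
                       f'NumberOfComponents="{arr.shape[1]}" format="ascii">')
            blk.append("\n".join(" ".join(f"{v:.12g}" for v in row)
                                 for row in arr))
            blk.append("</DataArray>")
        return blk

    out.append("<PointData>")
    out += data_block(point_data, npts)
    out.append("</PointData>")
    out.append("<CellData>")
    out += data_block(cell_data, ncell)
    out.append("</CellData>")
    out.append("</Piece></UnstructuredGrid></VTKFile>")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    command: str
    config: dict
    mesh_stats: Dict[str, float] = field(default_factory=dict)
    diagnostics: Dict[str, float] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)
    deterministic: bool = True   # no RNG anywhere in the pipeline
    created: str = ""

    def write(self, path) -> None:
        self.created = datetime.now(timezone.utc).isoformat()
        missing = [p for p in self.outputs.values() if not os.path.exists(p)]
        if missing:
            raise FileNotFoundError(f"manifest lists missing outputs: {missing}")
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
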