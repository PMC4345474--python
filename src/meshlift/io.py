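"""Plain-text serialization: Gmsh MSH 2.2, legacy VTK, and CSV field tables.

Boundary tags travel as Gmsh physical point groups (1 = mural,
2 = perivascular) and as VTK point data.  Refinement lineage is not
serialized — a written mesh reloads as a standalone level, so hierarchies
intended for the learning pipeline should be rebuilt in memory or paired
with an explicit nesting map (see :mod:`meshlift.external`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import INTERIOR, TriMesh
from .transport import ConcentrationField

__all__ = [
    "write_msh",
    "read_msh",
    "write_vtk",
    "write_field_csv",
    "read_field_csv",
]


def write_msh(mesh: TriMesh, path: str) -> None:
    """Write Gmsh MSH 2.2 ASCII: triangles plus tagged boundary points."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    for i, (x, y) in enumerate(mesh.node_coords, start=1):
        lines.append(f"{i} {x:.17g} {y:.17g} 0")
    lines.append("$EndNodes")
    tagged = np.flatnonzero(mesh.boundary_tag != INTERIOR)
    lines.append("$Elements")
    lines.append(str(mesh.n_elements + tagged.size))
    eid = 1
    for node in tagged:  # element type 15 = point, physical tag = boundary code
        lines.append(f"{eid} 15 2 {int(mesh.boundary_tag[node])} 0 {node + 1}")
        eid += 1
    for tri in mesh.elements:  # element type 2 = 3-node triangle
        lines.append(f"{eid} 2 2 0 0 {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}")
        eid += 1
    lines.append("$EndElements")
    Path(path).write_text("\n".join(lines) + "\n")


def read_msh(path: str) -> TriMesh:
    """Read a mesh written by :func:`write_msh` (MSH 2.2 ASCII subset)."""
    text = Path(path).read_text().splitlines()
    it = iter(text)
    coords = []
    tris = []
    tags = {}
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                coords.append((float(parts[1]), float(parts[2])))
        elif line.strip() == "$Elements":
            m = int(next(it))
            for _ in range(m):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                phys = int(parts[3]) if ntags >= 1 else 0
                conn = [int(v) - 1 for v in parts[3 + ntags:]]
                if etype == 15:
                    tags[conn[0]] = phys
                elif etype == 2:
                    tris.append(conn)
    coords = np.asarray(coords, dtype=float)
    boundary = np.zeros(len(coords), dtype=np.int8)
    for node, phys in tags.items():
        boundary[node] = phys
    return TriMesh(
        node_coords=coords,
        elements=np.asarray(tris, dtype=np.int64),
        boundary_tag=boundary,
        level=0,
    )


def write_vtk(mesh: TriMesh, path: str, point_data: dict | None = None) -> None:
    """Legacy ASCII VTK unstructured grid with boundary tags (and optional
    per-node scalar fields) as point data."""
    lines = [
        "# vtk DataFile Version 3.0",
        "meshlift mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for x, y in mesh.node_coords:
        lines.append(f"{x:.17g} {y:.17g} 0")
    m = mesh.n_elements
    lines.append(f"CELLS {m} {4 * m}")
    for tri in mesh.elements:
        lines.append(f"3 {tri[0]} {tri[1]} {tri[2]}")
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["5"] * m)  # VTK_TRIANGLE
    lines.append(f"POINT_DATA {mesh.n_nodes}")
    lines.append("SCALARS boundary_tag int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(t)) for t in mesh.boundary_tag)
    for name, vals in (point_data or {}).items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.17g}" for v in np.asarray(vals, dtype=float))
    Path(path).write_text("\n".join(lines) + "\n")


def write_field_csv(field: ConcentrationField, path: str) -> None:
    """CSV table (node_id, x, y, C, B) for one solved field."""
    df = pd.DataFrame(
        {
            "node_id": np.arange(field.mesh.n_nodes),
            "x": field.mesh.node_coords[:, 0],
            "y": field.mesh.node_coords[:, 1],
            "C": field.C,
            "B": field.B,
        }
    )
    df.to_csv(path, index=False)


def read_field_csv(mesh: TriMesh, path: str, atol: float = 1e-12) -> ConcentrationField:
    """Load a field table back onto a mesh, verifying node alignment."""
    df = pd.read_csv(path)
    coords = df[["x", "y"]].to_numpy()
    if coords.shape[0] != mesh.n_nodes or not np.allclose(
        coords, mesh.node_coords, atol=atol
    ):
        raise ValueError("field table does not align with the mesh nodes")
    return ConcentrationField(
        mesh=mesh, C=df["C"].to_numpy(), B=df["B"].to_numpy(), time=float("nan")
    )
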