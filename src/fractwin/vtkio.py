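"""Minimal VTK XML unstructured-grid (.vtu) writing and reading.

ASCII appended-free VTU with Float64/Int64 data arrays, covering exactly
what the pipeline exports: tet geometry (linear VTK cell type 10, quadratic
type 24), per-cell scalar fields (region, E, von Mises, octahedral shear
strain, volumetric strain, healing class) and per-node vector fields
(displacement). Files load in standard VTK readers; the bundled reader
round-trips everything this writer emits.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .meshing import TetMesh

__all__ = ["write_vtu", "read_vtu"]

_VTK_TET4 = 10
_VTK_TET10 = 24


def _data_array(name: str, arr: np.ndarray) -> str:
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        dtype = "Int64"
        body = " ".join(str(int(v)) for v in arr.ravel())
    else:
        dtype = "Float64"
        body = " ".join(f"{float(v):.17g}" for v in arr.ravel())
    ncomp = arr.shape[1] if arr.ndim == 2 else 1
    return (
        f'<DataArray type="{dtype}" Name="{name}" NumberOfComponents="{ncomp}" '
        f'format="ascii">\n{body}\n</DataArray>'
    )


def write_vtu(
    path: str | Path,
    mesh: TetMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the mesh and optional per-node / per-element fields.

    Field arrays must have one entry (row) per node or per element
    respectively; scalars may be 1-D, vectors (n, c).
    """
    point_data = point_data or {}
    cell_data = cell_data or {}
    for name, arr in point_data.items():
        if np.asarray(arr).shape[0] != mesh.n_nodes:
            raise ValueError(f"point field {name!r} has wrong length")
    for name, arr in cell_data.items():
        if np.asarray(arr).shape[0] != mesh.n_elements:
            raise ValueError(f"cell field {name!r} has wrong length")

    nn = mesh.elements.shape[1]
    ctype = _VTK_TET4 if nn == 4 else _VTK_TET10
    conn = mesh.elements.ravel()
    offsets = np.arange(1, mesh.n_elements + 1) * nn
    types = np.full(mesh.n_elements, ctype)

    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{mesh.n_elements}">',
        "<Points>",
        _data_array("Points", mesh.nodes),
        "</Points>",
        "<Cells>",
        _data_array("connectivity", conn),
        _data_array("offsets", offsets),
        _data_array("types", types),
        "</Cells>",
    ]
    parts.append("<PointData>")
    for name, arr in point_data.items():
        parts.append(_data_array(name, np.asarray(arr)))
    parts.append("</PointData>")
    parts.append("<CellData>")
    for name, arr in cell_data.items():
        parts.append(_data_array(name, np.asarray(arr)))
    parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts) + "\n")


def _parse_array(el: ET.Element) -> np.ndarray:
    dtype = float if el.attrib.get("type", "Float64").startswith("Float") else np.int64
    ncomp = int(el.attrib.get("NumberOfComponents", "1"))
    tokens = (el.text or "").split()
    arr = np.array(tokens, dtype=dtype) if tokens else np.empty(0, dtype=dtype)
    if ncomp > 1:
        arr = arr.reshape(-1, ncomp)
    return arr


def read_vtu(path: str | Path):
    """Read a file written by :func:`write_vtu`.

    Returns ``(mesh, point_data, cell_data)``; region labels are restored
    from the ``region`` cell field when present, else zero.
    """
    root = ET.parse(str(path)).getroot()
    piece = root.find("./UnstructuredGrid/Piece")
    if piece is None:
        raise ValueError("not an unstructured-grid VTU file")

    def arrays_in(tag: str) -> dict[str, np.ndarray]:
        sec = piece.find(tag)
        if sec is None:
            return {}
        return {el.attrib["Name"]: _parse_array(el) for el in sec.findall("DataArray")}

    points = arrays_in("Points")["Points"].reshape(-1, 3)
    cells = arrays_in("Cells")
    conn = cells["connectivity"].astype(np.int64)
    offsets = cells["offsets"].astype(np.int64)
    nn = int(offsets[0]) if offsets.size else 4
    elements = conn.reshape(-1, nn)
    point_data = arrays_in("PointData")
    cell_data = arrays_in("CellData")
    region = cell_data.get("region")
    if region is None:
        region = np.zeros(elements.shape[0], dtype=np.int64)
    mesh = TetMesh(points, elements, np.asarray(region, dtype=np.int64))
    return mesh, point_data, cell_data
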