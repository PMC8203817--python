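"""Minimal ASCII VTK XML PolyData (.vtp) and collection (.pvd) I/O.

Writes and reads triangulated surfaces with per-vertex scalar/vector
arrays in the plain-text VTK XML dialect, enough to exchange wall-shear
fields with ParaView-style tools.  Only ascii-encoded PolyData with
triangle cells is supported.
"""

from __future__ import annotations

from pathlib import Path
import xml.etree.ElementTree as ET

import numpy as np

from .mesh import SurfaceMesh

__all__ = ["write_vtp", "read_vtp", "write_pvd"]


def _data_array(name: str, data: np.ndarray) -> ET.Element:
    data = np.asarray(data)
    el = ET.Element("DataArray", {"type": "Float64", "Name": name, "format": "ascii"})
    if data.ndim == 2:
        el.set("NumberOfComponents", str(data.shape[1]))
    el.text = " ".join(repr(float(x)) for x in data.ravel())
    return el


def write_vtp(
    path: str | Path,
    mesh: SurfaceMesh,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a surface mesh and optional per-vertex arrays to an ascii .vtp file."""
    root = ET.Element(
        "VTKFile", {"type": "PolyData", "version": "0.1", "byte_order": "LittleEndian"}
    )
    poly = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(
        poly,
        "Piece",
        {"NumberOfPoints": str(mesh.n_vertices), "NumberOfPolys": str(len(mesh.triangles))},
    )
    pd = ET.SubElement(piece, "PointData")
    pd.append(_data_array("normals", mesh.vertex_normals))
    for name, arr in (point_data or {}).items():
        arr = np.asarray(arr, float)
        if arr.shape[0] != mesh.n_vertices:
            raise ValueError(f"array {name!r} has {arr.shape[0]} entries, mesh has {mesh.n_vertices}")
        pd.append(_data_array(name, arr))
    points = ET.SubElement(piece, "Points")
    points.append(_data_array("points", mesh.vertices))
    polys = ET.SubElement(piece, "Polys")
    conn = ET.Element("DataArray", {"type": "Int64", "Name": "connectivity", "format": "ascii"})
    conn.text = " ".join(str(int(i)) for i in mesh.triangles.ravel())
    offs = ET.Element("DataArray", {"type": "Int64", "Name": "offsets", "format": "ascii"})
    offs.text = " ".join(str(3 * (i + 1)) for i in range(len(mesh.triangles)))
    polys.append(conn)
    polys.append(offs)
    ET.ElementTree(root).write(path, xml_declaration=True)


def read_vtp(path: str | Path) -> tuple[SurfaceMesh, dict[str, np.ndarray]]:
    """Read an ascii .vtp written by :func:`write_vtp`.

    Returns the mesh and a dict of the per-vertex arrays (excluding the
    normals, which live on the mesh).
    """
    piece = ET.parse(path).getroot().find("./PolyData/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTK PolyData file")

    def parse(el: ET.Element) -> np.ndarray:
        if el.get("format") != "ascii":
            raise ValueError("only ascii-format DataArrays are supported")
        vals = np.array((el.text or "").split(), dtype=float)
        ncomp = int(el.get("NumberOfComponents", "1"))
        return vals.reshape(-1, ncomp) if ncomp > 1 else vals

    points = parse(piece.find("./Points/DataArray"))
    conn = parse(piece.find("./Polys/DataArray[@Name='connectivity']")).astype(int)
    triangles = conn.reshape(-1, 3)
    arrays: dict[str, np.ndarray] = {}
    normals = None
    for el in piece.findall("./PointData/DataArray"):
        data = parse(el)
        if el.get("Name") == "normals":
            normals = data
        else:
            arrays[el.get("Name", "unnamed")] = data
    if normals is None:
        raise ValueError(f"{path}: no 'normals' point array")
    return SurfaceMesh(points, triangles, normals), arrays


def write_pvd(path: str | Path, files_and_times: list[tuple[str, float]]) -> None:
    """Write a ParaView collection (.pvd) referencing a .vtp time series."""
    root = ET.Element("VTKFile", {"type": "Collection", "version": "0.1"})
    coll = ET.SubElement(root, "Collection")
    for fname, t in files_and_times:
        ET.SubElement(coll, "DataSet", {"timestep": repr(float(t)), "part": "0", "file": str(fname)})
    ET.ElementTree(root).write(path, xml_declaration=True)
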