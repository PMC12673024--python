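"""Minimal ASCII VTU (VTK XML unstructured grid) writer/reader.

Covers exactly what this package produces: tetrahedral cells with
optional per-cell and per-point scalar/vector data, ASCII encoded.
Intended for visualization in ParaView-compatible tools and for
round-trip tests; not a general VTK parser.
"""

from __future__ import annotations

from xml.etree import ElementTree as ET

import numpy as np

__all__ = ["write_vtu", "read_vtu"]

_VTK_TET = 10


def _array_text(a: np.ndarray) -> str:
    flat = np.asarray(a).ravel()
    if flat.dtype.kind in "iu":
        return " ".join(str(int(v)) for v in flat)
    return " ".join(f"{float(v):.9g}" for v in flat)


def _data_array(parent, name, a, n_comp=None):
    a = np.asarray(a)
    el = ET.SubElement(parent, "DataArray")
    el.set("type", "Int64" if a.dtype.kind in "iu" else "Float64")
    el.set("Name", name)
    if n_comp is None and a.ndim == 2:
        n_comp = a.shape[1]
    if n_comp:
        el.set("NumberOfComponents", str(n_comp))
    el.set("format", "ascii")
    el.text = _array_text(a)
    return el


def write_vtu(path, nodes: np.ndarray, tets: np.ndarray,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    n_pts, n_cells = nodes.shape[0], tets.shape[0]
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(n_pts),
                          NumberOfCells=str(n_cells))
    pts = ET.SubElement(piece, "Points")
    _data_array(pts, "Points", nodes.astype(float), n_comp=3)
    cells = ET.SubElement(piece, "Cells")
    _data_array(cells, "connectivity", tets.astype(np.int64))
    _data_array(cells, "offsets", (np.arange(1, n_cells + 1) * 4).astype(np.int64))
    _data_array(cells, "types", np.full(n_cells, _VTK_TET, dtype=np.int64))
    if point_data:
        pd = ET.SubElement(piece, "PointData")
        for name, arr in point_data.items():
            _data_array(pd, name, arr)
    if cell_data:
        cd = ET.SubElement(piece, "CellData")
        for name, arr in cell_data.items():
            _data_array(cd, name, arr)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _parse_array(el) -> np.ndarray:
    vals = el.text.split() if el.text else []
    if el.get("type", "").startswith("Int"):
        a = np.array([int(v) for v in vals], dtype=np.int64)
    else:
        a = np.array([float(v) for v in vals])
    nc = int(el.get("NumberOfComponents", "1"))
    return a.reshape(-1, nc) if nc > 1 else a


def read_vtu(path):
    """Returns (nodes, tets, point_data, cell_data)."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as e:
        raise ValueError(f"{path}: malformed VTU: {e}") from e
    piece = tree.getroot().find(".//Piece")
    if piece is None:
        raise ValueError(f"{path}: no <Piece> element")
    nodes = _parse_array(piece.find("./Points/DataArray"))
    cells = {el.get("Name"): el for el in piece.findall("./Cells/DataArray")}
    types = _parse_array(cells["types"])
    if np.any(types != _VTK_TET):
        raise ValueError(f"{path}: non-tetrahedral cells present")
    conn = _parse_array(cells["connectivity"]).reshape(-1, 4)
    point_data = {el.get("Name"): _parse_array(el)
                  for el in piece.findall("./PointData/DataArray")}
    cell_data = {el.get("Name"): _parse_array(el)
                 for el in piece.findall("./CellData/DataArray")}
    return nodes, conn, point_data, cell_data
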