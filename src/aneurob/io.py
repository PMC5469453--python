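"""Mesh and time-series I/O.

Supported formats: STL (via trimesh, no labels — labels go in a sidecar CSV),
VTK XML PolyData/UnstructuredGrid in ASCII (``.vtp`` / ``.vtu``) with region
labels as an integer cell-data array ``region``, and XDMF+HDF5 for field time
series. Per-face scalar fields can be exported as CSV.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .core_mesh import (
    LabeledSurfaceMesh,
    LabeledVolumeMesh,
    REGION_OTHER,
)


def _parse(text: str, dtype=float) -> np.ndarray:
    return np.array(text.split(), dtype=dtype)


def _array_text(a: np.ndarray) -> str:
    return "\n".join(" ".join(str(x) for x in row) for row in np.atleast_2d(a))


def write_vtp(path: str | Path, mesh: LabeledSurfaceMesh) -> None:
    """Write a labeled surface mesh as ASCII VTK XML PolyData."""
    n_pts, n_cells = len(mesh.vertices), mesh.n_faces
    root = ET.Element("VTKFile", type="PolyData", version="0.1",
                      byte_order="LittleEndian")
    poly = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(poly, "Piece", NumberOfPoints=str(n_pts),
                          NumberOfPolys=str(n_cells))
    pts = ET.SubElement(ET.SubElement(piece, "Points"), "DataArray",
                        type="Float64", NumberOfComponents="3", format="ascii")
    pts.text = _array_text(mesh.vertices)
    polys = ET.SubElement(piece, "Polys")
    conn = ET.SubElement(polys, "DataArray", type="Int64", Name="connectivity",
                         format="ascii")
    conn.text = _array_text(mesh.triangles)
    offs = ET.SubElement(polys, "DataArray", type="Int64", Name="offsets",
                         format="ascii")
    offs.text = " ".join(str(3 * (i + 1)) for i in range(n_cells))
    cdata = ET.SubElement(piece, "CellData")
    reg = ET.SubElement(cdata, "DataArray", type="Int64", Name="region",
                        format="ascii")
    reg.text = " ".join(str(int(r)) for r in mesh.face_region)
    ET.ElementTree(root).write(path, xml_declaration=True)


def read_vtp(path: str | Path) -> LabeledSurfaceMesh:
    root = ET.parse(path).getroot()
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTK PolyData file")
    pts = _parse(piece.find("./Points/DataArray").text)
    conn = _parse(piece.find("./Polys/DataArray[@Name='connectivity']").text, np.int64)
    offsets = _parse(piece.find("./Polys/DataArray[@Name='offsets']").text, np.int64)
    if np.any(np.diff(np.concatenate([[0], offsets])) != 3):
        raise ValueError(f"{path}: non-triangular polys")
    region = _read_region(piece, len(offsets))
    return LabeledSurfaceMesh(pts.reshape(-1, 3), conn.reshape(-1, 3), region)


def write_vtu(path: str | Path, mesh: LabeledVolumeMesh) -> None:
    """Write a labeled tet mesh as ASCII VTK XML UnstructuredGrid."""
    n_pts, n_cells = len(mesh.vertices), len(mesh.tetrahedra)
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(n_pts),
                          NumberOfCells=str(n_cells))
    pts = ET.SubElement(ET.SubElement(piece, "Points"), "DataArray",
                        type="Float64", NumberOfComponents="3", format="ascii")
    pts.text = _array_text(mesh.vertices)
    cells = ET.SubElement(piece, "Cells")
    conn = ET.SubElement(cells, "DataArray", type="Int64", Name="connectivity",
                         format="ascii")
    conn.text = _array_text(mesh.tetrahedra)
    offs = ET.SubElement(cells, "DataArray", type="Int64", Name="offsets",
                         format="ascii")
    offs.text = " ".join(str(4 * (i + 1)) for i in range(n_cells))
    types = ET.SubElement(cells, "DataArray", type="UInt8", Name="types",
                          format="ascii")
    types.text = " ".join("10" for _ in range(n_cells))  # VTK_TETRA
    cdata = ET.SubElement(piece, "CellData")
    reg = ET.SubElement(cdata, "DataArray", type="Int64", Name="region",
                        format="ascii")
    reg.text = " ".join(str(int(r)) for r in mesh.cell_region)
    ET.ElementTree(root).write(path, xml_declaration=True)


def read_vtu(path: str | Path) -> LabeledVolumeMesh:
    root = ET.parse(path).getroot()
    piece = root.find("./UnstructuredGrid/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTK UnstructuredGrid file")
    pts = _parse(piece.find("./Points/DataArray").text)
    conn = _parse(piece.find("./Cells/DataArray[@Name='connectivity']").text, np.int64)
    types = _parse(piece.find("./Cells/DataArray[@Name='types']").text, np.int64)
    if np.any(types != 10):
        raise ValueError(f"{path}: contains non-tetrahedral cells")
    region = _read_region(piece, len(types))
    return LabeledVolumeMesh(pts.reshape(-1, 3), conn.reshape(-1, 4), region)


def _read_region(piece: ET.Element, n_cells: int) -> np.ndarray:
    arr = piece.find("./CellData/DataArray[@Name='region']")
    if arr is None:
        return np.full(n_cells, REGION_OTHER, dtype=np.int64)
    return _parse(arr.text, np.int64)


def read_stl(path: str | Path, face_region: np.ndarray | None = None,
             labels_csv: str | Path | None = None) -> LabeledSurfaceMesh:
    """Read an STL wall (binary or ASCII); labels from an array or sidecar CSV.

    The sidecar CSV has one integer region code per face, in face order.
    Faces default to 'other' when no labels are given.
    """
    import trimesh

    tm = trimesh.load_mesh(str(path), process=False)
    if face_region is None and labels_csv is not None:
        face_region = np.loadtxt(labels_csv, dtype=np.int64, ndmin=1)
    if face_region is None:
        face_region = np.full(len(tm.faces), REGION_OTHER, dtype=np.int64)
    return LabeledSurfaceMesh(np.asarray(tm.vertices, dtype=float),
                              np.asarray(tm.faces), face_region)


def write_stl(path: str | Path, mesh: LabeledSurfaceMesh) -> None:
    import trimesh

    trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False).export(str(path))


def read_mesh(path: str | Path, fmt: str | None = None,
              **kwargs) -> LabeledSurfaceMesh | LabeledVolumeMesh:
    """Dispatch to the reader for ``fmt`` (default: from the file suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    readers = {"stl": read_stl, "vtp": read_vtp, "vtu": read_vtu}
    if fmt not in readers:
        raise ValueError(f"unsupported mesh format {fmt!r}")
    return readers[fmt](path, **kwargs)


def write_field_series_xdmf(path: str | Path, times: np.ndarray,
                            values: np.ndarray, name: str = "field") -> None:
    """Write a (n_times, n_locations, 3) series as XDMF + HDF5 heavy data."""
    import h5py

    path = Path(path)
    h5path = path.with_suffix(".h5")
    with h5py.File(h5path, "w") as h5:
        h5.create_dataset("times", data=np.asarray(times, dtype=float))
        h5.create_dataset(name, data=np.asarray(values, dtype=float))
    root = ET.Element("Xdmf", Version="3.0")
    dom = ET.SubElement(root, "Domain")
    grid = ET.SubElement(dom, "Grid", Name=name, GridType="Collection",
                         CollectionType="Temporal")
    values = np.asarray(values)
    for i, t in enumerate(np.asarray(times, dtype=float)):
        g = ET.SubElement(grid, "Grid", Name=f"t{i}")
        ET.SubElement(g, "Time", Value=str(t))
        attr = ET.SubElement(g, "Attribute", Name=name, Center="Cell",
                             AttributeType="Vector")
        item = ET.SubElement(attr, "DataItem",
                             Dimensions=f"{values.shape[1]} 3",
                             Format="HDF",
                             )
        item.set("NumberType", "Float")
        item.text = f"{h5path.name}:/{name}"
    ET.ElementTree(root).write(path, xml_declaration=True)


def read_field_series_h5(path: str | Path, name: str = "field"):
    """Read back (times, values) written by :func:`write_field_series_xdmf`."""
    import h5py

    with h5py.File(Path(path).with_suffix(".h5"), "r") as h5:
        return h5["times"][...], h5[name][...]


def write_face_field_csv(path: str | Path, mesh: LabeledSurfaceMesh,
                         field: np.ndarray, name: str = "value") -> None:
    import pandas as pd

    pd.DataFrame({
        "face": np.arange(mesh.n_faces),
        "region": mesh.face_region,
        "area_mm2": mesh.face_area,
        name: np.asarray(field),
    }).to_csv(path, index=False)
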