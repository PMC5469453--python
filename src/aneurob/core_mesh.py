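"""Mesh and field data model shared by all indicator computations.

Surface and volume meshes carry integer region labels per cell. Coordinates
are in mm, wall shear stress in Pa, velocity in m/s and time in s; unit
conversion happens only at the I/O boundary.

Region code table (cell-data array ``region`` in VTP/VTU files):

====  ===========
code  region
====  ===========
0     other
1     sac (aneurysm dome, Γa / Ωa)
2     neck (surface separating dome from parent vessel)
3     parent artery
4     near-vessel (within 1 cm shortest-path distance of the neck, Ωnv)
====  ===========
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra

logger = logging.getLogger(__name__)

REGION_OTHER = 0
REGION_SAC = 1
REGION_NECK = 2
REGION_PARENT = 3
REGION_NEAR_VESSEL = 4

REGION_NAMES = {
    "other": REGION_OTHER,
    "sac": REGION_SAC,
    "neck": REGION_NECK,
    "parent": REGION_PARENT,
    "near_vessel": REGION_NEAR_VESSEL,
}
REGION_CODES = {v: k for k, v in REGION_NAMES.items()}


def region_code(region: int | str) -> int:
    """Resolve a region given by name or integer code to its integer code."""
    if isinstance(region, str):
        try:
            return REGION_NAMES[region]
        except KeyError:
            raise ValueError(
                f"unknown region {region!r}; known: {sorted(REGION_NAMES)}"
            ) from None
    return int(region)


class DegenerateCellError(ValueError):
    """A cell has zero (or negative) measure; carries the offending indices."""

    def __init__(self, kind: str, indices: np.ndarray):
        self.indices = np.asarray(indices)
        super().__init__(
            f"{len(self.indices)} degenerate {kind}(s) with zero measure: "
            f"indices {self.indices[:20].tolist()}"
        )


@dataclass
class LabeledSurfaceMesh:
    """Triangulated vessel/aneurysm wall with per-face region labels.

    Parameters
    ----------
    vertices : (n_vertices, 3) float array, mm
    triangles : (n_faces, 3) int array of vertex indices (0-based)
    face_region : (n_faces,) int array of region codes (see module docstring)
    """

    vertices: np.ndarray
    triangles: np.ndarray
    face_region: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.face_region = np.asarray(self.face_region, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        if self.face_region.shape != (len(self.triangles),):
            raise ValueError("face_region must have one label per face")
        degenerate = np.flatnonzero(self.face_area <= 0)
        if degenerate.size:
            raise DegenerateCellError("face", degenerate)

    @property
    def n_faces(self) -> int:
        return len(self.triangles)

    def _corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        t = self.triangles
        return v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]

    @property
    def face_area(self) -> np.ndarray:
        """Per-face area, mm^2."""
        if "area" not in self._cache:
            p0, p1, p2 = self._corners()
            self._cache["area"] = 0.5 * np.linalg.norm(
                np.cross(p1 - p0, p2 - p0), axis=1
            )
        return self._cache["area"]

    @property
    def face_normals(self) -> np.ndarray:
        """Per-face unit normals from the triangle winding order."""
        if "normals" not in self._cache:
            p0, p1, p2 = self._corners()
            n = np.cross(p1 - p0, p2 - p0)
            self._cache["normals"] = n / np.linalg.norm(n, axis=1, keepdims=True)
        return self._cache["normals"]

    @property
    def face_centers(self) -> np.ndarray:
        if "centers" not in self._cache:
            p0, p1, p2 = self._corners()
            self._cache["centers"] = (p0 + p1 + p2) / 3.0
        return self._cache["centers"]

    def faces_in_region(self, region: int | str) -> np.ndarray:
        return np.flatnonzero(self.face_region == region_code(region))

    @property
    def sac_faces(self) -> np.ndarray:
        return self.faces_in_region(REGION_SAC)

    @property
    def neck_faces(self) -> np.ndarray:
        return self.faces_in_region(REGION_NECK)

    def region_area(self, region: int | str) -> float:
        faces = self.faces_in_region(region)
        if faces.size == 0:
            raise ValueError(f"region {region!r} is empty")
        return float(self.face_area[faces].sum())

    def vertex_to_face(self, vertex_values: np.ndarray) -> np.ndarray:
        """Average vertex-centered values (n_vertices, ...) onto faces."""
        vals = np.asarray(vertex_values, dtype=float)
        if vals.shape[0] != len(self.vertices):
            raise ValueError("first axis must run over vertices")
        return vals[self.triangles].mean(axis=1)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (n_edges, 2) sorted-index array."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def neck_boundary_vertices(self) -> np.ndarray:
        """Vertices on the curve separating the sac from the rest of the wall.

        Defined as vertices incident to at least one sac face and at least one
        non-sac face (neck cap faces count as non-sac, so the shared ring is
        found whether or not a neck surface is present).
        """
        sac = self.face_region == REGION_SAC
        in_sac = np.zeros(len(self.vertices), dtype=bool)
        in_rest = np.zeros(len(self.vertices), dtype=bool)
        in_sac[self.triangles[sac].ravel()] = True
        in_rest[self.triangles[~sac].ravel()] = True
        return np.flatnonzero(in_sac & in_rest)


@dataclass
class LabeledVolumeMesh:
    """Tetrahedral mesh with per-cell region labels (codes as for surfaces)."""

    vertices: np.ndarray
    tetrahedra: np.ndarray
    cell_region: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.tetrahedra = np.asarray(self.tetrahedra, dtype=np.int64)
        self.cell_region = np.asarray(self.cell_region, dtype=np.int64)
        if self.tetrahedra.ndim != 2 or self.tetrahedra.shape[1] != 4:
            raise ValueError("tetrahedra must be (m, 4)")
        if self.cell_region.shape != (len(self.tetrahedra),):
            raise ValueError("cell_region must have one label per cell")
        degenerate = np.flatnonzero(self.cell_volume <= 0)
        if degenerate.size:
            raise DegenerateCellError("tetrahedron", degenerate)

    @property
    def cell_volume(self) -> np.ndarray:
        """Per-cell volume, mm^3 (orientation-independent)."""
        if "volume" not in self._cache:
            v = self.vertices
            t = self.tetrahedra
            a = v[t[:, 1]] - v[t[:, 0]]
            b = v[t[:, 2]] - v[t[:, 0]]
            c = v[t[:, 3]] - v[t[:, 0]]
            self._cache["volume"] = np.abs(np.einsum("ij,ij->i", np.cross(a, b), c)) / 6.0
        return self._cache["volume"]

    def cells_in_region(self, region: int | str) -> np.ndarray:
        return np.flatnonzero(self.cell_region == region_code(region))

    def region_volume(self, region: int | str) -> float:
        cells = self.cells_in_region(region)
        if cells.size == 0:
            raise ValueError(f"region {region!r} is empty")
        return float(self.cell_volume[cells].sum())


def _validate_times(times: np.ndarray) -> None:
    times = np.asarray(times, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 time samples")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    span = times[-1] - times[0]
    if np.max(np.abs(dt - dt[0])) > 1e-12 * span:
        raise ValueError("time grid must be uniform")


@dataclass
class SurfaceVectorTimeSeries:
    """Vector field τ(x, t) on a surface over one cardiac cycle [T0, T1].

    ``values`` has shape (n_times, n_locations, 3); the grid is uniform and
    includes both cycle endpoints. For a periodic series the first and last
    samples represent the same cycle phase.
    """

    times: np.ndarray
    values: np.ndarray
    location: str = "face"  # "face" | "vertex"
    periodic: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _validate_times(self.times)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("values must be (n_times, n_locations, 3)")
        if self.values.shape[0] != self.times.size:
            raise ValueError("values first axis must match times")
        if self.location not in ("face", "vertex"):
            raise ValueError("location must be 'face' or 'vertex'")

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])

    def magnitudes(self) -> np.ndarray:
        """|τ| with shape (n_times, n_locations)."""
        return np.linalg.norm(self.values, axis=2)

    def on_faces(self, mesh: LabeledSurfaceMesh) -> "SurfaceVectorTimeSeries":
        """Resample a vertex-centered series to face centers (vertex mean)."""
        if self.location == "face":
            return self
        vals = self.values[:, mesh.triangles, :].mean(axis=2)
        return SurfaceVectorTimeSeries(self.times, vals, "face", self.periodic)


@dataclass
class VolumeFieldTimeSeries:
    """Velocity u(x, t), m/s, vertex-centered on a tetrahedral mesh."""

    times: np.ndarray
    values: np.ndarray
    mesh: LabeledVolumeMesh | None = None
    periodic: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _validate_times(self.times)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("values must be (n_times, n_vertices, 3)")
        if self.mesh is not None and self.values.shape[1] != len(self.mesh.vertices):
            raise ValueError("values second axis must match mesh vertices")

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])


def time_average(
    series: SurfaceVectorTimeSeries, mode: str = "norm_then_average"
) -> np.ndarray:
    """Time-average a surface vector series over its cycle.

    Composite trapezoidal rule on the uniform grid, divided by T1 − T0.

    Modes
    -----
    ``vector_then_norm``
        |mean vector| — magnitude of the time-averaged vector (|τ̄|).
    ``norm_then_average``
        mean of |τ| — time average of the magnitude.
    ``mean_vector``
        the time-averaged vector itself, shape (n_locations, 3).
    """
    t = series.times
    span = t[-1] - t[0]
    if mode == "mean_vector":
        return np.trapezoid(series.values, t, axis=0) / span
    if mode == "vector_then_norm":
        return np.linalg.norm(np.trapezoid(series.values, t, axis=0) / span, axis=1)
    if mode == "norm_then_average":
        return np.trapezoid(series.magnitudes(), t, axis=0) / span
    raise ValueError(f"unknown mode {mode!r}")


def time_average_scalar(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Trapezoidal cycle average of a scalar time series (first axis = time)."""
    times = np.asarray(times, dtype=float)
    return np.trapezoid(values, times, axis=0) / (times[-1] - times[0])


def surface_integral(
    field: np.ndarray, mesh: LabeledSurfaceMesh, region: int | str = REGION_SAC
) -> float:
    """∫ field dS over the faces of one region (midpoint rule per face).

    ``field`` is per-face; vertex-centered fields must be averaged to faces
    first (see :meth:`LabeledSurfaceMesh.vertex_to_face`).
    """
    field = np.asarray(field, dtype=float)
    if field.shape != (mesh.n_faces,):
        raise ValueError("field must be per-face over the whole mesh")
    faces = mesh.faces_in_region(region)
    if faces.size == 0:
        raise ValueError(f"region {region!r} is empty")
    return float(np.sum(field[faces] * mesh.face_area[faces]))


def _vertex_graph(mesh: LabeledSurfaceMesh) -> coo_matrix:
    e = mesh.edges()
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = len(mesh.vertices)
    return coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]),
                                  np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n),
    )


def geodesic_vertex_distances(
    mesh: LabeledSurfaceMesh, sources: np.ndarray
) -> np.ndarray:
    """Dijkstra shortest-path distance (mm) from source vertices along edges.

    Edge weights are Euclidean edge lengths; unreachable vertices get inf.
    """
    sources = np.asarray(sources, dtype=np.int64)
    if sources.size == 0:
        raise ValueError("no source vertices")
    return _dijkstra(_vertex_graph(mesh).tocsr(), indices=sources, min_only=True)


def near_vessel_labels(
    mesh: LabeledSurfaceMesh,
    cutoff: float = 10.0,
    sources: np.ndarray | None = None,
) -> np.ndarray:
    """Relabel wall faces within ``cutoff`` mm (shortest path) of the neck.

    Sources default to the neck boundary vertices. Faces currently labeled
    parent/other whose nearest vertex distance is < cutoff become
    near-vessel; sac and neck faces are never relabeled. Returns the new
    label array (the mesh is not modified).
    """
    if sources is None:
        sources = mesh.neck_boundary_vertices()
        if sources.size == 0:
            raise ValueError("no neck boundary found; pass sources explicitly")
    dist = geodesic_vertex_distances(mesh, sources)
    face_dist = dist[mesh.triangles].min(axis=1)
    labels = mesh.face_region.copy()
    eligible = (labels == REGION_PARENT) | (labels == REGION_OTHER)
    labels[eligible & (face_dist < cutoff)] = REGION_NEAR_VESSEL
    unreachable = eligible & ~np.isfinite(face_dist)
    if unreachable.any():
        logger.warning(
            "%d wall faces unreachable from the neck; left as 'other'",
            int(unreachable.sum()),
        )
        labels[unreachable] = REGION_OTHER
    return labels
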