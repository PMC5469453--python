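"""Morphological indicators: sac volume, non-sphericity index, aspect ratio.

The sac volume Va is enclosed by the dome (sac faces) closed by the neck
surface; the non-sphericity index NSI = 1 − (18π)^{1/3} Va^{2/3} / Aa uses
the dome area only, so an exact hemisphere on a planar neck has NSI = 0.
The aspect ratio is aneurysm depth over neck width; since neither is pinned
down uniquely by a triangulated surface, the defaults are deterministic
standard conventions: depth is the maximum distance of sac vertices from the
least-squares plane of the neck boundary curve (dome side), and neck width
the equivalent-circle diameter 2√(Aneck/π). Variants (``depth='max_vertex'``
chord-based depth, ``width='max_chord'``) are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core_mesh import LabeledSurfaceMesh, REGION_NECK, REGION_SAC

MORPHOLOGY_NAMES = ["volume", "nsi", "ar"]


@dataclass
class MorphologyIndicators:
    volume: float  # mm^3 (Va)
    area: float  # mm^2 (dome Aa)
    nsi: float
    ar: float
    depth: float  # mm
    neck_width: float  # mm

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


class OpenSurfaceError(ValueError):
    """The sac+neck surface is not closed/consistently oriented."""

    def __init__(self, boundary_edges: np.ndarray):
        self.boundary_edges = boundary_edges
        super().__init__(
            f"sac+neck surface is not a closed, consistently oriented "
            f"surface; {len(boundary_edges)} offending edges, e.g. "
            f"{boundary_edges[:10].tolist()}"
        )


def _closed_sac_triangles(mesh: LabeledSurfaceMesh) -> np.ndarray:
    if mesh.sac_faces.size == 0:
        raise ValueError("sac region is empty")
    sac = mesh.triangles[mesh.sac_faces]
    neck = mesh.triangles[mesh.neck_faces]
    try:
        return _check_closed(np.concatenate([sac, neck]))
    except OpenSurfaceError:
        # a neck surface wound toward the sac (the inflow convention) is
        # opposite to the dome's outward winding; flipping it may close the
        # surface consistently
        if neck.size == 0:
            raise
        return _check_closed(np.concatenate([sac, neck[:, ::-1]]))


def _check_closed(tris: np.ndarray) -> np.ndarray:
    # closed + consistent orientation <=> every directed edge appears exactly
    # once and its reverse exactly once
    directed = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    uniq, counts = np.unique(directed, axis=0, return_counts=True)
    if np.any(counts > 1):
        raise OpenSurfaceError(uniq[counts > 1])
    edge_list = [tuple(e) for e in directed.tolist()]
    fwd = set(edge_list)
    unmatched = np.array([e for e in edge_list if (e[1], e[0]) not in fwd],
                         dtype=np.int64).reshape(-1, 2)
    if unmatched.size:
        raise OpenSurfaceError(unmatched)
    return tris


def sac_volume(mesh: LabeledSurfaceMesh) -> float:
    """Sac volume, mm³, by the divergence theorem over sac+neck faces.

    Each triangle contributes the signed volume of its tetrahedron with the
    origin; the absolute value of the sum is returned, so the result is
    independent of the global orientation (and of translation, since the
    surface is closed).
    """
    tris = _closed_sac_triangles(mesh)
    v = mesh.vertices
    p0, p1, p2 = v[tris[:, 0]], v[tris[:, 1]], v[tris[:, 2]]
    signed = np.einsum("ij,ij->i", np.cross(p0, p1), p2) / 6.0
    return float(abs(signed.sum()))


def nsi(volume: float, dome_area: float) -> float:
    """Non-sphericity index 1 − (18π)^{1/3} V^{2/3} / A (dome area only)."""
    if volume <= 0 or dome_area <= 0:
        raise ValueError("volume and area must be positive")
    return float(1.0 - (18.0 * np.pi) ** (1.0 / 3.0) * volume ** (2.0 / 3.0)
                 / dome_area)


def neck_plane(mesh: LabeledSurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane of the neck boundary curve: (centroid, unit normal).

    The normal is oriented toward the dome (sac vertices lie on its positive
    side on average).
    """
    ring = mesh.neck_boundary_vertices()
    if ring.size < 3:
        raise ValueError("neck boundary has fewer than 3 vertices")
    pts = mesh.vertices[ring]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("neck boundary is degenerate (collinear)")
    normal = vt[2]
    sac_verts = np.unique(mesh.triangles[mesh.sac_faces].ravel())
    side = (mesh.vertices[sac_verts] - centroid) @ normal
    if side.mean() < 0:
        normal = -normal
    return centroid, normal


def aneurysm_depth(mesh: LabeledSurfaceMesh, method: str = "plane") -> float:
    """Maximum extent of the dome, mm.

    ``plane``: max signed distance of sac vertices from the neck plane on
    the dome side. ``max_vertex``: max distance from the neck-boundary
    centroid to any sac vertex.
    """
    centroid, normal = neck_plane(mesh)
    sac_verts = np.unique(mesh.triangles[mesh.sac_faces].ravel())
    rel = mesh.vertices[sac_verts] - centroid
    if method == "plane":
        return float(np.max(rel @ normal))
    if method == "max_vertex":
        return float(np.max(np.linalg.norm(rel, axis=1)))
    raise ValueError(f"unknown depth method {method!r}")


def neck_width(mesh: LabeledSurfaceMesh, method: str = "equivalent") -> float:
    """Neck width, mm: equivalent-circle diameter 2√(Aneck/π) (default) or
    the maximum chord of the neck boundary curve (``max_chord``)."""
    if method == "equivalent":
        a_neck = mesh.region_area(REGION_NECK)
        return float(2.0 * np.sqrt(a_neck / np.pi))
    if method == "max_chord":
        pts = mesh.vertices[mesh.neck_boundary_vertices()]
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        return float(d.max())
    raise ValueError(f"unknown width method {method!r}")


def aspect_ratio(mesh: LabeledSurfaceMesh, depth_method: str = "plane",
                 width_method: str = "equivalent") -> float:
    """Aspect ratio = aneurysm depth / neck width."""
    return aneurysm_depth(mesh, depth_method) / neck_width(mesh, width_method)


def compute_all(mesh: LabeledSurfaceMesh) -> MorphologyIndicators:
    va = sac_volume(mesh)
    aa = mesh.region_area(REGION_SAC)
    depth = aneurysm_depth(mesh)
    width = neck_width(mesh)
    return MorphologyIndicators(
        volume=va, area=aa, nsi=nsi(va, aa), ar=depth / width,
        depth=depth, neck_width=width,
    )
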