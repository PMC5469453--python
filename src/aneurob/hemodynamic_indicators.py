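"""Hemodynamic indicators computed from WSS and velocity time series.

The nine indicators are the ones commonly used to characterize aneurysmal
flow: sac-averaged and sac-maximum time-averaged wall shear stress (AWSS,
MWSS), oscillatory shear index (OSI), low shear area (LSA), viscous
dissipation ratio (VDR), inflow concentration index (ICI), shear
concentration index (SCI), and — to capture spatial and temporal variation —
the sac-averaged WSS gradient (WSSG) and temporal WSS derivative (TDWSS).

Conventions (all configurable where the literature is ambiguous):

* LSA threshold: time-averaged |τ| strictly below 0.1 × AWSS of the same sac
  (a parent-artery reference can be supplied instead).
* SCI high-shear set at each instant: faces with |τ| strictly above the
  area-weighted mean + 1 population SD of |τ| over the sac.
* MWSS: spatial max of the time-averaged magnitude (a space-time max is
  available via ``spacetime=True``).
* Instants with an empty inflow or high-shear set contribute 0 to the time
  average, preserving the 1/(T1−T0) normalization.
* Faces whose time-averaged |τ| vanishes contribute 0 to OSI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .core_mesh import (
    LabeledSurfaceMesh,
    LabeledVolumeMesh,
    REGION_SAC,
    SurfaceVectorTimeSeries,
    VolumeFieldTimeSeries,
    surface_integral,
    time_average,
    time_average_scalar,
)

logger = logging.getLogger(__name__)

#: Canonical order of the hemodynamic indicator columns.
HEMODYNAMIC_NAMES = [
    "awss", "mwss", "osi", "lsa", "vdr", "ici", "sci", "wssg", "tdwss",
]


@dataclass
class HemodynamicIndicators:
    """Per-case hemodynamic indicator values (NaN where not computable)."""

    awss: float  # Pa
    mwss: float  # Pa
    osi: float
    lsa: float
    vdr: float
    ici: float
    sci: float
    wssg: float  # Pa/mm
    tdwss: float  # Pa/s

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _sac_setup(wss: SurfaceVectorTimeSeries, mesh: LabeledSurfaceMesh):
    series = wss.on_faces(mesh)
    faces = mesh.sac_faces
    if faces.size == 0:
        raise ValueError("sac region is empty")
    return series, faces, mesh.face_area[faces]


def awss(wss: SurfaceVectorTimeSeries, mesh: LabeledSurfaceMesh) -> float:
    """Time- and sac-averaged WSS magnitude, Pa: (1/Aa) ∫Γa avg|τ| dS."""
    series, faces, _ = _sac_setup(wss, mesh)
    mag_avg = time_average(series, "norm_then_average")
    return surface_integral(mag_avg, mesh, REGION_SAC) / mesh.region_area(REGION_SAC)


def mwss(wss: SurfaceVectorTimeSeries, mesh: LabeledSurfaceMesh,
         spacetime: bool = False) -> float:
    """Maximum over the sac of the time-averaged WSS magnitude, Pa.

    With ``spacetime=True``, the maximum of |τ| over both sac faces and time
    samples instead (the time average moves inside/outside the max depending
    on the study convention).
    """
    series, faces, _ = _sac_setup(wss, mesh)
    if spacetime:
        return float(series.magnitudes()[:, faces].max())
    return float(time_average(series, "norm_then_average")[faces].max())


def osi(wss: SurfaceVectorTimeSeries, mesh: LabeledSurfaceMesh) -> float:
    """Oscillatory shear index: (1/Aa) ∫Γa ½(1 − |τ̄| / avg|τ|) dS ∈ [0, ½]."""
    series, faces, _ = _sac_setup(wss, mesh)
    vec_mag = time_average(series, "vector_then_norm")
    mag_avg = time_average(series, "norm_then_average")
    local = np.zeros(mesh.n_faces)
    ok = mag_avg > 0
    local[ok] = 0.5 * (1.0 - vec_mag[ok] / mag_avg[ok])
    n_stagnant = int(np.sum(~ok[faces]))
    if n_stagnant:
        logger.info("OSI: %d stagnant sac faces contribute 0", n_stagnant)
    # guard against tiny negative values from roundoff
    np.clip(local, 0.0, 0.5, out=local)
    return surface_integral(local, mesh, REGION_SAC) / mesh.region_area(REGION_SAC)


def lsa(wss: SurfaceVectorTimeSeries, mesh: LabeledSurfaceMesh,
        threshold_fraction: float = 0.1,
        reference_wss: float | None = None) -> float:
    """Low shear area: sac area fraction with avg|τ| < threshold × reference.

    The reference WSS defaults to the sac AWSS of the same case; pass
    ``reference_wss`` (e.g. a parent-artery AWSS) to override. Strict
    inequality, so a uniform field has LSA exactly 0.
    """
    series, faces, areas = _sac_setup(wss, mesh)
    mag_avg = time_average(series, "norm_then_average")
    ref = awss(wss, mesh) if reference_wss is None else float(reference_wss)
    low = mag_avg[faces] < threshold_fraction * ref
    return float(areas[low].sum() / areas.sum())


def _tet_gradients(mesh: LabeledVolumeMesh, values: np.ndarray) -> np.ndarray:
    """Per-cell gradient of a vertex-centered vector field, (n_cells, 3, 3).

    Linear (P1) shape functions per tetrahedron; entry [c, i, j] is
    ∂u_i/∂x_j on cell c. Units: field units per mm.
    """
    v = mesh.vertices
    t = mesh.tetrahedra
    # edge matrix rows: x1-x0, x2-x0, x3-x0
    E = np.stack([v[t[:, k]] - v[t[:, 0]] for k in (1, 2, 3)], axis=1)
    dU = np.stack([values[t[:, k]] - values[t[:, 0]] for k in (1, 2, 3)], axis=1)
    # solve E^T G^T = dU ... for each cell: dU = E @ grad^T  =>  grad^T = E^{-1} dU
    gradT = np.linalg.solve(E, dU)
    return np.transpose(gradT, (0, 2, 1))


def viscous_dissipation_density(mesh: LabeledVolumeMesh, velocity: np.ndarray,
                                mu: float, rho: float) -> np.ndarray:
    """Per-cell (2μ/ρ)‖ε‖²_F with ε = ½(∇u + ∇uᵀ), from P1 cell gradients.

    ``velocity`` is vertex-centered (n_vertices, 3) in m/s, coordinates in mm;
    the returned density is proportional to (m/s/mm)² — consistent across
    regions, so ratios of region averages are exact.
    """
    g = _tet_gradients(mesh, velocity)
    eps = 0.5 * (g + np.transpose(g, (0, 2, 1)))
    return (2.0 * mu / rho) * np.einsum("cij,cij->c", eps, eps)


def vdr(vel: VolumeFieldTimeSeries, mesh: LabeledVolumeMesh,
        mu: float = 3.45e-3, rho: float = 1056.0) -> float:
    """Viscous dissipation ratio: volume-averaged dissipation in the
    aneurysm over that in the near-vessel region, time-averaged.
    """
    cells_a = mesh.cells_in_region("sac")
    cells_nv = mesh.cells_in_region("near_vessel")
    if cells_a.size == 0 or cells_nv.size == 0:
        raise ValueError("both aneurysm and near-vessel regions are required")
    vol = mesh.cell_volume
    va, vnv = vol[cells_a].sum(), vol[cells_nv].sum()
    ratios = np.empty(len(vel.times))
    for i in range(len(vel.times)):
        dens = viscous_dissipation_density(mesh, vel.values[i], mu, rho)
        num = np.dot(dens[cells_a], vol[cells_a]) / va
        den = np.dot(dens[cells_nv], vol[cells_nv]) / vnv
        if den <= 0:
            raise ValueError(
                f"near-vessel dissipation vanishes at t={vel.times[i]:g}; "
                "VDR is ill-posed")
        ratios[i] = num / den
    return float(time_average_scalar(vel.times, ratios))


def ici(neck_velocity: SurfaceVectorTimeSeries, mesh: LabeledSurfaceMesh,
        parent_flux: np.ndarray) -> float:
    """Inflow concentration index: time average of (Qin/Qpa)/(Ain/Aneck).

    ``neck_velocity`` carries the velocity vectors sampled on the neck
    surface; neck face normals (triangle winding) must point into the sac.
    ``parent_flux`` is the flux through the parent-artery cross-section at
    each time sample, in the same velocity×area units as Qin (antegrade
    positive). Instants with no inflow (Ain = 0) contribute 0.
    """
    series = neck_velocity.on_faces(mesh)
    neck = mesh.neck_faces
    if neck.size == 0:
        raise ValueError("neck region is empty")
    parent_flux = np.asarray(parent_flux, dtype=float)
    if parent_flux.shape != series.times.shape:
        raise ValueError("parent_flux must have one value per time sample")
    if np.any(parent_flux <= 0):
        raise ValueError("parent flow must be antegrade (Qpa > 0) at all times")
    areas = mesh.face_area[neck]
    a_neck = areas.sum()
    normals = mesh.face_normals[neck]
    un = np.einsum("tfk,fk->tf", series.values[:, neck, :], normals)
    inflow = un > 0
    q_in = np.sum(np.where(inflow, un, 0.0) * areas, axis=1)
    a_in = np.sum(np.where(inflow, areas, 0.0), axis=1)
    inst = np.zeros(len(series.times))
    ok = a_in > 0
    inst[ok] = (q_in[ok] / parent_flux[ok]) / (a_in[ok] / a_neck)
    return float(time_average_scalar(series.times, inst))


def sci(wss: SurfaceVectorTimeSeries, mesh: LabeledSurfaceMesh,
        n_sd: float = 1.0) -> float:
    """Shear concentration index: time average of (Fh/Fa)/(Ah/Aa).

    At each instant the high-shear set H holds sac faces with |τ| strictly
    above the area-weighted mean + ``n_sd`` population SDs of |τ| over the
    sac; Fh, Fa are shear-force integrals over H and the whole sac. Instants
    with empty H contribute 0, so a spatially uniform field has SCI 0.
    """
    series, faces, areas = _sac_setup(wss, mesh)
    aa = areas.sum()
    w = areas / aa
    mags = series.magnitudes()[:, faces]  # (nt, n_sac)
    mean = mags @ w
    sd = np.sqrt(np.maximum((mags ** 2) @ w - mean ** 2, 0.0))
    thresh = mean + n_sd * sd
    # strict inequality with a relative guard so roundoff in the weighted
    # mean cannot flag an exactly-uniform field as high-shear
    tol = 1e-9 * np.max(np.abs(mags), axis=1, initial=0.0)
    high = mags > (thresh + tol)[:, None]
    fa = (mags * areas).sum(axis=1)
    fh = np.where(high, mags, 0.0) @ areas
    ah = high @ areas
    inst = np.zeros(len(series.times))
    ok = (ah > 0) & (fa > 0)
    inst[ok] = (fh[ok] / fa[ok]) / (ah[ok] / aa)
    return float(time_average_scalar(series.times, inst))


def _face_tangential_gradient(mesh: LabeledSurfaceMesh,
                              vertex_values: np.ndarray) -> np.ndarray:
    """Per-face tangential gradient of vertex-centered components.

    ``vertex_values`` has shape (n_vertices, d); returns (n_faces, d, 3):
    the in-plane gradient of each component from linear interpolation over
    the triangle (exact for fields linear in space).
    """
    v = mesh.vertices
    t = mesh.triangles
    p0, p1, p2 = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    e1, e2 = p1 - p0, p2 - p0
    n = np.cross(e1, e2)
    a2 = np.linalg.norm(n, axis=1, keepdims=True)  # 2×area
    nhat = n / a2
    # gradient of barycentric hat functions: rotate opposite edges into plane
    g1 = np.cross(nhat, p0 - p2) / a2  # ∇λ1
    g2 = np.cross(nhat, p1 - p0) / a2  # ∇λ2
    f0 = vertex_values[t[:, 0]]
    f1 = vertex_values[t[:, 1]]
    f2 = vertex_values[t[:, 2]]
    return (f1 - f0)[:, :, None] * g1[:, None, :] + \
           (f2 - f0)[:, :, None] * g2[:, None, :]


def wssg(wss: SurfaceVectorTimeSeries, mesh: LabeledSurfaceMesh,
         norm: str = "vector") -> float:
    """Sac-averaged, time-averaged surface gradient norm of the WSS, Pa/mm.

    Requires a vertex-centered series (the gradient needs sub-face
    variation). ``norm='vector'`` uses the Frobenius norm of the full
    tangential gradient of the WSS vector; ``norm='magnitude'`` the norm of
    the gradient of |τ|.
    """
    if wss.location != "vertex":
        raise ValueError(
            "WSSG needs a vertex-centered WSS series; resample face data to "
            "vertices first")
    nt = len(wss.times)
    grads = np.empty((nt, mesh.n_faces))
    for i in range(nt):
        if norm == "vector":
            g = _face_tangential_gradient(mesh, wss.values[i])
        elif norm == "magnitude":
            mag = np.linalg.norm(wss.values[i], axis=1)[:, None]
            g = _face_tangential_gradient(mesh, mag)
        else:
            raise ValueError(f"unknown norm {norm!r}")
        grads[i] = np.sqrt(np.einsum("fij,fij->f", g, g))
    grad_avg = time_average_scalar(wss.times, grads)
    return surface_integral(grad_avg, mesh, REGION_SAC) / mesh.region_area(REGION_SAC)


def tdwss(wss: SurfaceVectorTimeSeries, mesh: LabeledSurfaceMesh) -> float:
    """Sac-averaged time-average of |∂|τ|/∂t|, Pa/s.

    Central differences with periodic wrap-around on the cycle; the series
    must be flagged periodic (first and last samples share the cycle phase).
    """
    if not wss.periodic:
        raise ValueError("TDWSS assumes a periodic (single-cycle) series")
    series = wss.on_faces(mesh)
    mags = series.magnitudes()[:-1]  # drop duplicated endpoint
    dt = series.times[1] - series.times[0]
    dmag = (np.roll(mags, -1, axis=0) - np.roll(mags, 1, axis=0)) / (2 * dt)
    rate = np.abs(dmag)
    rate = np.concatenate([rate, rate[:1]], axis=0)  # restore endpoint
    rate_avg = time_average_scalar(series.times, rate)
    return surface_integral(rate_avg, mesh, REGION_SAC) / mesh.region_area(REGION_SAC)


def compute_all(
    wss: SurfaceVectorTimeSeries | None,
    surface: LabeledSurfaceMesh,
    velocity: VolumeFieldTimeSeries | None = None,
    volume: LabeledVolumeMesh | None = None,
    neck_velocity: SurfaceVectorTimeSeries | None = None,
    parent_flux: np.ndarray | None = None,
    mu: float = 3.45e-3,
    rho: float = 1056.0,
    lsa_threshold: float = 0.1,
    lsa_reference: float | None = None,
    sci_n_sd: float = 1.0,
    mwss_spacetime: bool = False,
) -> HemodynamicIndicators:
    """Compute every available indicator; missing inputs yield NaN fields."""
    nan = float("nan")
    vals = dict.fromkeys(HEMODYNAMIC_NAMES, nan)
    if wss is not None:
        vals["awss"] = awss(wss, surface)
        vals["mwss"] = mwss(wss, surface, spacetime=mwss_spacetime)
        vals["osi"] = osi(wss, surface)
        vals["lsa"] = lsa(wss, surface, lsa_threshold, lsa_reference)
        vals["sci"] = sci(wss, surface, sci_n_sd)
        vals["tdwss"] = tdwss(wss, surface)
        if wss.location == "vertex":
            vals["wssg"] = wssg(wss, surface)
    if velocity is not None and volume is not None:
        vals["vdr"] = vdr(velocity, volume, mu, rho)
    if neck_velocity is not None and parent_flux is not None:
        vals["ici"] = ici(neck_velocity, surface, parent_flux)
    return HemodynamicIndicators(**vals)
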