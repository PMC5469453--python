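"""Shared test helpers (kept out of conftest so they can be imported)."""

import numpy as np

from aneurob.core_mesh import (
    LabeledVolumeMesh,
    REGION_NEAR_VESSEL,
    REGION_SAC,
    VolumeFieldTimeSeries,
)
from aneurob.synthetic_data import tet_mesh_cylinder

PERIOD = 0.949


def poiseuille_volume_series(radius=2.0, length=8.0, edge=0.3, u_mean=0.27,
                             n_times=5):
    """Steady Poiseuille velocity on a cylinder tet mesh split into an
    'aneurysm' half and a 'near-vessel' half (identical flow in both)."""
    verts, tets = tet_mesh_cylinder(radius, length, edge)
    centers = verts[tets].mean(axis=1)
    region = np.where(centers[:, 0] < 0, REGION_SAC, REGION_NEAR_VESSEL)
    mesh = LabeledVolumeMesh(verts, tets, region)
    t = np.linspace(0.0, PERIOD, n_times)
    vel = np.zeros((n_times, len(verts), 3))
    r2 = (verts[:, 1] ** 2 + verts[:, 2] ** 2) / radius ** 2
    vel[:, :, 0] = 2 * u_mean * (1 - r2)[None, :]
    return VolumeFieldTimeSeries(t, vel, mesh), mesh
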