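import numpy as np
import pytest
import trimesh

from aneurob.core_mesh import (
    DegenerateCellError,
    LabeledSurfaceMesh,
    LabeledVolumeMesh,
    REGION_NEAR_VESSEL,
    REGION_PARENT,
    REGION_SAC,
    SurfaceVectorTimeSeries,
    geodesic_vertex_distances,
    near_vessel_labels,
    surface_integral,
    time_average,
)

PERIOD = 0.949
OMEGA = 2 * np.pi / PERIOD


def unit_square_mesh(region=REGION_SAC):
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    t = np.array([[0, 1, 2], [0, 2, 3]])
    return LabeledSurfaceMesh(v, t, np.full(2, region))


class TestSurfaceMesh:
    def test_unit_square_area(self):
        mesh = unit_square_mesh()
        assert mesh.region_area("sac") == pytest.approx(1.0)

    def test_icosphere_area_converges(self):
        exact = 4 * np.pi * 4  # r = 2 mm
        errs = []
        for sub in (2, 4):
            tm = trimesh.creation.icosphere(subdivisions=sub, radius=2.0)
            mesh = LabeledSurfaceMesh(tm.vertices, tm.faces,
                                      np.full(len(tm.faces), REGION_SAC))
            errs.append(abs(mesh.region_area("sac") - exact) / exact)
        assert errs[1] < 0.01  # within 1% at subdivision 4
        assert errs[1] < errs[0] / 2  # at least first-order convergence

    def test_degenerate_face_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        t = np.array([[0, 1, 2]])  # collinear
        with pytest.raises(DegenerateCellError) as err:
            LabeledSurfaceMesh(v, t, np.array([REGION_SAC]))
        assert 0 in err.value.indices

    def test_normals_unit_length(self, ideal_surface):
        norms = np.linalg.norm(ideal_surface.face_normals, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_degenerate_tet_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        with pytest.raises(DegenerateCellError):
            LabeledVolumeMesh(v, np.array([[0, 1, 2, 3]]),
                              np.array([REGION_SAC]))


class TestTimeAverage:
    def times(self, n=101):
        return np.linspace(0.0, PERIOD, n)

    def series(self, fn, n=101, n_loc=4):
        t = self.times(n)
        vals = np.zeros((n, n_loc, 3))
        vals[:] = np.asarray(fn(t))[:, None, :]
        return SurfaceVectorTimeSeries(t, vals)

    def test_constant_field_both_modes(self):
        s = self.series(lambda t: np.tile([2.0, 0, 0], (t.size, 1)))
        assert time_average(s, "vector_then_norm") == pytest.approx(2.0)
        assert time_average(s, "norm_then_average") == pytest.approx(2.0)

    def test_full_period_sine(self):
        s = self.series(lambda t: np.column_stack(
            [np.sin(OMEGA * t), 0 * t, 0 * t]))
        assert time_average(s, "vector_then_norm")[0] == pytest.approx(0.0, abs=1e-12)
        # 2/pi from a dense quadrature oracle, frozen
        assert time_average(s, "norm_then_average")[0] == pytest.approx(
            2 / np.pi, abs=1e-3)

    def test_offset_sine_mean_exact(self):
        # trapezoid integrates the sine to 0 exactly on a uniform periodic grid
        s = self.series(lambda t: np.column_stack(
            [2 + np.sin(OMEGA * t), 0 * t, 0 * t]))
        assert time_average(s, "vector_then_norm")[0] == pytest.approx(2.0)

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 0.1, 0.3, 0.5])
        with pytest.raises(ValueError, match="uniform"):
            SurfaceVectorTimeSeries(t, np.zeros((4, 2, 3)))

    def test_triangle_inequality_random_fields(self, rng):
        t = self.times(33)
        vals = rng.standard_normal((33, 50, 3))
        s = SurfaceVectorTimeSeries(t, vals)
        vtn = time_average(s, "vector_then_norm")
        nta = time_average(s, "norm_then_average")
        assert np.all(vtn <= nta + 1e-12)


class TestSurfaceIntegral:
    def test_unit_field(self, strip500):
        area = strip500.region_area("sac")
        assert surface_integral(np.ones(strip500.n_faces), strip500,
                                "sac") == pytest.approx(area)

    def test_linear_field_on_unit_square(self):
        # integral of z over the unit square rotated into the xz plane = 1/2;
        # face-midpoint rule is exact for linear integrands
        v = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 1], [0, 0, 1]], dtype=float)
        t = np.array([[0, 1, 2], [0, 2, 3]])
        mesh = LabeledSurfaceMesh(v, t, np.full(2, REGION_SAC))
        field = mesh.face_centers[:, 2]
        assert surface_integral(field, mesh, "sac") == pytest.approx(0.5)

    def test_empty_region_error(self, strip500):
        with pytest.raises(ValueError, match="parent"):
            surface_integral(np.ones(strip500.n_faces), strip500, "parent")

    def test_additivity_and_linearity(self, ideal_surface, rng):
        f = rng.random(ideal_surface.n_faces)
        g = rng.random(ideal_surface.n_faces)
        total = sum(
            surface_integral(f, ideal_surface, r)
            for r in ("sac", "neck", "parent", "near_vessel"))
        assert total == pytest.approx(float(np.sum(f * ideal_surface.face_area)))
        assert surface_integral(2 * f + g, ideal_surface, "sac") == pytest.approx(
            2 * surface_integral(f, ideal_surface, "sac")
            + surface_integral(g, ideal_surface, "sac"))


class TestNearVessel:
    def ring(self, tube):
        x0 = tube.vertices[:, 0].min()
        return np.flatnonzero(np.abs(tube.vertices[:, 0] - x0) < 1e-9)

    def test_band_extent_matches_cutoff(self, tube_wall):
        labels = near_vessel_labels(tube_wall, cutoff=10.0,
                                    sources=self.ring(tube_wall))
        band = labels == REGION_NEAR_VESSEL
        assert band.any()
        extent = tube_wall.face_centers[band, 0].max() - \
            tube_wall.vertices[:, 0].min()
        # exact geodesic band length is the cutoff; allow one edge length
        assert abs(extent - 10.0) < 0.45

    def test_zero_cutoff_labels_nothing(self, tube_wall):
        labels = near_vessel_labels(tube_wall, cutoff=0.0,
                                    sources=self.ring(tube_wall))
        assert not np.any(labels == REGION_NEAR_VESSEL)

    def test_large_cutoff_labels_everything_reachable(self, tube_wall):
        labels = near_vessel_labels(tube_wall, cutoff=1e9,
                                    sources=self.ring(tube_wall))
        assert np.all(labels == REGION_NEAR_VESSEL)

    def test_distances_monotone_under_edge_removal(self, tube_wall):
        # removing faces (hence edges) can only increase Dijkstra distances
        src = self.ring(tube_wall)
        full = geodesic_vertex_distances(tube_wall, src)
        keep = np.ones(tube_wall.n_faces, dtype=bool)
        keep[::3] = False
        sub = LabeledSurfaceMesh(tube_wall.vertices,
                                 tube_wall.triangles[keep],
                                 tube_wall.face_region[keep])
        subd = geodesic_vertex_distances(sub, src)
        used = np.unique(sub.triangles)
        assert np.all(subd[used] >= full[used] - 1e-9)

    def test_neck_boundary_ring_on_idealized(self, ideal_surface, ideal_spec):
        ring = ideal_surface.neck_boundary_vertices()
        r = np.hypot(ideal_surface.vertices[ring, 0],
                     ideal_surface.vertices[ring, 1])
        assert np.allclose(r, ideal_spec.neck_radius, atol=1e-9)
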