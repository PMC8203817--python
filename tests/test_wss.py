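"""TAWSS / OSI / RRT / transWSS fields: examples, identities, invariances."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import aortahemo as ah
from conftest import random_smooth_series


@pytest.fixture(scope="module")
def small_mesh():
    return ah.make_cylinder_mesh(10.0, 60.0, n_theta=12, n_z=7)


def uniform_series(mesh, vec, n_time=100, period=1.0):
    times = period * np.arange(n_time) / n_time
    tau = np.broadcast_to(np.asarray(vec, float), (n_time, mesh.n_vertices, 3)).copy()
    return ah.WSSVectorSeries(mesh, times, tau, period)


def flat_patch_series(tau_of_t, n_time=100, period=1.0):
    """Series on a tiny flat two-triangle patch with normal +z."""
    verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
    tris = np.array([[0, 1, 2], [0, 2, 3]])
    normals = np.tile([0.0, 0.0, 1.0], (4, 1))
    mesh = ah.SurfaceMesh(verts, tris, normals)
    times = period * np.arange(n_time) / n_time
    tau = np.stack([np.tile(tau_of_t(t), (4, 1)) for t in times])
    return mesh, ah.WSSVectorSeries(mesh, times, tau, period)


class TestTAWSS:
    def test_constant_vector(self, small_mesh):
        s = uniform_series(small_mesh, [2.0, 0.0, 0.0])
        np.testing.assert_allclose(ah.tawss(s), 2.0)

    def test_rectified_sine_mean(self):
        """TAWSS of A sin(wt) x_hat over a full cycle is 2A/pi."""
        A = 3.0
        _, s = flat_patch_series(lambda t: np.array([A * math.sin(2 * math.pi * t), 0, 0]))
        np.testing.assert_allclose(ah.tawss(s), 2 * A / math.pi, rtol=5e-3)

    def test_parametric_series_against_quadrature_oracle(self, rng, small_mesh):
        """Arbitrary smooth series: adaptive quadrature of |tau(t)| is the oracle."""
        V = small_mesh.n_vertices
        a = 1.0 + rng.random(V)
        b = rng.random(V)

        def tau_fn(t):
            w = 2 * math.pi * t
            out = np.zeros((V, 3))
            out[:, 0] = a + b * np.cos(w)
            out[:, 1] = 0.5 * b * np.sin(w)
            return out

        times = np.arange(64) / 64
        tau = np.stack([tau_fn(t) for t in times])
        s = ah.WSSVectorSeries(small_mesh, times, tau, 1.0)
        coarse = ah.tawss(s)
        oracle = np.array(
            [
                quad(lambda t, v=v: np.linalg.norm(tau_fn(t)[v]), 0.0, 1.0, limit=200)[0]
                for v in range(0, V, max(1, V // 8))
            ]
        )
        np.testing.assert_allclose(coarse[:: max(1, V // 8)][: len(oracle)], oracle, rtol=1e-6)


class TestOSI:
    def test_constant_vector_is_unidirectional(self, small_mesh):
        val, mask = ah.osi(uniform_series(small_mesh, [1.5, 0, 0]))
        np.testing.assert_allclose(val, 0.0, atol=1e-12)
        assert not mask.any()

    def test_zero_mean_sinusoid_is_fully_oscillatory(self):
        _, s = flat_patch_series(lambda t: np.array([math.sin(2 * math.pi * t), 0, 0]))
        val, _ = ah.osi(s)
        np.testing.assert_allclose(val, 0.5, atol=1e-12)

    def test_biaxial_value_matches_quadrature_oracle(self):
        B = 1.0
        _, s = flat_patch_series(lambda t: np.array([1.0, B * math.sin(2 * math.pi * t), 0]))
        val, _ = ah.osi(s)
        mean_mag = quad(lambda t: math.hypot(1.0, B * math.sin(2 * math.pi * t)), 0, 1)[0]
        expected = 0.5 * (1 - 1.0 / mean_mag)  # |mean vector| = 1
        assert 0.0 < val[0] < 0.5
        np.testing.assert_allclose(val, expected, rtol=1e-4)

    def test_all_zero_series_masked(self, small_mesh):
        val, mask = ah.osi(uniform_series(small_mesh, [0.0, 0.0, 0.0]))
        assert mask.all()
        assert np.isnan(val).all()


class TestRRT:
    def test_constant_two_pascal(self, small_mesh):
        s = uniform_series(small_mesh, [2.0, 0, 0])
        osi_f, _ = ah.osi(s)
        val, val_n, mask = ah.rrt(osi_f, ah.tawss(s), small_mesh)
        np.testing.assert_allclose(val, 0.5)
        np.testing.assert_allclose(val_n, 1.0)  # uniform field normalizes to 1
        assert not mask.any()

    def test_inverse_is_mean_vector_magnitude(self, rng, small_mesh):
        """Algebraic identity: (1 - 2 OSI) TAWSS = |time-mean WSS vector|."""
        s = random_smooth_series(rng, small_mesh)
        osi_f, _ = ah.osi(s)
        ta = ah.tawss(s)
        t_c, tau_c = s.closed_cycle()
        mean_vec = np.trapezoid(tau_c, t_c, axis=0) / s.period
        np.testing.assert_allclose(
            (1 - 2 * osi_f) * ta, np.linalg.norm(mean_vec, axis=1), rtol=1e-9
        )

    def test_fully_reversing_vertex_masked(self):
        _, s = flat_patch_series(lambda t: np.array([math.sin(2 * math.pi * t), 0, 0]))
        osi_f, _ = ah.osi(s)
        val, _, mask = ah.rrt(osi_f, ah.tawss(s))
        assert mask.all()
        assert np.isnan(val).all()


class TestTransWSS:
    def test_uniaxial_series_has_no_transverse_component(self, rng, small_mesh):
        amp = 1.0 + rng.random(small_mesh.n_vertices)
        times = np.arange(100) / 100
        profile = 2.0 + np.sin(2 * np.pi * times)
        axial = np.zeros((small_mesh.n_vertices, 3))
        axial[:, 2] = 1.0
        tau = profile[:, None, None] * (amp[None, :, None] * axial[None])
        s = ah.WSSVectorSeries(small_mesh, times, tau, 1.0)
        val, mask = ah.transwss(s)
        np.testing.assert_allclose(val, 0.0, atol=1e-12)
        assert not mask.any()

    def test_transverse_sinusoid_closed_form(self):
        """tau = (1, B sin wt, 0) on a z-normal patch: transWSS = 2B/pi."""
        B = 0.7
        _, s = flat_patch_series(lambda t: np.array([1.0, B * math.sin(2 * math.pi * t), 0]))
        val, _ = ah.transwss(s)
        np.testing.assert_allclose(val, 2 * B / math.pi, rtol=5e-3)

    def test_bounded_by_tawss(self, rng, small_mesh):
        s = random_smooth_series(rng, small_mesh)
        val, mask = ah.transwss(s)
        ta = ah.tawss(s)
        ok = ~mask
        assert np.all(val[ok] <= ta[ok] * (1 + 1e-9))

    def test_undefined_mean_direction_masked(self, small_mesh):
        s = uniform_series(small_mesh, [0.0, 0.0, 0.0])
        val, mask = ah.transwss(s)
        assert mask.all() and np.isnan(val).all()


class TestNormalization:
    def test_uniform_field_normalizes_to_one(self, small_mesh):
        ta = np.full(small_mesh.n_vertices, 3.3)
        ta_n, norm = ah.normalize_tawss(ta, small_mesh)
        np.testing.assert_allclose(ta_n, 1.0)
        assert norm == pytest.approx(3.3)

    def test_field_double_of_inlet_band(self, small_mesh):
        inlet = small_mesh.region("inlet_band")
        ta = np.full(small_mesh.n_vertices, 2.0)
        ta[inlet] = 1.0
        ta_n, _ = ah.normalize_tawss(ta, small_mesh)
        outside = np.setdiff1d(np.arange(small_mesh.n_vertices), inlet)
        np.testing.assert_allclose(ta_n[outside], 2.0)

    def test_missing_band_raises(self, small_mesh):
        with pytest.raises(KeyError):
            ah.normalize_tawss(np.ones(small_mesh.n_vertices), small_mesh, "nope")


class TestSurfaceMean:
    def test_constant_field(self, small_mesh):
        assert ah.surface_mean(np.full(small_mesh.n_vertices, 4.2), small_mesh) == pytest.approx(4.2)

    def test_two_triangle_hand_computation(self):
        # triangle A: (0,0)-(2,0)-(0,2), area 2; triangle B: (2,0)-(2,2)-(0,2), area 2
        verts = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 0]], float)
        tris = np.array([[0, 1, 2], [1, 3, 2]])
        normals = np.tile([0, 0, 1.0], (4, 1))
        mesh = ah.SurfaceMesh(verts, tris, normals)
        f = np.array([3.0, 6.0, 9.0, 12.0])
        # weights: v0 2/3, v1 4/3, v2 4/3, v3 2/3 -> mean = (2+8+12+8)/4
        assert ah.surface_mean(f, mesh) == pytest.approx((2 + 8 + 12 + 8) / 4.0)

    def test_refinement_stability_for_smooth_field(self):
        vals = []
        for n_theta, n_z in ((24, 49), (24, 97)):
            m = ah.make_cylinder_mesh(10.0, 60.0, n_theta, n_z)
            f = np.sin(m.vertices[:, 2] / 60.0 * math.pi)
            vals.append(ah.surface_mean(f, m))
        assert vals[0] == pytest.approx(vals[1], rel=1e-3)
        assert vals[1] == pytest.approx(2 / math.pi, rel=1e-3)  # exact surface mean


class TestMetricSuite:
    def test_rotation_invariance(self, rng, small_mesh):
        """Metrics are invariant under a joint rigid rotation of mesh and vectors."""
        s = random_smooth_series(rng, small_mesh)
        m0 = ah.compute_metrics(s, inlet_band=None)
        # random rotation matrix via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        mesh_r = ah.SurfaceMesh(
            small_mesh.vertices @ q.T,
            small_mesh.triangles,
            small_mesh.vertex_normals @ q.T,
            small_mesh.region_labels,
        )
        s_r = ah.WSSVectorSeries(mesh_r, s.times, s.tau @ q.T, s.period)
        m1 = ah.compute_metrics(s_r, inlet_band=None)
        for name in ("tawss", "osi", "rrt", "transwss"):
            np.testing.assert_allclose(
                getattr(m1, name), getattr(m0, name), rtol=1e-9, equal_nan=True
            )

    def test_osi_bounds_and_time_refinement_order(self, rng, small_mesh):
        s = random_smooth_series(rng, small_mesh)
        val, _ = ah.osi(s)
        assert np.all((val >= 0) & (val <= 0.5))
        # trapezoid time integration: rectified-sine TAWSS error falls ~n^-2
        errs = []
        for n in (16, 32, 64):
            _, ss = flat_patch_series(
                lambda t: np.array([math.sin(2 * math.pi * t + 0.4), 0, 0]), n_time=n
            )
            errs.append(abs(ah.tawss(ss)[0] - 2 / math.pi))
        order = math.log(errs[0] / errs[1]) / math.log(2)
        assert 1.5 <= order <= 2.6

    def test_compute_metrics_bundles_masks_and_normalizations(self, small_mesh):
        spec = ah.SyntheticWSSSpec(recipe="biaxial", mean_pa=1.0, amplitude_pa=1.0)
        s, _ = ah.make_wss_series(spec)
        m = ah.compute_metrics(s)
        assert m.inlet_mean_wss == pytest.approx(m.tawss[0], rel=1e-9)
        np.testing.assert_allclose(m.tawss_n, 1.0, rtol=1e-9)
        assert not m.rrt_infinite.any()
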