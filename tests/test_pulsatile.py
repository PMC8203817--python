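"""Womersley pipe flow: analytic solution, finite-difference solver, wall shear."""

import math

import numpy as np
import pytest

import aortahemo as ah
from aortahemo.fluids import BLOOD

R = 0.01  # m


def harmonic_problem(alpha, A=100.0, steady=0.0):
    """Single-harmonic problem with a prescribed per-harmonic Womersley number."""
    omega = alpha**2 * BLOOD.nu / R**2
    harmonics = [(omega, complex(A))]
    if steady:
        harmonics.insert(0, (0.0, complex(steady)))
    return ah.WomersleyProblem(R=R, harmonics=tuple(harmonics), fluid=BLOOD)


class TestAnalytic:
    def test_poiseuille_force_balance(self):
        G = 100.0
        p = ah.WomersleyProblem(R=R, harmonics=((0.0, G),))
        v = ah.womersley_analytic(p, np.linspace(0, R, 33), np.array([0.0]))
        assert v.u[0, 0] == pytest.approx(G * R**2 / (4 * BLOOD.mu), rel=1e-12)
        assert v.u[-1, 0] == 0.0  # no-slip
        assert ah.analytic_wall_shear(p, np.array([0.0])).tau[0] == pytest.approx(G * R / 2)

    def test_quasi_steady_limit_small_alpha(self):
        """At alpha = 0.1 the profile tracks Poiseuille at the instantaneous gradient."""
        p = harmonic_problem(0.1)
        radii = np.linspace(0, R, 33)
        times = np.linspace(0, p.period, 16, endpoint=False)
        v = ah.womersley_analytic(p, radii, times)
        g_inst = p.gradient(times)
        quasi = g_inst[None, :] * (R**2 - radii[:, None] ** 2) / (4 * BLOOD.mu)
        assert np.max(np.abs(v.u - quasi)) <= 0.01 * np.max(np.abs(quasi))

    def test_annular_effect_at_high_alpha(self):
        """At alpha = 20 the profile is plug-like with a near-wall overshoot."""
        p = harmonic_problem(20.0)
        radii = np.linspace(0, R, 101)
        times = np.linspace(0, p.period, 64, endpoint=False)
        v = ah.womersley_analytic(p, radii, times)
        i_r, _ = np.unravel_index(np.argmax(np.abs(v.u)), v.u.shape)
        assert i_r > 0  # maximum |u| is off-axis

    def test_linearity_of_harmonic_superposition(self):
        p12 = harmonic_problem(5.0, A=80.0, steady=50.0)
        radii = np.linspace(0, R, 17)
        times = np.linspace(0, p12.period, 8, endpoint=False)
        u_sum = ah.womersley_analytic(p12, radii, times).u
        parts = [
            ah.womersley_analytic(
                ah.WomersleyProblem(R=R, harmonics=(h,), period=p12.period), radii, times
            ).u
            for h in p12.harmonics
        ]
        np.testing.assert_allclose(u_sum, parts[0] + parts[1], rtol=0, atol=1e-14)


class TestFiniteDifference:
    def test_steady_problem_converges_to_poiseuille(self):
        # small radius so the start-from-rest transient decays within 5 cycles
        G = 100.0
        p = ah.WomersleyProblem(R=0.002, harmonics=((0.0, G),), period=1.0)
        v = ah.womersley_fd(p, nr=64, steps_per_cycle=200, n_cycles=5)
        exact = G * (0.002**2 - v.radii**2) / (4 * BLOOD.mu)
        err = np.max(np.abs(v.u - exact[:, None])) / exact[0]
        assert err < 1e-3
        assert v.periodicity < 1e-6

    def test_final_cycle_matches_analytic_solution(self):
        """After the 5-cycle protocol the FD cycle agrees with the Bessel series to <1%."""
        p = harmonic_problem(4.0, A=80.0, steady=50.0)
        v = ah.womersley_fd(p, nr=64, steps_per_cycle=200, n_cycles=5)
        va = ah.womersley_analytic(p, v.radii, 4 * p.period + v.times)
        err = np.max(np.abs(v.u - va.u)) / np.max(np.abs(va.u))
        assert err < 0.01
        assert v.periodicity < 1e-3

    def test_no_slip_every_step(self):
        p = harmonic_problem(4.0, A=80.0, steady=50.0)
        v = ah.womersley_fd(p, nr=32, steps_per_cycle=100, n_cycles=2)
        assert np.all(v.u[-1] == 0.0)

    def test_axis_symmetry(self):
        """du/dr at the axis vanishes: the first two nodes agree to O(dr^2)."""
        p = harmonic_problem(4.0, A=80.0, steady=50.0)
        v = ah.womersley_fd(p, nr=64, steps_per_cycle=200, n_cycles=5)
        scale = np.max(np.abs(v.u))
        assert np.max(np.abs(v.u[1] - v.u[0])) < 1e-3 * scale

    def test_periodicity_metric_decays_with_cycles(self):
        p = harmonic_problem(15.0)
        v5 = ah.womersley_fd(p, nr=32, steps_per_cycle=100, n_cycles=5)
        v10 = ah.womersley_fd(p, nr=32, steps_per_cycle=100, n_cycles=10)
        assert v10.periodicity < v5.periodicity

    def test_fd_linearity(self):
        p12 = harmonic_problem(5.0, A=80.0, steady=50.0)
        kw = dict(nr=32, steps_per_cycle=100, n_cycles=3)
        u12 = ah.womersley_fd(p12, **kw).u
        parts = [
            ah.womersley_fd(
                ah.WomersleyProblem(R=R, harmonics=(h,), period=p12.period), **kw
            ).u
            for h in p12.harmonics
        ]
        scale = np.max(np.abs(u12))
        np.testing.assert_allclose(u12, parts[0] + parts[1], rtol=0, atol=1e-6 * scale)

    def test_coarse_time_step_rejected(self):
        p = harmonic_problem(5.0)
        with pytest.raises(ValueError, match="50 steps"):
            ah.womersley_fd(p, nr=32, steps_per_cycle=40)
        with pytest.raises(ValueError, match="nr"):
            ah.womersley_fd(p, nr=8)

    def test_second_order_convergence_via_gci_machinery(self):
        """Simultaneous dr/dt refinement shows the expected order p in [1.8, 2.2]."""
        p = harmonic_problem(4.0, A=80.0, steady=50.0)
        f = []
        for nr, steps in ((16, 50), (32, 100), (64, 200)):
            v = ah.womersley_fd(p, nr=nr, steps_per_cycle=steps, n_cycles=8)
            va = ah.womersley_analytic(p, v.radii, 7 * p.period + v.times)
            f.append(float(np.max(np.abs(v.u - va.u))))
        # discretization errors converge to zero, so the Richardson estimate
        # of the observed order applies to them directly
        order = ah.observed_order(f[0], f[1], f[2], r=2.0)
        assert 1.8 <= order <= 2.2


class TestWallShear:
    def test_poiseuille_wall_shear_both_paths(self):
        G = 100.0
        p = ah.WomersleyProblem(R=R, harmonics=((0.0, G),))
        radii = np.linspace(0, R, 65)
        v = ah.womersley_analytic(p, radii, np.array([0.0]))
        fd = ah.wall_shear(v)
        assert fd.tau[0] == pytest.approx(G * R / 2, rel=5e-3)
        exact = ah.analytic_wall_shear(p, np.array([0.0]))
        assert exact.tau[0] == pytest.approx(G * R / 2, rel=1e-12)

    def test_zero_flow_zero_shear(self):
        v = ah.VelocityField1D(np.linspace(0, R, 9), np.zeros(3) + [0, 1, 2], np.zeros((9, 3)))
        assert np.all(ah.wall_shear(v).tau == 0.0)

    def test_too_few_nodes_rejected(self):
        v = ah.VelocityField1D(np.array([0.0, R]), np.array([0.0]), np.zeros((2, 1)))
        with pytest.raises(ValueError):
            ah.wall_shear(v)

    def test_wall_shear_trails_gradient_by_45_degrees_at_high_alpha(self):
        """Stokes-layer asymptotics: |phase(tau) - phase(G)| -> 45 deg as alpha -> inf."""
        p = harmonic_problem(50.0)
        t = np.linspace(0, p.period, 2048, endpoint=False)
        tau = ah.analytic_wall_shear(p, t).tau
        g = p.gradient(t)
        dphi = np.angle(np.fft.rfft(tau)[1]) - np.angle(np.fft.rfft(g)[1])
        assert abs(abs(math.degrees(dphi)) - 45.0) < 2.0


class TestFitHarmonics:
    def test_constant_flow_gives_poiseuille_gradient(self):
        t = np.arange(64) / 64
        w = ah.FlowWaveform(t, np.full(64, 2e-5), 1.0)
        p = ah.fit_harmonics(w, R, K=1)
        assert p.harmonics[0][1].real == pytest.approx(8 * BLOOD.mu * 2e-5 / (math.pi * R**4))

    def test_single_harmonic_round_trip(self):
        t = np.arange(200) / 200
        q = 1e-5 + 5e-6 * np.sin(2 * np.pi * t + 0.3)
        w = ah.FlowWaveform(t, q, 1.0)
        p = ah.fit_harmonics(w, 0.008, K=1)
        q_rec = ah.analytic_flow(p, t)
        assert np.max(np.abs(q_rec - q)) <= 0.005 * np.max(np.abs(q))

    def test_template_waveform_reconstruction(self, ts2_waveform):
        """K = 8 harmonics reconstruct an aortic-like waveform to ~RMS 2% of peak."""
        p = ah.fit_harmonics(ts2_waveform, R=0.00965, K=8)
        q_rec = ah.analytic_flow(p, ts2_waveform.times)
        rms = np.sqrt(np.mean((q_rec - ts2_waveform.flow) ** 2))
        assert rms < 0.02 * ts2_waveform.flow.max()

    def test_nyquist_guard(self, ts2_waveform):
        with pytest.raises(ValueError, match="Nyquist"):
            ah.fit_harmonics(ts2_waveform, R=0.01, K=100)
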