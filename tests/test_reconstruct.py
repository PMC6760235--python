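"""Joint solver, baselines and their supporting operations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import speckleqpi as sq
from speckleqpi.fields import IntensityImage, WavefrontMap
from speckleqpi.reconstruct import _border_weight
from conftest import rel_rms


class TestEvalObjective:
    def _setup(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        g = sq.SensorGeometry()
        I0 = IntensityImage(50.0 + 20 * rng.random((n, n)), g.sensor_pitch_um)
        return g, I0

    def test_perfect_fit_is_zero(self):
        g, I0 = self._setup()
        wf = WavefrontMap(np.zeros(I0.shape), g.sensor_pitch_um)
        params = sq.SolverParams()
        value = sq.eval_objective(wf, np.ones(I0.shape), I0, I0, g, params)
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_piston_invariance(self):
        g, I0 = self._setup()
        rng = np.random.default_rng(1)
        I = IntensityImage(I0.data * (1 + 0.05 * rng.random(I0.shape)),
                           g.sensor_pitch_um)
        params = sq.SolverParams()
        m = np.ones(I0.shape)
        base = sq.eval_objective(WavefrontMap(np.zeros(I0.shape), g.sensor_pitch_um),
                                 m, I0, I, g, params)
        offset = sq.eval_objective(
            WavefrontMap(np.full(I0.shape, 0.77), g.sensor_pitch_um),
            m, I0, I, g, params)
        assert offset == pytest.approx(base, rel=1e-12)

    def test_matches_brute_force_on_tiny_grid(self):
        """Every term recomputed with independent loops (bilinear warp)."""
        rng = np.random.default_rng(2)
        n = 6
        g = sq.SensorGeometry()
        params = sq.SolverParams(border_margin_px=0, interp_order=1)
        I0 = IntensityImage(40.0 + 10 * rng.random((n, n)), g.sensor_pitch_um)
        I = IntensityImage(40.0 + 10 * rng.random((n, n)), g.sensor_pitch_um)
        phi = 0.02 * rng.standard_normal((n, n))
        m = 1.0 + 0.1 * rng.standard_normal((n, n))
        wf = WavefrontMap.from_phase(phi, g.sensor_pitch_um)
        got = sq.eval_objective(wf, m, I0, I, g, params)

        kappa = g.phase_to_shift_px
        # forward differences, replicate boundary
        def gx(u): return np.pad(u[:, 1:] - u[:, :-1], ((0, 0), (0, 1)))
        def gy(u): return np.pad(u[1:, :] - u[:-1, :], ((0, 1), (0, 0)))
        def lap(u):
            # direct 5-point with replicate boundary via clamped indexing
            d = np.zeros_like(u)
            ny, nx = u.shape
            for i in range(ny):
                for j in range(nx):
                    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        ii = min(max(i + di, 0), ny - 1)
                        jj = min(max(j + dj, 0), nx - 1)
                        d[i, j] += u[ii, jj] - u[i, j]
            return d

        ux, uy = kappa * gx(phi), kappa * gy(phi)
        data = 0.0
        for i in range(n):
            for j in range(n):
                x = min(max(j + ux[i, j], 0.0), n - 1)
                y = min(max(i + uy[i, j], 0.0), n - 1)
                x0, y0 = int(np.floor(x)), int(np.floor(y))
                x1, y1 = min(x0 + 1, n - 1), min(y0 + 1, n - 1)
                fx, fy = x - x0, y - y0
                w = ((1 - fx) * (1 - fy) * I.data[y0, x0]
                     + fx * (1 - fy) * I.data[y0, x1]
                     + (1 - fx) * fy * I.data[y1, x0]
                     + fx * fy * I.data[y1, x1])
                data += (w - m[i, j] * I0.data[i, j]) ** 2
        reg_phi = (params.alpha * (np.abs(gx(phi)).sum() + np.abs(gy(phi)).sum())
                   + params.beta * ((gx(phi)**2 + gy(phi)**2).sum()
                                    + (lap(phi)**2).sum()))
        reg_m = (params.gamma * (np.abs(gx(m)).sum() + np.abs(gy(m)).sum()
                                 + np.abs(lap(m)).sum())
                 + params.tau * ((gx(m)**2 + gy(m)**2).sum()
                                 + (lap(m)**2).sum()))
        assert got == pytest.approx(data + reg_phi + reg_m, rel=1e-10)

    def test_rejects_nan(self):
        g, I0 = self._setup()
        wf = WavefrontMap(np.zeros(I0.shape), g.sensor_pitch_um)
        bad = np.ones(I0.shape)
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            sq.eval_objective(wf, bad, I0, I0, g, sq.SolverParams())


class TestRemoveTilt:
    def test_affine_input_maps_to_zero(self):
        ny, nx = 12, 17
        X, Y = np.meshgrid(np.arange(nx), np.arange(ny))
        wf = WavefrontMap(1.5 - 0.2 * X + 0.05 * Y, 6.45)
        assert np.allclose(sq.remove_tilt(wf).opd_um, 0.0, atol=1e-10)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 1000))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        wf = WavefrontMap(rng.normal(size=(9, 11)), 6.45)
        once = sq.remove_tilt(wf)
        twice = sq.remove_tilt(once)
        assert np.allclose(once.opd_um, twice.opd_um, atol=1e-12)

    def test_quadratic_matches_normal_equations(self):
        """Against an explicit least-squares fit of the [1, x, y] basis."""
        ny, nx = 10, 10
        X, Y = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
        u = 0.3 * X**2 + 0.1 * X * Y - 0.2 * Y + 4.0
        basis = np.stack([np.ones(u.size), X.ravel(), Y.ravel()], axis=1)
        coef, *_ = np.linalg.lstsq(basis, u.ravel(), rcond=None)
        expected = u - (basis @ coef).reshape(u.shape)
        out = sq.remove_tilt(WavefrontMap(u, 6.45))
        assert np.allclose(out.opd_um, expected, atol=1e-9)


class TestCorrectAmplitude:
    def _result(self, opd, m, pitch=6.45):
        wf = WavefrontMap(opd, pitch)
        return sq.ReconResult(wavefront=wf, modulated_intensity=m,
                              amplitude=np.ones_like(m))

    def test_flat_wavefront_returns_modulated_root(self, geometry):
        m = np.full((16, 16), 0.81)
        res = self._result(np.zeros((16, 16)), m)
        A = sq.correct_amplitude(res, geometry)
        assert np.allclose(A, 0.9)
        assert res.diagnostics["amplitude_clamp_count"] == 0

    def test_constant_curvature_uniform_correction(self, geometry):
        c = 40e-6  # 1/um
        ph = sq.curvature_phantom(40.0, (32, 32), 6.45)
        res = self._result(ph.wavefront.opd_um, np.ones((32, 32)))
        A = sq.correct_amplitude(res, geometry)
        assert np.allclose(A, np.sqrt(1 + geometry.z_um * c), rtol=1e-6)

    def test_composition_with_curvature_factor_first_order(self, geometry):
        """cf * (1 + z lap OPD) = 1 - (z lap OPD)^2: the caustic dimming and
        the correction cancel to first order."""
        ph = sq.curvature_phantom(30.0, (32, 32), 6.45)
        cf = sq.curvature_factor(ph.wavefront, geometry)
        res = self._result(ph.wavefront.opd_um, cf)
        A = sq.correct_amplitude(res, geometry)
        zc = geometry.z_um * 30e-6
        assert np.allclose(A**2, 1 - zc**2, atol=1e-9)

    def test_clamping_counts_extreme_curvature(self, geometry):
        ph = sq.curvature_phantom(900.0, (32, 32), 6.45)  # beyond 1/z
        res = self._result(ph.wavefront.opd_um, np.ones((32, 32)))
        A = sq.correct_amplitude(res, geometry)
        assert np.all(np.isfinite(A))
        assert res.diagnostics["amplitude_clamp_count"] == 0  # factor still > 0
        ph2 = sq.curvature_phantom(-900.0, (32, 32), 6.45)
        res2 = self._result(ph2.wavefront.opd_um, np.ones((32, 32)))
        sq.correct_amplitude(res2, geometry)
        assert res2.diagnostics["amplitude_clamp_count"] == 32 * 32


class TestTrackSlopes:
    def test_null_displacement(self, bench):
        s = sq.track_slopes(bench.reference, bench.reference, window_px=16)
        assert np.abs(s.dx_px).max() < 0.05
        assert np.abs(s.dy_px).max() < 0.05

    def test_known_global_shift(self, bench):
        shifted = IntensityImage(np.roll(bench.reference.data, 2, axis=1),
                                 bench.reference.pitch_um)
        s = sq.track_slopes(bench.reference, shifted, window_px=32)
        inner = (slice(16, -16),) * 2
        assert np.allclose(s.dx_px[inner], 2.0, atol=0.1)
        assert np.allclose(s.dy_px[inner], 0.0, atol=0.1)

    def test_window_too_small_rejected(self, bench):
        with pytest.raises(ValueError):
            sq.track_slopes(bench.reference, bench.reference, window_px=4)

    def test_textureless_reference_rejected(self, geometry):
        flat = IntensityImage(np.full((64, 64), 9.0), geometry.sensor_pitch_um)
        with pytest.raises(ValueError, match="texture"):
            sq.track_slopes(flat, flat, window_px=16)


class TestIntegrateSlopes:
    def test_zero_slopes_zero_wavefront(self, geometry):
        s = sq.SlopeField(np.zeros((32, 32)), np.zeros((32, 32)), geometry)
        wf = sq.integrate_slopes(s)
        assert np.allclose(wf.opd_um, 0.0, atol=1e-12)

    def test_exact_on_discrete_gradient_of_quadratic(self, geometry):
        """Integration inverts the discrete gradient to solver precision."""
        from speckleqpi._operators import grad
        X, Y = np.meshgrid(np.arange(48, dtype=float), np.arange(48, dtype=float))
        phi = 0.002 * (X - 24) ** 2 + 0.001 * (Y - 24) ** 2
        kappa = geometry.phase_to_shift_px
        gx, gy = grad(phi)
        s = sq.SlopeField(kappa * gx, kappa * gy, geometry)
        wf = sq.integrate_slopes(s)
        expected = geometry.wavelength_um * (phi - phi.mean()) / (2 * np.pi)
        assert np.sqrt(np.mean((wf.opd_um - expected) ** 2)) < 1e-6 * np.ptp(expected)

    def test_curl_component_is_projected_out(self, geometry):
        """Integrating the re-derived gradient of the first integration
        reproduces the same wavefront (idempotent curl-free projection)."""
        from speckleqpi._operators import grad
        rng = np.random.default_rng(0)
        dx = rng.normal(size=(32, 32))
        dy = rng.normal(size=(32, 32))
        wf1 = sq.integrate_slopes(sq.SlopeField(dx, dy, geometry))
        kappa = geometry.phase_to_shift_px
        gx, gy = grad(wf1.phase_rad)
        wf2 = sq.integrate_slopes(sq.SlopeField(kappa * gx, kappa * gy, geometry))
        assert np.allclose(wf1.opd_um, wf2.opd_um, atol=1e-9)


class TestSolveJoint:
    def test_null_recovery(self, bench):
        """Measuring the reference itself returns a flat wavefront and unit
        modulated intensity."""
        res = sq.solve_joint(bench.reference, bench.reference, bench.geometry)
        assert np.sqrt(np.mean(res.wavefront.opd_um**2)) < 1e-3  # < 1 nm
        assert np.sqrt(np.mean((res.modulated_intensity - 1) ** 2)) < 1e-3

    def test_microlens_recovery_from_model_consistent_data(self, bench):
        """On warped-model data the lenslet profile returns within 5% of its
        sag."""
        import warnings
        truth = bench.pair("microlens")[2]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            I = sq.geometric_forward(bench.reference, truth, bench.geometry)
        res = sq.solve_joint(bench.reference, I, bench.geometry)
        assert rel_rms(res.wavefront.opd_um, bench.truth_opd("microlens")) < 0.05

    def test_objective_trace_non_increasing(self, joint_results):
        for res in joint_results.values():
            trace = np.array(res.objective_trace)
            assert np.all(np.diff(trace) <= 1e-6 * np.maximum(trace[:-1], 1.0))

    def test_zero_reference_rejected(self, geometry):
        zero = IntensityImage(np.zeros((64, 64)), geometry.sensor_pitch_um)
        with pytest.raises(ValueError):
            sq.solve_joint(zero, zero, geometry)

    def test_shape_mismatch_rejected(self, bench, geometry):
        other = IntensityImage(np.ones((32, 32)), geometry.sensor_pitch_um)
        with pytest.raises(ValueError):
            sq.solve_joint(bench.reference, other, geometry)


def test_curl_free_flow_null_case(bench):
    wf = sq.curl_free_flow(bench.reference, bench.reference, bench.geometry)
    assert np.sqrt(np.mean(wf.opd_um**2)) < 1e-3


def test_border_weight_is_one_in_interior():
    w = _border_weight((32, 32), 4)
    assert np.allclose(w[8:-8, 8:-8], 1.0)
    assert w[0, 0] < 0.1
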