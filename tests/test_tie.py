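"""Transport-of-intensity solver: operators, autofocus, thickness."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from tieqpi import (
    BeadSpec,
    ComplexField,
    IntensityStack,
    OpticalConfig,
    PhaseMap,
    TieConfig,
    generate_stack,
    inverse_laplacian,
    make_bead_field,
    phase_to_thickness,
    select_focus,
    tamura_coefficient,
    tie_solve,
)


@pytest.fixture(scope="module")
def optics():
    return OpticalConfig()


def dense_inverse_5pt_laplacian(f: np.ndarray, pitch: float) -> np.ndarray:
    """Brute-force oracle: pseudo-inverse of the periodic 5-point Laplacian."""
    n = f.shape[0]
    idx = np.arange(n * n).reshape(n, n)
    A = np.zeros((n * n, n * n))
    for i in range(n):
        for j in range(n):
            k = idx[i, j]
            A[k, k] = -4.0 / pitch**2
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                A[k, idx[(i + di) % n, (j + dj) % n]] += 1.0 / pitch**2
    g = (np.linalg.pinv(A) @ f.ravel()).reshape(n, n)
    return g - g.mean()


class TestInverseLaplacian:
    periodic = TieConfig(boundary="periodic")

    def test_zero_input_zero_output(self):
        assert np.allclose(inverse_laplacian(np.zeros((16, 16)), 1.0), 0.0)

    def test_fourier_eigenfunction(self):
        # lap(sin(2 pi x / L)) = -(2 pi / L)^2 sin(2 pi x / L)
        n, pitch = 64, 0.5
        L = n * pitch
        x = np.arange(n) * pitch
        f = np.sin(2 * np.pi * x / L)[None, :].repeat(n, axis=0)
        g = inverse_laplacian(f, pitch, self.periodic)
        np.testing.assert_allclose(g, -((L / (2 * np.pi)) ** 2) * f, atol=1e-10)

    def test_matches_dense_pseudo_inverse_on_resolved_field(self):
        rng = np.random.default_rng(0)
        f = gaussian_filter(rng.standard_normal((32, 32)), 1.5, mode="wrap")
        f -= f.mean()
        g_fft = inverse_laplacian(f, 1.0, self.periodic)
        g_dense = dense_inverse_5pt_laplacian(f, 1.0)
        rel = np.linalg.norm(g_fft - g_dense) / np.linalg.norm(g_dense)
        assert rel < 1e-2  # spectral vs 5-point discretization difference

    def test_fft_forward_laplacian_round_trip_exact(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal((32, 32))
        f -= f.mean()
        g = inverse_laplacian(f, 1.0, self.periodic)
        u = np.fft.fftfreq(32, d=1.0)
        U, V = np.meshgrid(u, u)
        back = np.real(np.fft.ifft2(np.fft.fft2(g) * (-4 * np.pi**2 * (U**2 + V**2))))
        assert np.linalg.norm(back - f) / np.linalg.norm(f) < 1e-10

    def test_output_has_zero_mean(self):
        rng = np.random.default_rng(2)
        g = inverse_laplacian(rng.standard_normal((32, 32)), 0.3)
        assert abs(g.mean()) < 1e-12


class TestAxialDerivative:
    def _stack(self, frames, z, optics):
        return IntensityStack(z, frames, optics.pitch_um, optics)

    def test_identical_frames_zero_derivative(self, optics):
        frames = [np.ones((8, 8))] * 3
        stack = self._stack(frames, [-1.0, 0.0, 1.0], optics)
        from tieqpi.tie import axial_derivative

        assert np.allclose(axial_derivative(stack, 0.0), 0.0)

    def test_linear_ramp_exact_for_central_difference(self, optics):
        c = 0.37
        z = [-2.0, 0.0, 2.0]
        frames = [np.full((8, 8), 5.0 + c * zz) for zz in z]
        stack = self._stack(frames, z, optics)
        from tieqpi.tie import axial_derivative

        np.testing.assert_allclose(axial_derivative(stack, 0.0), c, rtol=1e-12)

    def test_matches_fine_step_oracle_for_gaussian_phase(self, optics):
        # forward-model oracle: Richardson-extrapolated derivative at
        # dz = 0.01 um vs the central difference at dz = 1 um
        n = 128
        x = (np.arange(n) - n / 2) * optics.pitch_um
        X, Y = np.meshgrid(x, x)
        phase = 1.5 * np.exp(-(X**2 + Y**2) / (2 * 1.5**2))
        field = ComplexField(np.exp(1j * phase), optics.pitch_um)

        coarse = generate_stack(field, [-1.0, 0.0, 1.0], optics)
        from tieqpi.tie import axial_derivative

        didz = axial_derivative(coarse, 0.0)

        h = 0.01
        fine = generate_stack(field, [-2 * h, -h, h, 2 * h], optics)
        d1 = (fine.frames[2] - fine.frames[1]) / (2 * h)
        d2 = (fine.frames[3] - fine.frames[0]) / (4 * h)
        oracle = (4 * d1 - d2) / 3.0  # Richardson extrapolation
        rms = np.sqrt(np.mean((didz - oracle) ** 2)) / np.sqrt(np.mean(oracle**2))
        assert rms < 0.02

    def test_missing_bracketing_frames_rejected_with_z_list(self, optics):
        stack = self._stack([np.ones((8, 8))] * 2, [0.0, 1.0], optics)
        from tieqpi.tie import axial_derivative

        with pytest.raises(ValueError, match=r"available z"):
            axial_derivative(stack, 0.0)


class TestTieSolve:
    def test_uniform_stack_gives_zero_phase(self, optics):
        frames = [np.ones((32, 32))] * 3
        stack = IntensityStack([-1.0, 0.0, 1.0], frames, optics.pitch_um, optics)
        pm = tie_solve(stack, TieConfig(), optics)
        assert np.allclose(pm.phase_rad, 0.0, atol=1e-12)

    def test_output_is_mean_subtracted(self, optics):
        field = make_bead_field(BeadSpec(), (128, 128), optics)
        stack = generate_stack(field, [-1.0, 0.0, 1.0], optics)
        pm = tie_solve(stack, TieConfig(), optics)
        assert abs(pm.phase_rad.mean()) < 1e-10

    def test_weak_phase_linearity(self, optics):
        """Scaling a weak input phase by alpha scales the output by alpha."""
        n = 128
        x = (np.arange(n) - n / 2) * optics.pitch_um
        X, Y = np.meshgrid(x, x)
        shape = np.exp(-(X**2 + Y**2) / (2 * 1.5**2))
        recovered = {}
        for alpha in (0.1, 0.2):
            field = ComplexField(np.exp(1j * alpha * shape), optics.pitch_um)
            stack = generate_stack(field, [-1.0, 0.0, 1.0], optics)
            recovered[alpha] = tie_solve(stack, TieConfig(), optics).phase_rad
        ratio = np.ptp(recovered[0.2]) / np.ptp(recovered[0.1])
        assert ratio == pytest.approx(2.0, rel=0.03)

    def test_gauge_invariance_constant_offset(self, optics):
        """A global phase offset on the object leaves the output unchanged."""
        n = 128
        x = (np.arange(n) - n / 2) * optics.pitch_um
        X, Y = np.meshgrid(x, x)
        shape = 0.5 * np.exp(-(X**2 + Y**2) / (2 * 1.5**2))
        outs = []
        for offset in (0.0, 0.7):
            field = ComplexField(np.exp(1j * (shape + offset)), optics.pitch_um)
            stack = generate_stack(field, [-1.0, 0.0, 1.0], optics)
            outs.append(tie_solve(stack, TieConfig(), optics).phase_rad)
        np.testing.assert_allclose(outs[0], outs[1], atol=1e-9)

    def test_dark_pixels_handled_by_intensity_floor(self, optics):
        field = make_bead_field(BeadSpec(attenuation_per_um=5.0), (128, 128), optics)
        stack = generate_stack(field, [-1.0, 0.0, 1.0], optics)
        pm = tie_solve(stack, TieConfig(), optics)  # must not divide by ~0
        assert np.all(np.isfinite(pm.phase_rad))


class TestTamura:
    def test_constant_image_is_zero(self):
        assert tamura_coefficient(np.full((8, 8), 3.0)) == 0.0

    def test_two_level_hand_value(self):
        # mean 1, population std 1 -> sqrt(1/1) = 1
        img = np.array([[0.0, 2.0]])
        assert tamura_coefficient(img) == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16)) + 0.5
        assert tamura_coefficient(img) == pytest.approx(tamura_coefficient(5 * img))

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            tamura_coefficient(np.zeros((4, 4)))


class TestSelectFocus:
    def test_pure_phase_bead_stack_selects_focus(self):
        cfg = OpticalConfig(magnification=10)
        field = make_bead_field(BeadSpec(attenuation_per_um=0.0), (64, 64), cfg)
        z = list(np.arange(-60.0, 61.0, 15.0))
        stack = generate_stack(field, z, cfg)
        assert stack.z_positions_um[select_focus(stack, mode="min")] == 0.0

    def test_tie_break_prefers_plane_nearest_zero(self):
        cfg = OpticalConfig(magnification=10)
        frames = [np.ones((8, 8)) + np.eye(8)] * 5
        stack = IntensityStack([-30.0, -15.0, 0.0, 15.0, 30.0], frames, 0.345, cfg)
        assert select_focus(stack) == 2

    def test_absorbing_disk_sharpest_in_focus_with_max_mode(self):
        cfg = OpticalConfig(magnification=10)
        field = make_bead_field(
            BeadSpec(bead_index=1.33, attenuation_per_um=0.843), (64, 64), cfg
        )
        z = list(np.arange(-60.0, 61.0, 15.0))
        stack = generate_stack(field, z, cfg)
        assert stack.z_positions_um[select_focus(stack, mode="max")] == 0.0

    def test_too_few_frames_rejected(self):
        cfg = OpticalConfig(magnification=10)
        stack = IntensityStack([0.0, 1.0], [np.ones((4, 4))] * 2, 0.345, cfg)
        with pytest.raises(ValueError):
            select_focus(stack)


class TestPhaseToThickness:
    def test_bead_peak_phase_maps_back_to_diameter(self, optics):
        pm = PhaseMap(np.array([[14.029]]), optics.pitch_um)
        h = phase_to_thickness(pm, 0.35, optics)
        assert h.thickness_um[0, 0] == pytest.approx(4.0, abs=0.01)

    def test_zero_phase_zero_thickness(self, optics):
        pm = PhaseMap(np.zeros((4, 4)), optics.pitch_um)
        assert np.allclose(phase_to_thickness(pm, 0.35, optics).thickness_um, 0.0)

    def test_doubling_delta_n_halves_thickness(self, optics):
        pm = PhaseMap(np.full((4, 4), 3.0), optics.pitch_um)
        h1 = phase_to_thickness(pm, 0.2, optics).thickness_um
        h2 = phase_to_thickness(pm, 0.4, optics).thickness_um
        np.testing.assert_allclose(h1, 2 * h2)

    def test_zero_delta_n_rejected(self, optics):
        with pytest.raises(ValueError):
            phase_to_thickness(PhaseMap(np.zeros((2, 2)), 1.0), 0.0, optics)


class TestPhaseMap8Bit:
    def test_round_trip_within_quantization(self):
        rng = np.random.default_rng(3)
        pm = PhaseMap(rng.uniform(-1.0, 3.0, (32, 32)), 0.1)
        img = pm.to_uint8()
        back = PhaseMap.from_uint8(img, pm.normalization, 0.1)
        span = pm.normalization[1] - pm.normalization[0]
        assert np.abs(back.phase_rad - pm.phase_rad).max() < span / 255.0
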