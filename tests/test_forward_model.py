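"""Forward model: attenuated line-integral intensity, step profile
construction, triangular detector kernel and smearing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saxsbeam import (
    DensityProfile,
    MediumProperties,
    ScatteringProfile,
    SphericalTarget,
    TriangularKernel,
    build_step_profile,
    default_q_grid,
    half_angle_from_q,
    make_triangular_kernel,
    read_profile,
    relative_intensity,
    relative_q_spread,
    simulate_scene,
    smear_profile,
    write_profile,
)
from saxsbeam.phantoms import paper_sweep_configs


class TestRelativeIntensity:
    def test_no_scatterers_no_signal(self, medium):
        density = DensityProfile.uniform(0.0, 1.0)
        assert relative_intensity(medium, density, 20.0) == 0.0

    def test_attenuation_free_closed_form(self):
        medium = MediumProperties(mu=0.0, rho_t=5.5e5, sigma=5e-23)
        density = DensityProfile.uniform(5.5e5, 2.0)
        got = relative_intensity(medium, density, 4.0)
        assert got == pytest.approx(5e-23 * 5.5e5 * 4.0, rel=1e-12)

    def test_reference_parameters_closed_form(self, medium):
        """sigma rho_t 2 r_t exp(-mu l) at the reference medium values."""
        density = DensityProfile.uniform(5.5e5, 0.5)
        got = relative_intensity(medium, density, 20.0)
        expected = 5e-23 * 5.5e5 * 1.0 * math.exp(-0.30 * 20.0)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_nonuniform_density_quadrature(self, medium):
        # triangular density ramp: integral is half the rectangle
        x = np.linspace(-1.0, 1.0, 401)
        density = DensityProfile(x, 5.5e5 * (1 - np.abs(x)))
        got = relative_intensity(medium, density, 20.0)
        expected = 5e-23 * 5.5e5 * 1.0 * math.exp(-6.0)
        assert got == pytest.approx(expected, rel=1e-4)

    def test_path_shorter_than_target_rejected(self, medium):
        with pytest.raises(ValueError, match="path_length"):
            relative_intensity(medium, DensityProfile.uniform(1.0, 2.0), 1.0)

    def test_log_intensity_affine_in_path_length(self, medium):
        """Beer-Lambert structure: slope of log I vs l is -mu."""
        density = DensityProfile.uniform(5.5e5, 0.5)
        ls = np.array([5.0, 10.0, 15.0, 20.0])
        logs = np.log([relative_intensity(medium, density, l) for l in ls])
        slopes = np.diff(logs) / np.diff(ls)
        assert np.allclose(slopes, -0.30, rtol=1e-9)


class TestStepProfile:
    def make(self, medium, beam, r_t, **kwargs):
        q_center = 13.4
        theta = half_angle_from_q(q_center, beam.wavelength)
        spread = q_center * relative_q_spread(theta, beam.L0, r_t)
        grid = default_q_grid(q_center, spread)
        return build_step_profile(
            medium, SphericalTarget(r_t), beam, q_center, grid, **kwargs
        )

    def test_area_equals_relative_intensity(self, medium, beam):
        profile = self.make(medium, beam, 2.0, path_length=20.0)
        expected = relative_intensity(
            medium, DensityProfile.uniform(medium.rho_t, 2.0), 20.0
        )
        assert profile.area() == pytest.approx(expected, rel=1e-9)

    def test_support_symmetric_about_center(self, medium, beam):
        profile = self.make(medium, beam, 2.0)
        nz = np.nonzero(profile.intensity)[0]
        lo, hi = profile.q_grid[nz[0]], profile.q_grid[nz[-1]]
        # first-order symmetric support around q_center
        assert (13.4 - lo) == pytest.approx(hi - 13.4, rel=0.15)

    def test_doubling_density_doubles_profile(self, beam):
        m1 = MediumProperties(mu=0.30, rho_t=5.5e5, sigma=5e-23)
        m2 = MediumProperties(mu=0.30, rho_t=1.1e6, sigma=5e-23)
        p1 = self.make(m1, beam, 1.0, path_length=10.0)
        p2 = self.make(m2, beam, 1.0, path_length=10.0)
        assert np.allclose(p2.intensity, 2.0 * p1.intensity, rtol=1e-12, atol=0.0)

    def test_linearity_in_cross_section(self, beam):
        m1 = MediumProperties(mu=0.30, rho_t=5.5e5, sigma=5e-23)
        m2 = MediumProperties(mu=0.30, rho_t=5.5e5, sigma=1.5e-22)
        p1 = self.make(m1, beam, 1.0, path_length=10.0)
        p2 = self.make(m2, beam, 1.0, path_length=10.0)
        assert np.allclose(p2.intensity, 3.0 * p1.intensity, rtol=1e-12, atol=0.0)

    def test_tiny_target_concentrates_at_center(self, medium, beam):
        q_center = 13.4
        grid = default_q_grid(q_center, 0.5)
        profile = build_step_profile(
            medium, SphericalTarget(1e-4), beam, q_center, grid
        )
        centroid = np.sum(profile.q_grid * profile.intensity) / np.sum(
            profile.intensity
        )
        assert centroid == pytest.approx(q_center, abs=2 * profile.q_step)

    def test_narrow_grid_rejected(self, medium, beam):
        grid = np.linspace(13.3, 13.5, 64)
        with pytest.raises(ValueError, match="support"):
            build_step_profile(medium, SphericalTarget(2.0), beam, 13.4, grid)

    def test_step_width_matches_geometric_spread(self, medium, beam):
        """The q extent of the unsmeared step agrees with the closed-form
        spread to second order in r_t / L0."""
        r_t = 2.0
        profile = self.make(medium, beam, r_t)
        nz = np.nonzero(profile.intensity)[0]
        width = profile.q_grid[nz[-1]] - profile.q_grid[nz[0]]
        theta = half_angle_from_q(13.4, beam.wavelength)
        spread = 13.4 * relative_q_spread(theta, beam.L0, r_t)
        eps = r_t / beam.L0
        assert abs(width - spread) / spread <= 2 * eps


class TestTriangularKernel:
    def test_base_width_fraction_and_unit_area(self):
        kernel = make_triangular_kernel(1.0, 0.01)
        assert kernel.base_width == pytest.approx(0.35)
        assert kernel.samples.sum() * kernel.q_step == pytest.approx(1.0, abs=1e-9)

    @given(spread=st.floats(0.1, 5.0), n=st.integers(20, 400))
    @settings(derandomize=True, max_examples=50)
    def test_area_invariant(self, spread, n):
        q_step = 0.35 * spread / n
        kernel = make_triangular_kernel(spread, q_step)
        assert kernel.samples.sum() * kernel.q_step == pytest.approx(1.0, abs=1e-9)

    def test_peak_approaches_continuum_value(self):
        kernel = make_triangular_kernel(1.0, 0.0005)
        assert kernel.samples.max() == pytest.approx(2 / 0.35, rel=1e-2)

    def test_coarse_step_rejected(self):
        with pytest.raises(ValueError, match="coarse"):
            make_triangular_kernel(1.0, 0.2)


class TestSmearing:
    def rectangle(self, width=2.0, height=3.0, n=2001):
        q = np.linspace(5.0, 15.0, n)
        y = np.where(np.abs(q - 10.0) <= width / 2, height, 0.0)
        return ScatteringProfile(q, y)

    def test_single_sample_kernel_is_identity(self):
        profile = self.rectangle()
        dq = profile.q_step
        kernel = TriangularKernel(
            base_width=0.0, q_step=dq, samples=np.array([1.0 / dq])
        )
        smeared = smear_profile(profile, kernel)
        assert np.allclose(smeared.intensity, profile.intensity)

    def test_rectangle_becomes_trapezoid(self):
        profile = self.rectangle(width=2.0, height=3.0)
        kernel = make_triangular_kernel(2.0, profile.q_step)
        smeared = smear_profile(profile, kernel)
        assert smeared.intensity.max() <= 3.0 + 1e-12
        # flanks are softened: intermediate values exist
        assert np.any((smeared.intensity > 0.5) & (smeared.intensity < 2.5))
        # plateau survives because the kernel is narrower than the step
        assert smeared.intensity.max() == pytest.approx(3.0, rel=1e-9)

    def test_area_conserved(self):
        profile = self.rectangle()
        kernel = make_triangular_kernel(2.0, profile.q_step)
        smeared = smear_profile(profile, kernel)
        assert abs(smeared.area() - profile.area()) / profile.area() < 1e-6

    def test_matches_direct_convolution(self):
        profile = self.rectangle(n=801)
        kernel = make_triangular_kernel(2.0, profile.q_step)
        smeared = smear_profile(profile, kernel)
        m = kernel.half_samples
        direct = np.zeros(profile.intensity.size + 2 * m)
        for i, w in enumerate(profile.intensity):
            direct[i : i + 2 * m + 1] += w * kernel.samples * profile.q_step
        assert np.allclose(smeared.intensity, direct, rtol=1e-9, atol=1e-15)

    def test_nonuniform_grid_rejected(self):
        q = np.concatenate([np.linspace(0, 1, 50), np.linspace(1.1, 3, 50)])
        profile = ScatteringProfile(q, np.ones_like(q))
        kernel = make_triangular_kernel(1.0, 0.01)
        with pytest.raises(ValueError, match="uniform"):
            smear_profile(profile, kernel)


class TestSceneBehaviors:
    """Qualitative forward-model behaviors on the analytic sweeps."""

    @staticmethod
    def peaks(name):
        from saxsbeam import summarize

        return [
            summarize(simulate_scene(scene)) for scene in paper_sweep_configs(name)
        ]

    def test_smaller_object_scatters_brighter(self):
        metrics = self.peaks("fig1")
        peaks = [m.I_p for m in metrics]
        assert all(a > b for a, b in zip(peaks, peaks[1:]))

    def test_target_closer_to_detector_smears_more(self):
        metrics = self.peaks("fig2")
        hwhm = [m.delta_q for m in metrics]  # L0 = 18..22
        assert all(a > b for a, b in zip(hwhm, hwhm[1:]))

    def test_shorter_chord_scatters_brighter(self):
        metrics = self.peaks("fig3")  # decreasing subtended angle = shorter chord
        peaks = [m.I_p for m in metrics]
        assert all(a < b for a, b in zip(peaks, peaks[1:]))

    def test_elliptical_target_peak_angle_invariant(self):
        metrics = self.peaks("fig4")
        peaks = [m.I_p for m in metrics]
        assert max(peaks) / min(peaks) - 1 < 0.02
        hwhm = [m.delta_q for m in metrics]  # phi = 0 .. pi/2
        assert all(a < b for a, b in zip(hwhm, hwhm[1:]))

    def test_larger_target_lower_peak_wider_spread(self):
        metrics = self.peaks("fig8")
        peaks = [m.I_p for m in metrics]
        hwhm = [m.delta_q for m in metrics]
        assert all(a > b for a, b in zip(peaks, peaks[1:]))
        assert all(a < b for a, b in zip(hwhm, hwhm[1:]))


class TestProfileIO:
    def test_round_trip(self, tmp_path, medium, beam):
        scene = paper_sweep_configs("fig8")[0]
        profile = simulate_scene(scene)
        path = tmp_path / "profile.tsv"
        write_profile(profile, str(path), header={"scene": "fig8_0"})
        back = read_profile(str(path))
        # 9-significant-digit text round trip
        assert np.allclose(back.q_grid, profile.q_grid, rtol=1e-8)
        assert np.allclose(back.intensity, profile.intensity, rtol=1e-8)

    def test_written_text_is_stable(self, tmp_path, medium, beam):
        scene = paper_sweep_configs("fig8")[0]
        profile = simulate_scene(scene)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_profile(profile, str(p1))
        write_profile(profile, str(p2))
        assert p1.read_bytes() == p2.read_bytes()
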