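"""Fresnel interface physics and the multibeam interference sum."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipilyzer.optics import (
    OpticalStack,
    fresnel_amplitudes,
    interfere,
    multibeam_intensities,
    optical_path_difference,
    phase_difference,
    reflectance_transmittance,
    reflection_spectrum,
    snell_refraction_angle,
)


class TestSnell:
    def test_normal_incidence_stays_normal(self):
        stack = OpticalStack(incidence_angle=0.0)
        assert snell_refraction_angle(stack, "air", "lipid") == 0.0

    def test_direct_arithmetic(self):
        stack = OpticalStack(n_lipid=2.0, incidence_angle=math.pi / 6)
        theta2 = snell_refraction_angle(stack, "air", "lipid")
        assert theta2 == pytest.approx(math.asin(0.25), abs=1e-15)

    def test_round_trip_symmetry(self):
        stack = OpticalStack(incidence_angle=0.4)
        theta2 = snell_refraction_angle(stack, "air", "lipid")
        # crossing back out must return the original incidence angle
        sin_back = stack.n_lipid * math.sin(theta2) / stack.n_air
        assert math.asin(sin_back) == pytest.approx(0.4, abs=1e-12)

    def test_non_adjacent_layers_rejected(self):
        with pytest.raises(ValueError):
            snell_refraction_angle(OpticalStack(), "air", "tear")


class TestOpticalPath:
    def test_zero_thickness(self):
        assert optical_path_difference(OpticalStack(), 0.0) == 0.0

    def test_direct_arithmetic_normal_incidence(self):
        stack = OpticalStack(n_lipid=1.5, incidence_angle=0.0)
        assert optical_path_difference(stack, 100.0) == pytest.approx(300.0)

    def test_monotone_in_thickness(self):
        stack = OpticalStack(incidence_angle=0.3)
        opds = [optical_path_difference(stack, d) for d in (10, 50, 100, 200)]
        assert all(a < b for a, b in zip(opds, opds[1:]))

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError):
            optical_path_difference(OpticalStack(), -1.0)


class TestPhase:
    @pytest.mark.parametrize(
        "opd,lam,expected",
        [(300.0, 600.0, math.pi), (0.0, 500.0, 0.0), (600.0, 600.0, 2 * math.pi)],
    )
    def test_direct_values(self, opd, lam, expected):
        assert phase_difference(opd, lam) == pytest.approx(expected)

    def test_doubling_wavelength_halves_phase(self):
        assert phase_difference(450.0, 900.0) == pytest.approx(
            phase_difference(450.0, 450.0) / 2
        )

    def test_nonpositive_wavelength_rejected(self):
        with pytest.raises(ValueError):
            phase_difference(100.0, 0.0)


class TestFresnel:
    def test_normal_incidence_closed_form(self):
        r_s, t_s, r_p, t_p = fresnel_amplitudes(1.0, 1.5, 0.0)
        assert r_s == pytest.approx(-0.2, abs=1e-15)
        # the p convention flips the sign at normal incidence
        assert r_p == pytest.approx(0.2, abs=1e-15)
        assert abs(r_s) == abs(r_p)

    def test_brewster_angle_kills_p_reflection(self):
        n1, n2 = 1.0, 1.48
        theta_b = math.atan(n2 / n1)
        _, _, r_p, _ = fresnel_amplitudes(n1, n2, theta_b)
        assert abs(r_p) < 1e-12

    def test_matched_media_transparent(self):
        r_s, t_s, r_p, t_p = fresnel_amplitudes(1.4, 1.4, 0.7)
        assert r_s == 0 and r_p == 0
        assert t_s == pytest.approx(1.0) and t_p == pytest.approx(1.0)

    def test_normal_incidence_reflectance(self):
        (R_s, T_s), (R_p, T_p) = reflectance_transmittance(1.0, 1.5, 0.0)
        assert R_s == pytest.approx(((1 - 1.5) / (1 + 1.5)) ** 2, abs=1e-15)
        assert R_p == R_s

    def test_reflectance_symmetric_under_media_swap_at_normal(self):
        (R_a, _), _ = reflectance_transmittance(1.0, 1.48, 0.0)
        (R_b, _), _ = reflectance_transmittance(1.48, 1.0, 0.0)
        assert R_a == pytest.approx(R_b, abs=1e-15)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        n1=st.floats(1.0, 2.5),
        n2=st.floats(1.0, 2.5),
        theta=st.floats(0.0, 1.2),
    )
    def test_energy_conservation(self, n1, n2, theta):
        """A lossless dielectric interface reflects + transmits all energy."""
        if n1 * math.sin(theta) / n2 >= 1.0:
            return  # total internal reflection configuration
        for R, T in reflectance_transmittance(n1, n2, theta):
            assert R + T == pytest.approx(1.0, abs=1e-12)


class TestMultibeam:
    def test_geometric_ratio_between_orders(self):
        stack = OpticalStack()
        rays = multibeam_intensities(stack, 550.0, 80.0, truncation_tol=1e-30)
        intensities = [i for i, _ in rays]
        ratios = [b / a for a, b in zip(intensities[1:], intensities[2:])]
        assert len(set(round(r, 14) for r in ratios)) == 1

    def test_closed_form_matches_partial_sums(self, rng):
        """Total reflected energy: geometric-series formula vs accumulation."""
        for _ in range(200):
            stack = OpticalStack(
                n_lipid=rng.uniform(1.2, 1.8),
                n_tear=rng.uniform(1.1, 1.6),
                incidence_angle=rng.uniform(0, 1.0),
            )
            rays = multibeam_intensities(
                stack, rng.uniform(400, 700), rng.uniform(0, 240), truncation_tol=1e-30
            )
            intensities = [i for i, _ in rays]
            brute = sum(intensities[1:])
            ratio = intensities[2] / intensities[1]
            m = len(intensities) - 1
            closed = intensities[1] * (1 - ratio**m) / (1 - ratio)
            assert brute == pytest.approx(closed, abs=1e-10)

    def test_zero_thickness_means_zero_phases(self):
        rays = multibeam_intensities(OpticalStack(), 550.0, 0.0)
        assert all(theta == 0.0 for _, theta in rays)

    def test_truncation_controls_order_count(self):
        few = multibeam_intensities(OpticalStack(), 550.0, 80.0, truncation_tol=1e-3)
        many = multibeam_intensities(OpticalStack(), 550.0, 80.0, truncation_tol=1e-15)
        assert len(few) < len(many)


class TestInterfere:
    def test_zero_thickness_is_in_phase_maximum(self):
        stack = OpticalStack()
        rays = multibeam_intensities(stack, 600.0, 0.0)
        expected = sum(math.sqrt(i) for i, _ in rays) ** 2
        result = interfere(stack, 600.0, 0.0)
        assert result.intensity == pytest.approx(expected, rel=1e-12)
        # and no thickness gives more
        ds = np.linspace(0, 240, 97)
        assert all(interfere(stack, 600.0, d).intensity <= expected + 1e-12 for d in ds)

    def test_periodic_in_thickness_at_normal_incidence(self):
        stack = OpticalStack(incidence_angle=0.0)
        period = 600.0 / (2 * stack.n_lipid)
        for d in (10.0, 55.0, 130.0):
            a = interfere(stack, 600.0, d, truncation_tol=1e-12).intensity
            b = interfere(stack, 600.0, d + period, truncation_tol=1e-12).intensity
            assert a == pytest.approx(b, rel=1e-9)

    def test_truncation_converged_by_second_order(self):
        """Dropping orders beyond m=2 changes intensity by less than the
        analytic geometric-tail bound (the omitted amplitude is a geometric
        series in sqrt(R21*R23), entering the intensity via a cross term)."""
        stack = OpticalStack()
        rays = multibeam_intensities(stack, 550.0, 10.0, truncation_tol=1e-30)
        ratio = rays[2][0] / rays[1][0]
        tail_amp = math.sqrt(rays[2][0]) / (1 - math.sqrt(ratio))
        total_amp = sum(math.sqrt(i) for i, _ in rays)
        bound = 2 * total_amp * tail_amp + tail_amp**2
        for d in (0.0, 40.0, 120.0, 240.0):
            lo = interfere(stack, 550.0, d, max_orders=2, truncation_tol=0.0).intensity
            hi = interfere(stack, 550.0, d, max_orders=50, truncation_tol=1e-30).intensity
            assert abs(hi - lo) <= bound
        # at the default tolerance the retained orders are fully converged
        default = interfere(stack, 550.0, 80.0).intensity
        full = interfere(stack, 550.0, 80.0, max_orders=50, truncation_tol=1e-30).intensity
        # omitted orders have I_m < 1e-9, so their amplitude cross term
        # perturbs the intensity by < ~2*|A|*sqrt(1e-9) ~ 1e-5
        assert abs(full - default) < 1e-5

    def test_intensity_is_squared_amplitude(self):
        res = interfere(OpticalStack(), 500.0, 77.0)
        assert res.intensity == pytest.approx(abs(res.amplitude) ** 2)

    def test_signed_amplitudes_make_thin_film_dark(self):
        """With the physical half-wave shifts, a vanishing film reflects least."""
        stack = OpticalStack()
        lam = np.linspace(400.0, 700.0, 31)
        at_zero = reflection_spectrum(stack, lam, 0.0, signed_amplitudes=True)
        at_quarter = reflection_spectrum(stack, lam, 100.0, signed_amplitudes=True)
        assert at_zero.mean() < at_quarter.mean()

    def test_spectrum_matches_scalar_interfere(self):
        stack = OpticalStack()
        lam = np.array([450.0, 550.0, 650.0])
        spec = reflection_spectrum(stack, lam, 90.0)
        for i, w in enumerate(lam):
            s = interfere(stack, w, 90.0, polarization="s").intensity
            p = interfere(stack, w, 90.0, polarization="p").intensity
            assert spec[i] == pytest.approx((s + p) / 2, rel=1e-10)
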