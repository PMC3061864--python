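"""Photoselection, anisotropy, beam and multipulse theory."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from pulsedyn.photoselection import (
    InfeasibleAnisotropyError,
    MultipulseSchedule,
    PulseParameters,
    SampleGeometry,
    anisotropy_degenerate,
    anisotropy_factor,
    beam_profile_fraction,
    beam_ratio_correction,
    depth_average_anisotropy,
    ensemble_fraction,
    excitation_strength,
    extract_dipole_angle,
    measured_anisotropy,
    multipulse_anisotropy,
    multipulse_fraction,
    multipulse_weights,
    orientational_fraction,
    pure_intermediate_signal,
)

PHYTOCHROME = dict(energy=1.65e-6, wavelength=640e-9, beam_size=120e-6,
                   cross_section=1.08e-16, quantum_yield=0.1)


def quad_fraction(x, absorber="linear"):
    """Independent adaptive-quadrature oracle for <f>."""
    if absorber == "linear":
        f = lambda p: 1.0 - np.exp(-3.0 * x * p * p)  # noqa: E731
    else:
        f = lambda p: 1.0 - np.exp(-1.5 * x * (1 - p * p))  # noqa: E731
    return quad(f, 0.0, 1.0, epsabs=1e-14, epsrel=1e-14)[0]


def quad_anisotropy(x):
    """Independent oracle for r_opt = <f P2>/<f>."""
    p2 = lambda p: 0.5 * (3 * p * p - 1)  # noqa: E731
    f = lambda p: 1.0 - np.exp(-3.0 * x * p * p)  # noqa: E731
    num = quad(lambda p: f(p) * p2(p), 0, 1, epsabs=1e-14, epsrel=1e-14)[0]
    den = quad(f, 0, 1, epsabs=1e-14, epsrel=1e-14)[0]
    return num / den


class TestExcitationStrength:
    def test_linear_in_pulse_energy(self):
        p1 = PulseParameters(**PHYTOCHROME)
        p2 = PulseParameters(**{**PHYTOCHROME, "energy": 2 * PHYTOCHROME["energy"]})
        assert excitation_strength(p2) == pytest.approx(2 * excitation_strength(p1), rel=1e-12)

    def test_phytochrome_working_point_hand_arithmetic(self):
        # x = (E / (hc/lambda)) / (pi (D/2)^2) * sigma * Phi, area in cm^2
        photon_energy = 6.62607015e-34 * 2.99792458e8 / 640e-9
        flux = (1.65e-6 / photon_energy) / (np.pi * (60e-6 * 100) ** 2)
        expected = flux * 1.08e-16 * 0.1
        pulse = PulseParameters(**PHYTOCHROME)
        assert excitation_strength(pulse) == pytest.approx(expected, rel=1e-3)

    def test_gaussian_peak_uses_integral_equality_factor(self):
        # equal energy, FWHM = top-hat diameter: peak flux ratio is ln 2,
        # from N/(2 pi s^2) vs N/(pi D^2/4) with s = D/(2 sqrt(2 ln 2))
        th = PulseParameters(**PHYTOCHROME, profile="top-hat")
        ga = PulseParameters(**PHYTOCHROME, profile="gaussian")
        assert excitation_strength(ga) / excitation_strength(th) == pytest.approx(
            np.log(2), rel=1e-12
        )

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            PulseParameters(**{**PHYTOCHROME, "quantum_yield": 1.5})
        with pytest.raises(ValueError):
            PulseParameters(**{**PHYTOCHROME, "beam_size": 0.0})


class TestOrientationalFraction:
    def test_perpendicular_linear_absorber_never_photolysed(self):
        for x in (0.1, 1.0, 100.0):
            assert orientational_fraction(x, 0.0, "linear") == 0.0

    def test_no_light_no_photolysis(self):
        p = np.linspace(0, 1, 11)
        assert np.all(orientational_fraction(0.0, p, "linear") == 0.0)
        assert np.all(orientational_fraction(0.0, p, "circular") == 0.0)

    def test_aligned_molecules_saturate_at_high_power(self):
        assert orientational_fraction(50.0, 1.0, "linear") == pytest.approx(1.0, abs=1e-12)

    def test_circular_absorber_excites_perpendicular_orientations(self):
        # contrast with the linear case: p = 0 molecules are photolysed
        assert orientational_fraction(1.0, 0.0, "circular") > 0.0

    def test_monotone_in_x(self):
        xs = np.linspace(0, 5, 30)
        vals = [orientational_fraction(x, 0.7) for x in xs]
        assert np.all(np.diff(vals) > 0)

    def test_invalid_orientation_rejected(self):
        with pytest.raises(ValueError):
            orientational_fraction(1.0, 1.2)


class TestEnsembleFraction:
    def test_zero_power(self):
        assert ensemble_fraction(0.0) == 0.0
        assert ensemble_fraction(0.0, method="taylor") == 0.0

    def test_never_reaches_unity_for_linear_absorber(self):
        val = ensemble_fraction(500.0)
        assert 0.9 < val < 1.0

    @pytest.mark.parametrize("x", [1e-3, 0.02, 0.1, 0.5, 2.0])
    def test_matches_quadrature_oracle(self, x):
        assert ensemble_fraction(x) == pytest.approx(quad_fraction(x), abs=1e-8)

    @pytest.mark.parametrize("x", [1e-3, 0.02, 0.1])
    @pytest.mark.parametrize("absorber", ["linear", "circular"])
    def test_taylor_and_quadrature_agree_at_low_power(self, x, absorber):
        assert ensemble_fraction(x, absorber, "taylor") == pytest.approx(
            ensemble_fraction(x, absorber, "quadrature"), abs=1e-6
        )

    def test_taylor_three_term_truncation_available(self):
        x = 0.05
        three = ensemble_fraction(x, method="taylor", order=3)
        expected = x - 0.9 * x**2 + (9 / 14) * x**3
        assert three == pytest.approx(expected, rel=1e-12)

    def test_taylor_beyond_radius_falls_back(self):
        with pytest.warns(UserWarning, match="Taylor radius"):
            val = ensemble_fraction(3.0, method="taylor")
        assert val == pytest.approx(ensemble_fraction(3.0), abs=1e-10)

    @settings(deadline=None, max_examples=30)
    @given(x=st.floats(1e-6, 10.0))
    def test_bounded_and_increasing(self, x):
        f = ensemble_fraction(x)
        assert 0.0 < f < 1.0
        assert ensemble_fraction(1.01 * x) > f


class TestBeamProfile:
    def test_tophat_vanishes_outside_radius(self):
        pulse = PulseParameters(**PHYTOCHROME)
        r = np.array([0.0, 50e-6, 60e-6, 61e-6, 1e-3])
        f = beam_profile_fraction(pulse, r)
        assert f[0] == f[1] == f[2] > 0
        assert f[3] == f[4] == 0.0

    def test_gaussian_centre_vs_tophat_ratio(self):
        th = PulseParameters(**PHYTOCHROME, profile="top-hat")
        ga = PulseParameters(**PHYTOCHROME, profile="gaussian")
        f_th = beam_profile_fraction(th, np.array([0.0]))[0]
        f_ga = beam_profile_fraction(ga, np.array([0.0]))[0]
        x_th = excitation_strength(th)
        assert f_ga == pytest.approx(quad_fraction(np.log(2) * x_th), abs=1e-8)
        assert f_th == pytest.approx(quad_fraction(x_th), abs=1e-8)

    def test_gaussian_fraction_monotone_decreasing(self):
        ga = PulseParameters(**PHYTOCHROME, profile="gaussian")
        r = np.linspace(0, 300e-6, 25)
        f = beam_profile_fraction(ga, r)
        assert np.all(np.diff(f) < 0)


class TestAnisotropyFactor:
    def test_low_power_limit_is_two_fifths(self):
        assert anisotropy_factor(1e-8) == pytest.approx(0.4, abs=1e-6)
        assert anisotropy_factor(0.0) == 0.4

    @pytest.mark.parametrize("x", [0.05, 0.5076, 1.0, 3.0])
    def test_matches_quadrature_oracle(self, x):
        assert anisotropy_factor(x) == pytest.approx(quad_anisotropy(x), abs=1e-6)

    def test_saturating_power_depresses_anisotropy(self):
        # five times the phytochrome working power saturates orientations
        x_work = excitation_strength(PulseParameters(**PHYTOCHROME))
        assert anisotropy_factor(5 * x_work) < 0.3

    @pytest.mark.parametrize("x", [1e-3, 0.02, 0.1])
    def test_taylor_agrees_with_quadrature_at_low_power(self, x):
        assert anisotropy_factor(x, method="taylor") == pytest.approx(
            anisotropy_factor(x, method="quadrature"), abs=1e-6
        )

    def test_three_term_series_coefficients(self):
        x = 0.03
        expected = 0.4 - (27 / 175) * x + (57 / 1750) * x**2
        assert anisotropy_factor(x, method="taylor", order=3) == pytest.approx(
            expected, rel=1e-12
        )

    def test_strictly_decreasing(self):
        xs = np.linspace(0.01, 4.0, 25)
        vals = [anisotropy_factor(x) for x in xs]
        assert np.all(np.diff(vals) < 0)


class TestMeasuredAnisotropy:
    def test_isotropic_signal_gives_zero(self):
        r, magic = measured_anisotropy(0.3, 0.3)
        assert r == 0.0
        assert magic == pytest.approx(0.3)

    def test_vanishing_perpendicular_gives_unity(self):
        r, _ = measured_anisotropy(0.5, 0.0)
        assert r == 1.0

    def test_two_to_one_ratio_hand_algebra(self):
        r, magic = measured_anisotropy(2.0, 1.0)
        assert r == pytest.approx(0.25)
        assert magic == pytest.approx(4.0 / 3.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(InfeasibleAnisotropyError):
            measured_anisotropy(2.0, -1.0)


class TestDegenerateAnisotropy:
    def test_in_plane_limit(self):
        assert anisotropy_degenerate(0.0) == pytest.approx(0.1)

    def test_out_of_plane_limit(self):
        assert anisotropy_degenerate(90.0) == pytest.approx(-0.2)

    def test_continuous_and_monotone_between_limits(self):
        angles = np.linspace(0, 90, 91)
        vals = [anisotropy_degenerate(a) for a in angles]
        assert np.all(np.diff(vals) < 0)
        assert min(vals) >= -0.2 and max(vals) <= 0.1


class TestExtractDipoleAngle:
    def test_aligned_dipoles(self):
        assert extract_dipole_angle(0.4, 0.4) == pytest.approx(0.0, abs=1e-6)

    def test_zero_anisotropy_is_magic_angle(self):
        assert extract_dipole_angle(0.0, 0.4) == pytest.approx(54.7356, abs=1e-3)

    def test_perpendicular_dipoles(self):
        assert extract_dipole_angle(-0.2, 0.4) == pytest.approx(90.0)

    def test_infeasible_ratio_raises(self):
        with pytest.raises(InfeasibleAnisotropyError):
            extract_dipole_angle(0.5, 0.4)


class TestBeamRatioCorrection:
    @pytest.mark.parametrize("R,expected", [(1.0, 0.71), (2.0, 0.89), (3.0, 0.95)])
    def test_printed_values(self, R, expected):
        assert beam_ratio_correction(R) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize("R", [0.5, 1.0, 2.0, 3.7, 10.0])
    def test_matches_gaussian_product_integral_oracle(self, R):
        """Probe-weighted pump average along a transverse axis of the 2-D
        beam-product profile, evaluated numerically."""
        s_pr = 1.0
        s_pu = R * s_pr
        y = np.linspace(-12 * s_pu, 12 * s_pu, 200001)
        pump = np.exp(-(y**2) / (2 * s_pu**2))
        probe = np.exp(-(y**2) / (2 * s_pr**2))
        oracle = np.trapezoid(pump * probe, y) / np.trapezoid(probe, y)
        assert beam_ratio_correction(R) == pytest.approx(oracle, abs=1e-4)

    def test_monotone_and_limits(self):
        rs = np.linspace(0.2, 50, 60)
        vals = [beam_ratio_correction(R) for R in rs]
        assert np.all(np.diff(vals) > 0)
        assert beam_ratio_correction(1e6) == pytest.approx(1.0, abs=1e-9)


class TestDepthAveraging:
    def test_transparent_sample_equals_surface_value(self):
        pulse = PulseParameters(**PHYTOCHROME)
        geom = SampleGeometry(absorbance=0.0, thickness=1e-4)
        x = excitation_strength(pulse)
        assert depth_average_anisotropy(pulse, geom) == pytest.approx(
            anisotropy_factor(x), abs=1e-12
        )

    def test_default_layers_match_fine_grid_oracle(self):
        pulse = PulseParameters(**PHYTOCHROME)
        for A in (0.4, 1.0, 2.0):
            coarse = depth_average_anisotropy(pulse, SampleGeometry(A, 1e-4, n_layers=200))
            fine = depth_average_anisotropy(pulse, SampleGeometry(A, 1e-4, n_layers=10000))
            assert coarse == pytest.approx(fine, abs=1e-6)

    def test_attenuation_moves_anisotropy_towards_low_power_limit(self):
        pulse = PulseParameters(**PHYTOCHROME)
        vals = [depth_average_anisotropy(pulse, SampleGeometry(A, 1e-4)) for A in (0, 0.4, 1, 2)]
        assert np.all(np.diff(vals) > 0)  # less average excitation -> closer to 0.4
        assert all(v <= 0.4 for v in vals)


class TestMultipulse:
    def test_full_recovery_reduces_to_single_pulse(self):
        p = np.linspace(0, 1, 21)
        sched = MultipulseSchedule(x1=0.8, x2=0.5, recovery=1.0)
        np.testing.assert_allclose(
            multipulse_fraction(sched, p), orientational_fraction(0.5, p), atol=1e-14
        )
        assert multipulse_fraction(sched) == pytest.approx(ensemble_fraction(0.5), abs=1e-10)

    @pytest.mark.parametrize("x", [0.0, 0.05, 0.5, 2.0, 5.0])
    def test_zero_delay_equals_single_pulse_at_doubled_power(self, x):
        p = np.linspace(0, 1, 41)
        sched = MultipulseSchedule(x1=x, x2=x, recovery=0.0)
        total = multipulse_fraction(sched, p, which="total")
        np.testing.assert_allclose(total, orientational_fraction(2 * x, p), atol=1e-10)
        assert multipulse_fraction(sched, which="total") == pytest.approx(
            ensemble_fraction(2 * x), abs=1e-10
        )

    def test_pulse_two_fraction_grows_with_recovery(self):
        x = 0.5076  # phytochrome working point
        fracs = [multipulse_fraction(MultipulseSchedule(x1=x, x2=x, recovery=G))
                 for G in (0.13, 0.64, 0.9)]
        assert np.all(np.diff(fracs) > 0)
        for G, f in zip((0.13, 0.64, 0.9), fracs):
            oracle = quad(
                lambda p: (1 - (1 - G) * (1 - np.exp(-3 * x * p * p)))
                * (1 - np.exp(-3 * x * p * p)),
                0.0, 1.0, epsabs=1e-13,
            )[0]
            assert f == pytest.approx(oracle, abs=1e-8)

    def test_invalid_recovery_rejected(self):
        with pytest.raises(ValueError):
            MultipulseSchedule(x1=0.1, x2=0.1, recovery=1.2)


class TestMultipulseAnisotropy:
    def test_reduces_to_single_pulse_curve(self):
        sched = MultipulseSchedule(x1=1e-12, x2=0.7, recovery=1.0)
        assert multipulse_anisotropy(sched) == pytest.approx(anisotropy_factor(0.7), abs=1e-9)

    def test_smaller_recovery_deviates_more(self):
        x = 0.5
        single = anisotropy_factor(x)
        devs = [abs(multipulse_anisotropy(MultipulseSchedule(x1=x, x2=x, recovery=G)) - single)
                for G in (0.9, 0.64, 0.13)]
        assert np.all(np.diff(devs) > 0)

    def test_unequal_pulse_powers_give_distinct_curves(self):
        G = 0.64
        a = multipulse_anisotropy(MultipulseSchedule(x1=1.0, x2=0.5, recovery=G))
        b = multipulse_anisotropy(MultipulseSchedule(x1=0.5, x2=0.5, recovery=G))
        assert a != pytest.approx(b, abs=1e-6)
        # quadrature oracle for the x1 = 2 x2 case
        x1, x2 = 1.0, 0.5
        f2 = lambda p: 1 - np.exp(-3 * x2 * p * p)  # noqa: E731
        avail = lambda p: 1 - (1 - G) * (1 - np.exp(-3 * x1 * p * p))  # noqa: E731
        num = quad(lambda p: avail(p) * f2(p) * 0.5 * (3 * p * p - 1), 0, 1, epsabs=1e-13)[0]
        den = quad(lambda p: avail(p) * f2(p), 0, 1, epsabs=1e-13)[0]
        assert a == pytest.approx(num / den, abs=1e-8)

    @pytest.mark.parametrize("x", [1e-3, 0.02, 0.1])
    def test_taylor_quadrature_consistency(self, x):
        sched = MultipulseSchedule(x1=x, x2=x, recovery=0.64)
        assert multipulse_anisotropy(sched, method="taylor") == pytest.approx(
            multipulse_anisotropy(sched, method="quadrature"), abs=1e-6
        )


class TestInvariants:
    @settings(deadline=None, max_examples=30)
    @given(x1=st.floats(0.0, 3.0), x2=st.floats(1e-4, 3.0), g=st.floats(0.0, 1.0))
    def test_fractions_bounded_anisotropy_in_linear_range(self, x1, x2, g):
        sched = MultipulseSchedule(x1=x1, x2=x2, recovery=g)
        f = multipulse_fraction(sched)
        assert 0.0 <= f <= 1.0
        # pulse II addresses a hole-burned, non-isotropic ground state: its
        # orientation factor is bounded by the extreme Legendre values
        # P2(0) = -1/2 and P2(1) = 1 weighted through <f P2>/<f>, not by the
        # single-pulse [-0.2, 0.4] window
        r = multipulse_anisotropy(sched)
        assert -0.5 - 1e-9 <= r <= 0.4 + 1e-9


def test_pure_intermediate_round_trip():
    from pulsedyn.kinetics import build_sequential_scheme
    from pulsedyn.synthdata import make_multipulse_experiment

    sched = MultipulseSchedule(x1=0.5, x2=0.5, recovery=0.64)
    scheme = build_sequential_scheme([0.2, 0.0])
    s_pp, s_dp, s_pdp, truth = make_multipulse_experiment(scheme, sched, seed=3)
    recovered = pure_intermediate_signal(s_pp, s_dp, s_pdp, multipulse_weights(sched))
    np.testing.assert_allclose(recovered.values, truth.values, atol=1e-12)


def test_pure_intermediate_zero_planted():
    from pulsedyn.io import DataMatrix

    t = np.linspace(0, 10, 12)
    ch = np.arange(1.0, 6.0)
    rng = np.random.default_rng(0)
    base = rng.standard_normal((12, 5))
    gs = rng.standard_normal((12, 5))
    w = multipulse_weights(MultipulseSchedule(x1=0.5, x2=0.5, recovery=0.5))
    s_pp = DataMatrix(t, ch, base)
    s_dp = DataMatrix(t, ch, gs)
    s_pdp = DataMatrix(t, ch, base + w["ground_state"] * gs)  # no intermediate term
    out = pure_intermediate_signal(s_pp, s_dp, s_pdp, w)
    np.testing.assert_allclose(out.values, 0.0, atol=1e-12)


def test_pure_intermediate_axis_mismatch_rejected():
    from pulsedyn.io import DataMatrix

    t = np.linspace(0, 10, 12)
    ch = np.arange(1.0, 6.0)
    a = DataMatrix(t, ch, np.zeros((12, 5)))
    b = DataMatrix(t + 1.0, ch, np.zeros((12, 5)))
    with pytest.raises(ValueError):
        pure_intermediate_signal(a, b, a, {"ground_state": 1.0, "intermediate": 0.5})
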