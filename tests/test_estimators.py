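"""Tests for the Kasai and complex-regression estimators.

The regression estimator carries an exact algebraic identity (its
dispersion objective equals total power minus coherent-sum power because
derotation preserves moduli), which supplies an independent brute-force
oracle for the fast search path.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from doppleroct import (EstimatorSpec, MScan, UndefinedPhaseError,
                        complex_average, complex_dispersion,
                        complex_regression_phase, conventional_doppler,
                        doppler_image, kasai_phase, phase_to_velocity, realign,
                        theta_grid)

finite_complex = st.complex_numbers(min_magnitude=0.0, max_magnitude=10.0,
                                    allow_nan=False, allow_infinity=False)


def tone(theta, m=64, amplitudes=None):
    k = np.arange(m)
    amp = 1.0 if amplitudes is None else np.asarray(amplitudes)
    return amp * np.exp(1j * theta * k)


class TestKasaiPhase:
    def test_quarter_turn(self):
        assert kasai_phase([1.0, 1j]) == pytest.approx(math.pi / 2)

    @pytest.mark.parametrize("n", [2, 5, 64])
    def test_constant_rotation_any_length(self, n):
        assert kasai_phase(tone(0.1, n)) == pytest.approx(0.1)

    def test_amplitude_weighted_two_pair_oracle(self):
        # a 3-point window whose lag-one products are 4*e^{i0.2} and
        # 1*e^{i0.4}: the estimate is arg(4e^{i0.2} + e^{i0.4}), frozen
        # from direct complex arithmetic — amplitude weighting pulls the
        # answer toward the stronger pair's 0.2 rad.
        window = np.array([2.0, 2.0 * np.exp(0.2j), 0.5 * np.exp(0.6j)])
        products = window[1:] * np.conj(window[:-1])
        assert products == pytest.approx(np.array([4 * np.exp(0.2j),
                                                   np.exp(0.4j)]))
        assert kasai_phase(window) == pytest.approx(0.2398717643307836,
                                                    abs=1e-12)

    def test_all_zero_window_is_flagged(self):
        with pytest.raises(UndefinedPhaseError):
            kasai_phase(np.zeros(8, dtype=complex))

    def test_too_short_window(self):
        with pytest.raises(ValueError):
            kasai_phase([1.0 + 0j])


class TestRealign:
    @given(st.lists(finite_complex, min_size=2, max_size=32),
           st.floats(-math.pi, math.pi))
    def test_moduli_preserved(self, values, theta):
        window = np.array(values)
        assert np.abs(realign(window, theta)) == pytest.approx(np.abs(window))

    def test_zero_theta_is_identity(self):
        window = tone(0.3, 16)
        assert realign(window, 0.0) == pytest.approx(window)

    @given(st.floats(-3.0, 3.0))
    def test_perfect_alignment_of_pure_tone(self, theta):
        aligned = realign(tone(theta, 32), theta)
        assert aligned == pytest.approx(np.ones(32, dtype=complex), abs=1e-9)


class TestComplexDispersion:
    def test_identical_points_zero(self):
        assert complex_dispersion(np.full(10, 2.0 + 1.0j)) == 0.0

    def test_antipodal_unit_points(self):
        assert complex_dispersion([1.0 + 0j, -1.0 + 0j]) == pytest.approx(1.0)

    @given(st.lists(finite_complex, min_size=2, max_size=32))
    def test_power_identity(self, values):
        z = np.array(values)
        expected_sq = np.mean(np.abs(z) ** 2) - np.abs(z.mean()) ** 2
        assert complex_dispersion(z) ** 2 == pytest.approx(
            max(expected_sq, 0.0), abs=1e-9)


class TestComplexRegression:
    def test_noiseless_tone_exact_recovery_no_wrap(self):
        est = complex_regression_phase(tone(0.100, 64))
        assert est.theta_rad == pytest.approx(0.100, abs=1e-12)
        assert est.delta_phi_rad == pytest.approx(6.300, abs=1e-10)
        assert est.delta_phi_rad > 2 * math.pi  # accumulates beyond one turn
        assert est.dispersion == pytest.approx(0.0, abs=1e-9)

    def test_amplitude_invariant_for_noiseless_tone(self, rng):
        amps = rng.uniform(0.2, 5.0, 64)
        est = complex_regression_phase(tone(0.250, 64, amps))
        assert est.theta_rad == pytest.approx(0.250, abs=1e-12)

    @pytest.mark.parametrize("theta", [-3.141, -1.5, 0.5, 3.0, 3.141])
    def test_total_phase_up_to_63_pi(self, theta):
        est = complex_regression_phase(tone(theta, 64))
        assert est.theta_rad == pytest.approx(theta, abs=1e-12)
        assert est.delta_phi_rad == pytest.approx(63 * theta, rel=1e-12)

    def test_tie_break_prefers_zero_for_constant_window(self):
        est = complex_regression_phase(np.ones(16, dtype=complex))
        assert est.theta_rad == 0.0

    def test_fast_path_matches_bruteforce_dispersion_search(self, rng):
        for _ in range(5):
            window = (rng.standard_normal(16) + 1j * rng.standard_normal(16))
            fast = complex_regression_phase(window, grid_step=0.01)
            brute = complex_regression_phase(window, grid_step=0.01,
                                             method="bruteforce")
            assert fast.theta_rad == brute.theta_rad
            assert fast.dispersion == pytest.approx(brute.dispersion, abs=1e-9)

    def test_fast_path_matches_bruteforce_at_default_grid(self, rng):
        window = tone(0.007, 64) + 0.1 * (rng.standard_normal(64)
                                          + 1j * rng.standard_normal(64))
        fast = complex_regression_phase(window)
        brute = complex_regression_phase(window, method="bruteforce")
        assert fast.theta_rad == brute.theta_rad

    def test_dispersion_argmin_equals_coherent_argmax(self, rng):
        # the central identity: minimizing the std of realigned points ==
        # maximizing the coherent-sum magnitude, checked point-by-point.
        window = (rng.standard_normal(24) + 1j * rng.standard_normal(24))
        grid = theta_grid(0.02)
        disp = np.array([complex_dispersion(realign(window, t)) for t in grid])
        coh = np.array([np.abs(np.mean(realign(window, t))) for t in grid])
        assert np.allclose(disp ** 2, np.mean(np.abs(window) ** 2) - coh ** 2,
                           atol=1e-12)
        assert np.argmin(disp) == np.argmax(coh)

    def test_agrees_with_kasai_at_high_snr(self, rng):
        # SNR 30 dB, theta 0.1: both estimators see the same tone.
        window = tone(0.1, 64) + math.sqrt(1e-3 / 2) * (
            rng.standard_normal(64) + 1j * rng.standard_normal(64))
        reg = complex_regression_phase(window).theta_rad
        kas = kasai_phase(window)
        assert abs(reg - kas) <= 2e-3

    def test_zero_window_flagged(self):
        with pytest.raises(UndefinedPhaseError):
            complex_regression_phase(np.zeros(8, dtype=complex))

    def test_grid_contract(self):
        grid = theta_grid(1e-3)
        assert grid[0] > -math.pi  # half-open at -pi
        assert grid[-1] == math.pi
        assert 0.0 in grid
        with pytest.raises(ValueError):
            theta_grid(4.0)


class TestConventionalDoppler:
    def make_scan(self, theta, T=70):
        return MScan(samples=tone(theta, T)[:, None], aline_interval_s=594e-9)

    def test_noiseless_rotation(self):
        est = conventional_doppler(self.make_scan(0.05), depth=0,
                                   window_start=0, n_averages=5)
        assert est.theta_rad == pytest.approx(0.05)
        assert est.delta_phi_rad == est.theta_rad  # single-interval semantics
        assert est.n_points == 6

    def test_out_of_bounds_window(self):
        scan = self.make_scan(0.05, T=10)
        with pytest.raises(IndexError):
            conventional_doppler(scan, depth=0, window_start=6, n_averages=5)

    def test_averaging_noise_reduction_telescopes(self, rng):
        """Overlapping-pair averaging reduces noise ~1/N, not 1/sqrt(N).

        The summed lag-one products of a static signal with i.i.d.
        complex noise telescope: interior noise terms cancel and only
        the endpoint A-lines contribute, so the Monte-Carlo std ratio
        std(N)/std(1) tracks 1/N (with a small noise-noise correction),
        far below the 1/sqrt(N) of independent pair measurements.
        """
        sigma = math.sqrt(1 / 108.5 / 2)  # the calibrated-phantom noise level
        reps = 4000
        stds = {}
        for n_avg in (1, 5, 63):
            s = 1.0 + sigma * (rng.standard_normal((reps, n_avg + 1))
                               + 1j * rng.standard_normal((reps, n_avg + 1)))
            acc = np.sum(s[:, 1:] * np.conj(s[:, :-1]), axis=1)
            stds[n_avg] = np.angle(acc).std()
        assert stds[5] / stds[1] == pytest.approx(1 / 5, rel=0.15)
        assert stds[63] / stds[1] == pytest.approx(0.0183, rel=0.25)
        assert stds[63] / stds[1] < 0.5 / math.sqrt(63)


class TestDopplerImage:
    def test_full_scale_window_count(self, config):
        scan = MScan(samples=tone(0.02, 16000)[:, None], aline_interval_s=594e-9)
        vmap = doppler_image(scan, EstimatorSpec("complex_regression", 64),
                             config=config)
        assert vmap.n_windows == 250

    def test_uniform_rotation_gives_constant_map(self, config):
        scan = MScan(samples=np.tile(tone(0.05, 256)[:, None], (1, 3)),
                     aline_interval_s=594e-9)
        for kind, n in (("complex_regression", 64), ("conventional_avg", 5)):
            vmap = doppler_image(scan, EstimatorSpec(kind, n), config=config)
            expected = phase_to_velocity(0.05, config)
            assert vmap.axial_velocity == pytest.approx(expected, rel=1e-9)

    def test_static_scan_gives_zero_map(self, config):
        scan = MScan(samples=np.ones((256, 2), dtype=complex),
                     aline_interval_s=594e-9)
        vmap = doppler_image(scan, EstimatorSpec("complex_regression", 64),
                             config=config)
        assert np.all(vmap.axial_velocity == 0.0)

    def test_window_longer_than_scan_rejected(self, config):
        scan = MScan(samples=np.ones((32, 1), dtype=complex),
                     aline_interval_s=594e-9)
        with pytest.raises(ValueError):
            doppler_image(scan, EstimatorSpec("complex_regression", 64),
                          window_length=64, config=config)

    def test_stride_controls_overlap(self, config):
        scan = MScan(samples=tone(0.01, 256)[:, None], aline_interval_s=594e-9)
        vmap = doppler_image(scan, EstimatorSpec("complex_regression", 64),
                             stride=32, config=config)
        assert vmap.n_windows == (256 - 64) // 32 + 1


class TestComplexAverage:
    def test_identical_alines_unchanged(self):
        samples = np.tile((1.0 + 2.0j), (12, 3))
        assert complex_average(samples, 4) == pytest.approx(samples[:3])

    def test_destructive_interference(self):
        out = complex_average(np.array([1.0 + 0j, np.exp(1j * math.pi)]), 2)
        assert abs(out[0]) == pytest.approx(0.0, abs=1e-15)

    def test_noise_power_reduced_by_group_size(self, rng):
        group = 8
        noise = 0.5 * (rng.standard_normal((4000, 4))
                       + 1j * rng.standard_normal((4000, 4)))
        out = complex_average(1.0 + noise, group)
        ratio = np.mean(np.abs(out - 1.0) ** 2) / np.mean(np.abs(noise) ** 2)
        assert ratio == pytest.approx(1 / group, rel=0.15)

    def test_trailing_remainder_dropped(self):
        out = complex_average(np.arange(10, dtype=complex), 4)
        assert out.shape == (2,)
        assert out[0] == pytest.approx(1.5)

    def test_invalid_group(self):
        with pytest.raises(ValueError):
            complex_average(np.ones(4, dtype=complex), 0)
        with pytest.raises(ValueError):
            complex_average(np.ones(4, dtype=complex), 5)
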