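"""Phase-amplitude coupling: filtering, histogram, MI, comodulogram, surrogates."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from mazelfp.crossfreq import (
    BandGrid,
    PhaseAmpDistribution,
    bandpass_zero_phase,
    comodulogram,
    modulation_index,
    phase_amplitude_histogram,
    phase_and_envelope,
    surrogate_zscores,
)
from mazelfp.synthetic import CouplingSpec, generate_coupled_process, generate_coupled_signal

FS = 1000.0


def _dist(weights):
    w = np.asarray(weights, float)
    return PhaseAmpDistribution(w, np.linspace(-np.pi, np.pi, w.size + 1))


def _brute_force_mi(weights):
    """Independent entropy oracle: plain loop, no shared code path."""
    import math

    h = 0.0
    for p in weights:
        if p > 0:
            h -= p * math.log(p)
    return (math.log(len(weights)) - h) / math.log(len(weights))


class TestBandpass:
    def test_in_band_tone_amplitude_and_phase_preserved(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 8.0 * t)
        y = bandpass_zero_phase(x, FS, 7.0, 9.0)
        interior = slice(int(6 * FS), int(24 * FS))  # clear of filter edges
        amp = np.max(np.abs(y[interior]))
        assert amp == pytest.approx(1.0, abs=0.05)
        # zero-phase: cross-correlation peaks at zero lag
        lags = np.arange(-50, 51)
        xc = [np.dot(x[interior], np.roll(y, k)[interior]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_out_of_band_tone_strongly_attenuated(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 8.0 * t)
        y = bandpass_zero_phase(x, FS, 50.0, 70.0)
        assert np.sqrt(np.mean(y**2)) < 0.01 * np.sqrt(np.mean(x**2))

    def test_zero_in_zero_out(self):
        assert np.all(bandpass_zero_phase(np.zeros(5000), FS, 5.0, 12.0) == 0.0)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_zero_phase(np.zeros(5000), FS, 400.0, 600.0)


class TestPhaseAndEnvelope:
    def test_sinusoid_envelope_near_constant_amplitude(self):
        t = np.arange(int(10 * FS)) / FS
        _, env = phase_and_envelope(3.0 * np.sin(2 * np.pi * 8.0 * t))
        interior = env[int(FS) : -int(FS)]
        np.testing.assert_allclose(interior, 3.0, rtol=0.02)
        assert np.all(env >= 0.0)

    def test_phase_advances_at_signal_frequency(self):
        t = np.arange(int(4 * FS)) / FS
        phase, _ = phase_and_envelope(np.sin(2 * np.pi * 8.0 * t))
        dphi = np.angle(np.exp(1j * np.diff(phase[int(FS) : -int(FS)])))
        np.testing.assert_allclose(dphi, 2 * np.pi * 8.0 / FS, rtol=0.02)

    def test_cosine_peak_has_zero_phase(self):
        # Phase convention: analytic-signal angle is 0 at the peak of a
        # cosine-aligned oscillation and +/- pi at its trough.
        t = np.arange(int(4 * FS)) / FS
        phase, _ = phase_and_envelope(np.cos(2 * np.pi * 5.0 * t))
        period = int(FS / 5.0)
        peaks = np.arange(2 * period, 3500, period)  # cosine maxima, away from edges
        assert np.max(np.abs(phase[peaks])) < 0.05
        troughs = peaks + period // 2
        assert np.min(np.abs(phase[troughs])) > np.pi - 0.05


class TestHistogram:
    def test_uniform_coverage_gives_uniform_weights(self):
        phase = np.linspace(-np.pi, np.pi, 18 * 200, endpoint=False)
        dist = phase_amplitude_histogram(phase, np.ones_like(phase))
        np.testing.assert_allclose(dist.weights, 1.0 / 18.0, atol=1e-12)

    def test_single_bin_concentration(self):
        phase = np.full(50, -np.pi + 5.5 * (2 * np.pi / 18))  # inside bin 5
        amp = np.ones(50)
        dist = phase_amplitude_histogram(phase, amp)
        assert dist.weights[5] == 1.0
        assert dist.weights.sum() == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # 36 samples, 2 per bin center, all amplitude 1 except one sample of
        # 19 in bin 3: that bin sums to 20 of a grand total 54.
        centers = -np.pi + (np.arange(18) + 0.5) * (2 * np.pi / 18)
        phase = np.repeat(centers, 2)
        amp = np.ones(36)
        amp[np.flatnonzero(np.repeat(np.arange(18), 2) == 3)[0]] = 19.0
        dist = phase_amplitude_histogram(phase, amp)
        assert dist.weights[3] == pytest.approx(20.0 / 54.0)
        others = np.delete(dist.weights, 3)
        np.testing.assert_allclose(others, 2.0 / 54.0)

    def test_phase_pi_wraps_to_bin_zero(self):
        dist = phase_amplitude_histogram(np.array([np.pi, -np.pi]), np.ones(2))
        assert dist.weights[0] == 1.0

    def test_all_zero_amplitude_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            phase_amplitude_histogram(np.zeros(10), np.zeros(10))


class TestModulationIndex:
    def test_uniform_is_zero(self):
        assert modulation_index(_dist(np.full(18, 1 / 18))) == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_is_one(self):
        w = np.zeros(18)
        w[4] = 1.0
        assert modulation_index(_dist(w)) == pytest.approx(1.0)

    def test_half_split_matches_closed_form(self):
        w = np.zeros(18)
        w[0] = w[9] = 0.5
        expected = 1.0 - np.log(2.0) / np.log(18.0)
        assert modulation_index(_dist(w)) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=36))
    def test_matches_brute_force_oracle_and_stays_in_unit_interval(self, raw):
        w = np.asarray(raw) / np.sum(raw)
        mi = modulation_index(_dist(w))
        assert 0.0 <= mi <= 1.0
        assert mi == pytest.approx(_brute_force_mi(w), abs=1e-12)

    def test_oracle_equivalence_over_many_simplex_draws(self):
        rng = np.random.default_rng(0)
        draws = rng.dirichlet(np.full(18, 0.4), size=10_000)
        for w in draws[::500]:  # spot-check brute force on a subsample
            assert modulation_index(_dist(w)) == pytest.approx(_brute_force_mi(w), abs=1e-12)
        mis = np.array([modulation_index(_dist(w)) for w in draws[:2000]])
        assert np.all((mis >= 0.0) & (mis <= 1.0))

    def test_invariant_to_bin_relabeling(self):
        rng = np.random.default_rng(1)
        w = rng.dirichlet(np.ones(18))
        base = modulation_index(_dist(w))
        for shift in (1, 5, 9):
            assert modulation_index(_dist(np.roll(w, shift))) == pytest.approx(base, abs=1e-14)

    def test_log_base_cancels(self):
        # MI computed with log2 equals MI computed with ln.
        rng = np.random.default_rng(2)
        w = rng.dirichlet(np.ones(18))
        h2 = -np.sum(w * np.log2(w))
        mi_log2 = (np.log2(18) - h2) / np.log2(18)
        assert modulation_index(_dist(w)) == pytest.approx(mi_log2, abs=1e-12)

    def test_amplitude_scale_invariance_through_histogram(self):
        rng = np.random.default_rng(3)
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = rng.gamma(2.0, 1.0, 5000) * (1 + np.cos(phase))
        a = modulation_index(phase_amplitude_histogram(phase, amp))
        b = modulation_index(phase_amplitude_histogram(phase, 123.4 * amp))
        assert a == pytest.approx(b, abs=1e-14)


class TestComodulogram:
    def test_deterministic_coupling_peaks_at_true_cell(self):
        spec = CouplingSpec(coupling_strength=0.8, f_theta=8.0, f_gamma=60.0)
        rec = generate_coupled_signal(spec, 60.0, FS, seed=1)
        com = comodulogram(rec.samples[0], rec.samples[0], FS)
        fp, fa = com.argmax_freqs()
        assert abs(fp - 8.0) <= 1.0
        assert abs(fa - 60.0) <= 5.0

    def test_self_pairing_matches_duplicated_channel(self, coupled_recording):
        x = coupled_recording.samples[0][: int(20 * FS)]
        a = comodulogram(x, x, FS)
        b = comodulogram(x, x.copy(), FS)
        np.testing.assert_allclose(a.mi, b.mi, atol=1e-14)

    def test_insufficient_clean_data_rejected(self, coupled_recording):
        x = coupled_recording.samples[0][: int(20 * FS)]
        clean = np.zeros(x.size, dtype=bool)
        clean[: int(2 * FS)] = True  # < 10 cycles of the 2 Hz band
        with pytest.raises(ValueError, match="clean samples"):
            comodulogram(x, x, FS, clean=clean)

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="above 0"):
            BandGrid(phase_freqs=(0.5,))
        with pytest.raises(ValueError, match="below the amplitude"):
            BandGrid(phase_freqs=(2.0, 25.0))


class TestSurrogates:
    def test_same_seed_gives_identical_z(self, coupled_recording):
        x = coupled_recording.samples[0][: int(20 * FS)]
        grid = BandGrid(phase_freqs=(6.0, 8.0), amp_freqs=(40.0, 60.0))
        a = surrogate_zscores(x, x, FS, grid, n_surrogates=20, seed=5)
        b = surrogate_zscores(x, x, FS, grid, n_surrogates=20, seed=5)
        np.testing.assert_array_equal(a.z, b.z)

    def test_coupled_cell_strongly_significant(self, coupled_recording):
        x = coupled_recording.samples[0]
        grid = BandGrid(phase_freqs=(6.0, 8.0, 10.0), amp_freqs=(40.0, 60.0, 80.0))
        zc = surrogate_zscores(x, x, FS, grid, n_surrogates=100, seed=6)
        assert zc.z[grid.amp_freqs.index(60.0), grid.phase_freqs.index(8.0)] > 3.0

    def test_null_z_consistent_with_standard_normal(self):
        # Phase from one realization, amplitude from an independent one:
        # z over the grid should look standard normal in most runs.
        grid = BandGrid(phase_freqs=(4.0, 6.0, 8.0, 10.0), amp_freqs=(40.0, 60.0, 80.0, 100.0))
        passing = 0
        for run in range(10):
            xa = generate_coupled_process(
                CouplingSpec(coupling_strength=0.0), 30.0, FS, seed=100 + run
            ).samples[0]
            xb = generate_coupled_process(
                CouplingSpec(coupling_strength=0.0), 30.0, FS, seed=200 + run
            ).samples[0]
            zc = surrogate_zscores(xa, xb, FS, grid, n_surrogates=100, seed=run)
            if sps.kstest(zc.z.ravel(), "norm").pvalue > 0.01:
                passing += 1
        assert passing >= 8

    def test_too_short_signal_for_shifts_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            surrogate_zscores(np.zeros(1500) + np.sin(np.arange(1500)), np.ones(1500), FS,
                              BandGrid(phase_freqs=(8.0,), amp_freqs=(60.0,)))
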