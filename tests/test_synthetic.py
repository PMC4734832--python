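"""Ground-truth generator: formulas, determinism, spectral content, artifacts."""

import numpy as np
import pytest

from mazelfp.spectral import multitaper_coherence, multitaper_psd, peak_in_band
from mazelfp.synthetic import (
    ArtifactSpec,
    CouplingSpec,
    SessionSpec,
    generate_coupled_process,
    generate_coupled_signal,
    generate_session,
    inject_artifacts,
    pink_noise,
)


class TestCoupledSignal:
    def test_full_coupling_envelope_endpoints(self):
        # c = 1, no noise: gamma vanishes where cos(theta phase) = -1 and
        # reaches gamma_amp where cos = +1.
        spec = CouplingSpec(
            f_theta=8.0, f_gamma=64.0, coupling_strength=1.0,
            theta_amp=0.0, gamma_amp=1.0, noise_amp=0.0,
        )
        fs = 1024.0
        rec = generate_coupled_signal(spec, duration=2.0, fs=fs, seed=0)
        t = np.arange(rec.n_samples) / fs
        env = np.abs(rec.samples[0]) / np.abs(np.sin(2 * np.pi * 64.0 * t) + 1e-300)
        trough = np.argmin(np.abs(t - 1.0 / 16.0))  # cos(2 pi 8 t) = -1 at t = 1/16
        assert abs(rec.samples[0][trough]) < 1e-6
        peak_region = np.abs(np.cos(2 * np.pi * 8.0 * t) - 1.0) < 1e-3
        assert np.max(env[peak_region]) == pytest.approx(1.0, abs=0.01)

    def test_zero_coupling_gives_constant_envelope(self):
        spec = CouplingSpec(coupling_strength=0.0, theta_amp=0.0, noise_amp=0.0, gamma_amp=1.0)
        rec = generate_coupled_signal(spec, 2.0, 1000.0, seed=0)
        t = np.arange(rec.n_samples) / 1000.0
        np.testing.assert_allclose(
            rec.samples[0], np.sin(2 * np.pi * spec.f_gamma * t), atol=1e-12
        )

    def test_aliasing_gamma_rejected(self):
        with pytest.raises(ValueError, match="alias"):
            generate_coupled_signal(CouplingSpec(f_gamma=600.0), 1.0, 1000.0, seed=0)

    def test_deterministic_given_seed(self):
        a = generate_coupled_signal(CouplingSpec(), 5.0, 500.0, seed=42)
        b = generate_coupled_signal(CouplingSpec(), 5.0, 500.0, seed=42)
        np.testing.assert_array_equal(a.samples, b.samples)

    @pytest.mark.parametrize("gen", [generate_coupled_signal, generate_coupled_process])
    def test_psd_peaks_at_theta_and_gamma(self, gen):
        spec = CouplingSpec(theta_amp=2.0, gamma_amp=1.0, noise_amp=0.2)
        rec = gen(spec, 30.0, 1000.0, seed=3)
        psd = multitaper_psd(rec.samples[0], 1000.0)
        theta_peak = peak_in_band(psd, (5.0, 12.0))
        assert theta_peak.freq == pytest.approx(spec.f_theta, abs=1.0)
        gamma_peak = peak_in_band(psd, (40.0, 80.0))
        assert gamma_peak.freq == pytest.approx(spec.f_gamma, abs=2.0)

    def test_pink_noise_spectral_slope(self):
        # log-log slope of the PSD should be about -alpha.
        rng = np.random.default_rng(0)
        x = np.mean(
            [np.abs(np.fft.rfft(pink_noise(2**14, 1000.0, 1.5, rng))) ** 2 for _ in range(20)],
            axis=0,
        )
        f = np.fft.rfftfreq(2**14, 1e-3)
        sel = (f > 1.0) & (f < 100.0)
        slope = np.polyfit(np.log(f[sel]), np.log(x[sel]), 1)[0]
        assert slope == pytest.approx(-1.5, abs=0.2)


class TestInjectArtifacts:
    def test_zero_rate_is_identity(self):
        rec = generate_coupled_signal(CouplingSpec(), 10.0, 500.0, seed=0)
        out, gt = inject_artifacts(rec, ArtifactSpec(rate=0.0), seed=1)
        np.testing.assert_array_equal(out.samples, rec.samples)
        assert gt.artifact_intervals == {"ch0": []}

    def test_total_artifact_time_matches_rate(self):
        # rate * duration_mean = 0.15 over 100 s -> ~15 s, Poisson spread.
        spec = ArtifactSpec(rate=0.2, duration_mean=0.75, burst_amp_factor=10.0)
        totals = []
        for seed in range(10):
            rec = generate_coupled_signal(CouplingSpec(), 100.0, 1000.0, seed=seed)
            _, gt = inject_artifacts(rec, spec, seed=seed + 50)
            totals.append(sum(b - a for a, b in gt.artifact_intervals["ch0"]))
        assert np.mean(totals) == pytest.approx(15.0, abs=4.0)

    def test_burst_windows_much_louder_than_clean(self):
        rec = generate_coupled_signal(CouplingSpec(), 60.0, 1000.0, seed=2)
        spec = ArtifactSpec(rate=0.1, duration_mean=1.0, burst_amp_factor=10.0)
        dirty, gt = inject_artifacts(rec, spec, seed=3)
        truth = np.zeros(dirty.n_samples, dtype=bool)
        for a, b in gt.artifact_intervals["ch0"]:
            truth[int(a * 1000) : int(b * 1000)] = True
        assert truth.any() and (~truth).any()
        rms_burst = np.sqrt(np.mean(dirty.samples[0][truth] ** 2))
        rms_clean = np.sqrt(np.mean(dirty.samples[0][~truth] ** 2))
        assert rms_burst >= 5.0 * rms_clean

    def test_intervals_merged_and_in_bounds(self):
        rec = generate_coupled_signal(CouplingSpec(), 30.0, 500.0, seed=4)
        _, gt = inject_artifacts(rec, ArtifactSpec(rate=0.5, duration_mean=1.0), seed=5)
        ivs = gt.artifact_intervals["ch0"]
        for (a, b), (c, d) in zip(ivs, ivs[1:]):
            assert b < c  # merged: no touching/overlapping intervals remain
        assert all(0 <= a < b <= 30.0 for a, b in ivs)


class TestGenerateSession:
    def test_event_table_layout(self, small_session):
        spec, (rec, events, _) = small_session
        assert events.trial_ids == [1, 2]
        for tid in events.trial_ids:
            start = events.time_of(tid, "trial_start")
            reach = events.time_of(tid, "platform_reach")
            assert reach - start == pytest.approx(10.0)
        assert rec.duration == pytest.approx(30.0 + 2 * (10.0 + 10.0))

    def test_same_seed_bit_identical(self):
        spec = SessionSpec(pre_maze_duration=10.0, n_trials=1, trial_durations=6.0,
                           platform_duration=5.0, seed=9)
        a = generate_session(spec)[0]
        b = generate_session(spec)[0]
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_unit_coherence_target_measured_above_095(self):
        spec = SessionSpec(
            pre_maze_duration=40.0, n_trials=1, trial_durations=6.0,
            platform_duration=5.0, theta_coherence=1.0, seed=13,
        )
        rec, _, _ = generate_session(spec)
        windows = [(s, s + 2000) for s in range(0, 38000, 1000)]
        coh = multitaper_coherence(rec.samples[0], rec.samples[1], 1000.0, windows=windows)
        assert peak_in_band(coh, (5.0, 12.0)).value > 0.95

    def test_trial_duration_mismatch_rejected(self):
        with pytest.raises(ValueError, match="trial durations"):
            SessionSpec(n_trials=3, trial_durations=(10.0, 10.0)).resolved_trial_durations()
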