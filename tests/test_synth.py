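"""Generator contracts: determinism, beat placement, spectral fidelity,
ectopic injection and cohort structure."""

import numpy as np
import numpy.testing as npt
import pytest

import cardiocoh as cc
from cardiocoh.errors import ConfigurationError


def _quiet_config(**kw):
    base = dict(duration_s=60.0, mean_rr_ms=1000.0, rsa_amp_ms=0.0,
                breath_jitter_sd_hz=0.0, noise_sd_ms=0.0, resp_noise_sd=0.0,
                seed=1)
    base.update(kw)
    return cc.SynthConfig(**base)


class TestGenerateRR:
    def test_constant_rate_degenerate_case(self):
        rr = cc.generate_rr_series(_quiet_config())
        assert rr.n_beats == 61
        npt.assert_allclose(np.diff(rr.beat_times), 1.0, atol=1e-12)
        assert rr.beat_times[0] == 0.0 and rr.beat_times[-1] == 60.0

    def test_same_seed_identical_different_seed_differs(self):
        cfg = cc.guided_config(seed=5)
        a = cc.generate_rr_series(cfg)
        b = cc.generate_rr_series(cc.guided_config(seed=5))
        npt.assert_array_equal(a.beat_times, b.beat_times)
        c = cc.generate_rr_series(cc.guided_config(seed=6))
        assert not np.array_equal(a.beat_times, c.beat_times)

    def test_beat_count_conservation_without_modulation(self):
        for mean_rr in (700.0, 850.0, 1000.0):
            cfg = _quiet_config(mean_rr_ms=mean_rr, duration_s=120.0)
            rr = cc.generate_rr_series(cfg)
            expected = 120.0 * 1000.0 / mean_rr
            assert abs((rr.n_beats - 1) - expected) <= 1

    def test_guided_dominant_frequency_matches_dense_fft_oracle(self):
        # jitter = noise = 0: RR(t) is an exact sinusoid; the oracle is the
        # FFT of the analytic RR(t) sampled densely, independent of the
        # beat-placement path.
        cfg = _quiet_config(duration_s=300.0, mean_rr_ms=850.0, rsa_amp_ms=60.0,
                            breath_freq_hz=0.1)
        fs_dense = 8.0
        t = np.arange(0, 300.0, 1 / fs_dense)
        analytic = 850.0 + 60.0 * np.sin(2 * np.pi * 0.1 * t)
        spec = np.abs(np.fft.rfft(analytic - analytic.mean())) ** 2
        freqs = np.fft.rfftfreq(t.size, 1 / fs_dense)
        f_oracle = freqs[np.argmax(spec)]
        assert abs(f_oracle - 0.1) < 0.005

        rr = cc.generate_rr_series(cfg)
        tach = cc.smoothness_priors_detrend(cc.resample_tachogram(rr))
        peak = cc.main_peak(cc.compute_psd(tach), cc.Band())
        assert abs(peak.location - f_oracle) <= 0.001

    def test_spectral_fidelity_of_modulation_lines(self):
        # with jitter = noise = 0, >= 95% of mean-removed variance must sit
        # within +/-0.01 Hz of the RSA and Mayer lines (dense-sampling FFT)
        cfg = _quiet_config(duration_s=600.0, mean_rr_ms=850.0, rsa_amp_ms=50.0,
                            breath_freq_hz=0.25, mayer_amp_ms=25.0,
                            mayer_freq_hz=0.1)
        from cardiocoh.synth import _instantaneous_rr_ms, _GRID_DT
        dense = _instantaneous_rr_ms(cfg)
        x = dense - dense.mean()
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(x.size, _GRID_DT)
        near = ((np.abs(freqs - 0.25) <= 0.01) | (np.abs(freqs - 0.1) <= 0.01))
        assert spec[near].sum() / spec.sum() >= 0.95

    def test_invariant_violations_name_offending_field(self):
        with pytest.raises(ConfigurationError, match="duration_s"):
            cc.SynthConfig(duration_s=-1.0)
        with pytest.raises(ConfigurationError, match="breath_freq_hz"):
            cc.SynthConfig(breath_freq_hz=0.6)
        with pytest.raises(ConfigurationError, match="rsa_amp_ms"):
            cc.SynthConfig(mean_rr_ms=100.0, rsa_amp_ms=90.0, noise_sd_ms=10.0)


class TestRespSignal:
    def test_pure_sine_cycles_all_ten_seconds(self):
        cfg = _quiet_config(duration_s=300.0, breath_freq_hz=0.1)
        resp = cc.generate_resp_signal(cfg, fs=1.0)
        assert resp.samples.size == 300
        cycles = cc.detect_resp_cycles(resp)
        npt.assert_allclose(cycles.cycle_durations, 10.0, atol=1e-9)

    def test_low_snr_flagged_unusable(self):
        cfg = _quiet_config(duration_s=300.0, breath_freq_hz=0.1,
                            resp_amp=1.0, resp_noise_sd=3.0)
        resp = cc.generate_resp_signal(cfg, fs=1.0)
        with pytest.raises(cc.UnusableSeriesError):
            cc.detect_resp_cycles(resp)

    def test_seed_reproducibility(self):
        cfg = cc.guided_config(seed=9)
        a = cc.generate_resp_signal(cfg, fs=4.0)
        b = cc.generate_resp_signal(cc.guided_config(seed=9), fs=4.0)
        npt.assert_array_equal(a.samples, b.samples)

    def test_shares_breathing_phase_with_rr(self):
        # same config: belt crests must align with RSA crests of the RR model
        cfg = cc.guided_config(seed=3, noise_sd_ms=0.0, resp_noise_sd=0.0)
        from cardiocoh.synth import _instantaneous_rr_ms, _grid_size, _GRID_DT
        resp = cc.generate_resp_signal(cfg, fs=4.0)
        rr_dense = _instantaneous_rr_ms(cfg)[:resp.samples.size]
        rsa = (rr_dense - cfg.mean_rr_ms) / cfg.rsa_amp_ms
        npt.assert_allclose(resp.samples, rsa, atol=1e-9)

    def test_sub_hertz_sampling_rejected(self):
        with pytest.raises(ConfigurationError, match="fs"):
            cc.generate_resp_signal(_quiet_config(), fs=0.5)


class TestInjectEctopics:
    def test_zero_rate_is_noop(self):
        rr = cc.RRSeries.from_intervals(np.full(100, 1000.0))
        out, idx = cc.inject_ectopics(rr, 0.0, seed=1)
        npt.assert_array_equal(out.rr_ms, rr.rr_ms)
        assert idx.size == 0

    def test_event_shape_is_early_beat_plus_pause(self):
        rr = cc.RRSeries.from_intervals(np.full(200, 1000.0))
        out, idx = cc.inject_ectopics(rr, 1.0, seed=7)
        assert idx.size > 0
        for k in idx:
            assert out.rr_ms[k] == pytest.approx(600.0)
            assert out.rr_ms[k + 1] == pytest.approx(1400.0)
        untouched = np.setdiff1d(np.arange(200), np.concatenate([idx, idx + 1]))
        npt.assert_array_equal(out.rr_ms[untouched], 1000.0)
        # pair total preserved exactly -> overall duration unchanged
        assert out.duration_s == pytest.approx(rr.duration_s)

    def test_poisson_consistent_event_count(self):
        rr = cc.RRSeries.from_intervals(np.full(360, 1000.0))  # 6 min
        counts = [cc.inject_ectopics(rr, 2.0, seed=s)[1].size for s in range(40)]
        mean = np.mean(counts)
        # Poisson(12) mean over 40 draws: SE ~ 0.55
        assert 10.0 < mean < 14.0

    def test_overlapping_rate_raises(self):
        rr = cc.RRSeries.from_intervals(np.full(10, 1000.0))
        with pytest.raises(ConfigurationError):
            cc.inject_ectopics(rr, 600.0, seed=2)


class TestCohort:
    def test_counts_contract(self):
        cfg = cc.CohortConfig(n_visual=1, n_haptic=1, n_visuo_haptic=1, seed=0)
        cohort = cc.generate_cohort(cfg)
        assert len(cohort) == 3
        assert sorted(p.condition for p in cohort) == [
            "haptic", "visual", "visuo-haptic"]
        for p in cohort:
            for rr in (p.rr_video, p.rr_guided):
                assert isinstance(rr, cc.RRSeries)
            for resp in (p.resp_video, p.resp_guided):
                assert isinstance(resp, cc.RespSignal)

    def test_cohort_reproducible(self):
        cfg = cc.CohortConfig(n_visual=1, n_haptic=1, n_visuo_haptic=1, seed=4)
        a = cc.generate_cohort(cfg)
        b = cc.generate_cohort(cfg)
        for pa, pb in zip(a, b):
            npt.assert_array_equal(pa.rr_guided.beat_times, pb.rr_guided.beat_times)
            npt.assert_array_equal(pa.resp_video.samples, pb.resp_video.samples)

    def test_default_group_sizes_match_study(self):
        cfg = cc.CohortConfig(seed=0)
        assert cfg.group_sizes == {"visual": 11, "haptic": 8, "visuo-haptic": 13}
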