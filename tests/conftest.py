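"""Shared fixtures: analytic beat builders and a reusable guided-phase run."""

import logging
import warnings

import numpy as np
import pytest

import cardiocoh as cc

logging.disable(logging.INFO)


def build_beats(rr_of_t, duration_s, t0=0.0):
    """Place beats iteratively from an analytic RR(t) in ms (the generator's
    placement rule, re-implemented independently for oracle construction)."""
    beats = [t0]
    t = t0
    while True:
        t_next = t + rr_of_t(t) / 1000.0
        if t_next > t0 + duration_s + 1e-9:
            break
        beats.append(t_next)
        t = t_next
    return cc.RRSeries.from_beat_times(np.array(beats))


@pytest.fixture(scope="session")
def resonant_rr():
    """Noiseless 0.1 Hz modulated RR series, 300 s (pure resonance)."""
    return build_beats(lambda t: 850.0 + 60.0 * np.sin(2 * np.pi * 0.1 * t), 300.0)


@pytest.fixture(scope="session")
def guided_run():
    """One seeded guided phase through the full chain: series, clean series,
    detrended tachogram and PSD."""
    cfg = cc.guided_config(seed=42)
    rr = cc.generate_rr_series(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clean = cc.correct_artifacts(rr, cc.detect_artifacts(rr))
    tach = cc.smoothness_priors_detrend(cc.resample_tachogram(clean))
    psd = cc.compute_psd(tach)
    return {"config": cfg, "rr": rr, "clean": clean, "tach": tach, "psd": psd}


@pytest.fixture(scope="session")
def video_psd():
    """Spontaneous (video) phase PSD matching guided_run's estimator settings."""
    rr = cc.generate_rr_series(cc.spontaneous_config(seed=43))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clean = cc.correct_artifacts(rr, cc.detect_artifacts(rr))
    tach = cc.smoothness_priors_detrend(cc.resample_tachogram(clean))
    return cc.compute_psd(tach)
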