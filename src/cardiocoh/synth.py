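"""Synthetic cardiorespiratory physiology for testing the coherence pipeline.

The generator emulates the two phases of a guided-breathing session:

* a *guided* phase in which respiratory sinus arrhythmia (RSA) is locked to
  the 0.1 Hz device pacing (5 s inspiration / 5 s expiration), with a small
  random drift of the instantaneous breathing frequency modelling human
  tracking error;
* a *spontaneous* (video) phase with RSA at the natural 0.2-0.3 Hz breathing
  rate plus an independent ~0.1 Hz Mayer-wave component.

RR intervals are modulated directly (not through an integral-pulse-frequency
model): the instantaneous interval is

    RR(t) = mean_rr + rsa_amp * sin(2*pi*phi(t))
                    + mayer_amp * sin(2*pi*f_mayer*t + phi0) + noise,

where ``phi(t)`` integrates an instantaneous breathing frequency performing a
seeded, mean-reverting bounded walk around ``breath_freq_hz`` with stationary
SD ``breath_jitter_sd_hz`` (clipped at +/-3 SD).  Beats are placed
iteratively, ``t_{k+1} = t_k + RR(t_k)/1000``.  The chest-belt respiration
waveform shares the same frequency walk, so heart and breath stay coupled.

All randomness flows from one integer seed through named generator streams,
so identical configurations reproduce identical series beat-for-beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigurationError
from .preprocess import RespSignal, RRSeries

__all__ = [
    "SynthConfig",
    "ConditionParams",
    "CohortConfig",
    "Participant",
    "guided_config",
    "spontaneous_config",
    "generate_rr_series",
    "generate_resp_signal",
    "inject_ectopics",
    "generate_cohort",
    "CONDITIONS",
]

#: resolution (s) of the instantaneous-frequency walk grid
_GRID_DT = 0.25
#: mean-reversion time constant (s) of the frequency walk.  Pacer tracking is
#: corrective within half a breath phase, which keeps the realized dominant
#: frequency pinned at the pacing target while dispersing power around it.
_WALK_TAU_S = 2.5

# named sub-streams of the per-series seed
_STREAM_BREATH = 11
_STREAM_MAYER = 13
_STREAM_BEAT_NOISE = 17
_STREAM_RESP_NOISE = 19


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic RR / respiration recording.

    Amplitudes are in milliseconds of RR modulation; frequencies in Hz.
    ``breath_jitter_sd_hz`` is the stationary SD of the instantaneous
    breathing-frequency drift (human tracking error); ``noise_sd_ms`` is
    white beat-to-beat noise.  ``resp_amp`` / ``resp_noise_sd`` set the
    chest-belt waveform scale and its additive noise (arbitrary units).
    """

    duration_s: float = 300.0
    mean_rr_ms: float = 850.0
    rsa_amp_ms: float = 60.0
    breath_freq_hz: float = 0.1
    breath_jitter_sd_hz: float = 0.005
    mayer_amp_ms: float = 0.0
    mayer_freq_hz: float = 0.1
    noise_sd_ms: float = 5.0
    ectopic_rate_per_min: float = 0.0
    resp_amp: float = 1.0
    resp_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        def _require(cond: bool, name: str, why: str) -> None:
            if not cond:
                raise ConfigurationError(f"{name}: {why}")

        _require(self.duration_s > 0, "duration_s", "must be positive")
        _require(self.mean_rr_ms > 0, "mean_rr_ms", "must be positive")
        for name in ("rsa_amp_ms", "mayer_amp_ms", "noise_sd_ms",
                     "breath_jitter_sd_hz", "ectopic_rate_per_min",
                     "resp_amp", "resp_noise_sd"):
            _require(getattr(self, name) >= 0, name, "must be non-negative")
        _require(0.0 < self.breath_freq_hz < 0.5, "breath_freq_hz",
                 "must lie in (0, 0.5) Hz")
        _require(self.mayer_freq_hz >= 0, "mayer_freq_hz", "must be non-negative")
        _require(
            self.rsa_amp_ms + self.mayer_amp_ms + 4 * self.noise_sd_ms
            < self.mean_rr_ms,
            "rsa_amp_ms",
            "rsa_amp_ms + mayer_amp_ms + 4*noise_sd_ms must stay below "
            "mean_rr_ms (intervals would go non-positive)",
        )


def guided_config(seed: int = 0, **overrides) -> SynthConfig:
    """Study conditions of a 5-min guided phase: RSA locked near 0.1 Hz.

    At resonance the Mayer rhythm merges with the paced RSA, so the guided
    preset carries a single 0.1 Hz component.
    """
    base = dict(duration_s=300.0, mean_rr_ms=850.0, rsa_amp_ms=60.0,
                breath_freq_hz=0.1, breath_jitter_sd_hz=0.005,
                mayer_amp_ms=0.0, noise_sd_ms=5.0, seed=seed)
    base.update(overrides)
    return SynthConfig(**base)


def spontaneous_config(seed: int = 0, **overrides) -> SynthConfig:
    """Study conditions of an 8-min spontaneous (video) phase.

    RSA sits at the natural ~0.25 Hz breathing rate with a looser frequency
    drift, alongside an independent 0.1 Hz Mayer-wave component.
    """
    base = dict(duration_s=480.0, mean_rr_ms=850.0, rsa_amp_ms=35.0,
                breath_freq_hz=0.25, breath_jitter_sd_hz=0.015,
                mayer_amp_ms=25.0, mayer_freq_hz=0.1, noise_sd_ms=8.0,
                seed=seed)
    base.update(overrides)
    return SynthConfig(**base)


# ---------------------------------------------------------------------------
# instantaneous frequency / phase model


def _phase_on_grid(config: SynthConfig, n_grid: int) -> np.ndarray:
    """Breathing phase (cycles) on the ``_GRID_DT`` grid, shared by RR and belt.

    The instantaneous frequency is ``breath_freq_hz`` plus a mean-reverting
    AR(1) walk with stationary SD ``breath_jitter_sd_hz`` and time constant
    ``_WALK_TAU_S`` (2.5 s: corrections within half a pacing cycle), clipped at +/-3 SD; the phase is its trapezoidal
    integral.
    """
    f = np.full(n_grid, config.breath_freq_hz)
    sd = config.breath_jitter_sd_hz
    if sd > 0:
        rng = np.random.default_rng([config.seed, _STREAM_BREATH])
        a = float(np.exp(-_GRID_DT / _WALK_TAU_S))
        innov_sd = sd * np.sqrt(1.0 - a * a)
        eps = rng.normal(0.0, innov_sd, n_grid)
        x0 = rng.normal(0.0, sd)
        drift = lfilter([1.0], [1.0, -a], eps, zi=np.array([a * x0]))[0]
        f += np.clip(drift, -3.0 * sd, 3.0 * sd)
    phi = np.empty(n_grid)
    phi[0] = 0.0
    np.cumsum((f[:-1] + f[1:]) * (0.5 * _GRID_DT), out=phi[1:])
    return phi


def _grid_size(duration_s: float) -> int:
    # cover the duration plus a margin of a few beats for the final interval
    return int(np.ceil((duration_s + 5.0) / _GRID_DT)) + 2


def _instantaneous_rr_ms(config: SynthConfig) -> np.ndarray:
    """Noise-free RR(t) in ms on the ``_GRID_DT`` grid."""
    n_grid = _grid_size(config.duration_s)
    t = np.arange(n_grid) * _GRID_DT
    rr = config.mean_rr_ms + config.rsa_amp_ms * np.sin(
        2.0 * np.pi * _phase_on_grid(config, n_grid)
    )
    if config.mayer_amp_ms > 0:
        rng = np.random.default_rng([config.seed, _STREAM_MAYER])
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        rr = rr + config.mayer_amp_ms * np.sin(
            2.0 * np.pi * config.mayer_freq_hz * t + phi0
        )
    return rr


# ---------------------------------------------------------------------------
# public generators


def generate_rr_series(config: SynthConfig) -> RRSeries:
    """Generate a seeded RR-interval event series covering ``[0, duration_s]``.

    Beats are placed iteratively: the interval starting at ``t_k`` has
    duration ``RR(t_k)/1000`` seconds, where RR(t) follows the module-level
    model.  Beat-to-beat noise draws are clipped at +/-4 SD, which together
    with the amplitude invariant guarantees positive intervals.
    """
    grid = _instantaneous_rr_ms(config)
    dur = config.duration_s
    min_rr = config.mean_rr_ms - config.rsa_amp_ms - config.mayer_amp_ms \
        - 4.0 * config.noise_sd_ms
    max_beats = int(dur * 1000.0 / min_rr) + 3
    if config.noise_sd_ms > 0:
        rng = np.random.default_rng([config.seed, _STREAM_BEAT_NOISE])
        noise = np.clip(rng.normal(0.0, config.noise_sd_ms, max_beats),
                        -4.0 * config.noise_sd_ms, 4.0 * config.noise_sd_ms)
    else:
        noise = np.zeros(max_beats)

    inv_dt = 1.0 / _GRID_DT
    g = grid  # local alias for the loop
    beats = [0.0]
    t = 0.0
    k = 0
    while True:
        pos = t * inv_dt
        i = int(pos)
        frac = pos - i
        rr_ms = g[i] * (1.0 - frac) + g[i + 1] * frac + noise[k]
        t_next = t + rr_ms / 1000.0
        if t_next > dur + 1e-9:
            break
        beats.append(t_next)
        t = t_next
        k += 1
    return RRSeries.from_beat_times(np.array(beats))


def generate_resp_signal(config: SynthConfig, fs: float = 4.0) -> RespSignal:
    """Chest-belt-like respiration sharing the RR series' breathing-phase walk.

    ``samples = resp_amp * sin(2*pi*phi(t)) + noise`` over ``duration_s * fs``
    samples.  With the same ``config`` (same seed), the waveform's phase is
    identical to the RSA phase of :func:`generate_rr_series`.
    """
    if fs < 1.0:
        raise ConfigurationError("fs: must be at least 1 Hz")
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    n_grid = _grid_size(config.duration_s)
    phi_grid = _phase_on_grid(config, n_grid)
    phi = np.interp(t, np.arange(n_grid) * _GRID_DT, phi_grid)
    samples = config.resp_amp * np.sin(2.0 * np.pi * phi)
    if config.resp_noise_sd > 0:
        rng = np.random.default_rng([config.seed, _STREAM_RESP_NOISE])
        samples = samples + rng.normal(0.0, config.resp_noise_sd, n)
    return RespSignal(fs=fs, samples=samples)


def inject_ectopics(rr: RRSeries, rate_per_min: float,
                    seed: int) -> tuple[RRSeries, np.ndarray]:
    """Inject extrasystole/compensatory-pause pairs at seeded random beats.

    Each event scales interval ``k`` to 0.6x (early beat) and ``k+1`` to 1.4x
    (compensatory pause), preserving the pair's total time exactly.  The
    event count is Poisson with mean ``rate_per_min * duration / 60``; event
    start indices keep a separation of at least 3 intervals so pairs never
    overlap.  Returns the modified series and the sorted event start indices.
    """
    if rr.rr_ms.size < 2:
        raise ValueError("need at least two intervals to inject an ectopic pair")
    if rate_per_min < 0:
        raise ConfigurationError("rate_per_min: must be non-negative")
    if rate_per_min == 0:
        return rr, np.array([], dtype=int)
    rng = np.random.default_rng([seed, 29])
    n = rr.rr_ms.size
    n_events = int(rng.poisson(rate_per_min * rr.duration_s / 60.0))
    if n_events == 0:
        return rr, np.array([], dtype=int)
    candidates = rng.permutation(n - 1)  # k and k+1 must both be valid
    chosen: list[int] = []
    for k in candidates:
        if all(abs(k - c) >= 3 for c in chosen):
            chosen.append(int(k))
            if len(chosen) == n_events:
                break
    if len(chosen) < n_events:
        raise ConfigurationError(
            "ectopic_rate_per_min: rate too high, injected pairs would overlap"
        )
    new_rr = rr.rr_ms.copy()
    idx = np.sort(np.array(chosen, dtype=int))
    new_rr[idx] *= 0.6
    new_rr[idx + 1] *= 1.4
    out = RRSeries.from_intervals(new_rr, t0=rr.beat_times[0],
                                  corrected_fraction=rr.corrected_fraction)
    return out, idx


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class ConditionParams:
    """Condition-level tracking-error parameters.

    ``breath_jitter_sd_hz`` is the guided-phase frequency-drift SD typical of
    the guidance modality; RSA amplitude varies between subjects as
    ``Normal(rsa_amp_mean_ms, rsa_amp_sd_ms)``.
    """

    breath_jitter_sd_hz: float
    rsa_amp_mean_ms: float = 60.0
    rsa_amp_sd_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.breath_jitter_sd_hz < 0 or self.rsa_amp_sd_ms < 0:
            raise ConfigurationError("ConditionParams: SDs must be non-negative")
        if self.rsa_amp_mean_ms <= 0:
            raise ConfigurationError("rsa_amp_mean_ms: must be positive")


#: calibrated defaults: visual guidance tracks worst (largest frequency
#: jitter, weakest resonance amplitude), visuo-haptic best; haptic guidance
#: carries the largest between-subject amplitude spread (sensitivity to
#: haptic stimuli varies more across people than vision does)
CONDITIONS: dict[str, ConditionParams] = {
    "visual": ConditionParams(breath_jitter_sd_hz=0.013,
                              rsa_amp_mean_ms=48.0, rsa_amp_sd_ms=10.0),
    "haptic": ConditionParams(breath_jitter_sd_hz=0.008,
                              rsa_amp_mean_ms=58.0, rsa_amp_sd_ms=16.0),
    "visuo-haptic": ConditionParams(breath_jitter_sd_hz=0.005,
                                    rsa_amp_mean_ms=62.0, rsa_amp_sd_ms=10.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout with per-condition tracking-error parameters.

    Default group sizes follow the study demographics (11 / 8 / 13).
    """

    n_visual: int = 11
    n_haptic: int = 8
    n_visuo_haptic: int = 13
    conditions: dict = field(default_factory=lambda: dict(CONDITIONS))
    guided_duration_s: float = 300.0
    video_duration_s: float = 480.0
    ectopic_rate_per_min: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_visual", "n_haptic", "n_visuo_haptic"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name}: must be at least 1")
        missing = set(CONDITIONS) - set(self.conditions)
        if missing:
            raise ConfigurationError(f"conditions: missing {sorted(missing)}")

    @property
    def group_sizes(self) -> dict[str, int]:
        return {"visual": self.n_visual, "haptic": self.n_haptic,
                "visuo-haptic": self.n_visuo_haptic}


@dataclass
class Participant:
    """One synthetic participant: both phases of RR and respiration."""

    participant_id: str
    condition: str
    seed: int
    rr_video: RRSeries
    rr_guided: RRSeries
    resp_video: RespSignal
    resp_guided: RespSignal
    ectopic_indices_guided: np.ndarray
    ectopic_indices_video: np.ndarray


def _participant_seed(cohort_seed: int, idx: int, offset: int = 0) -> int:
    return int((cohort_seed * 100_003 + 7_919 * idx + offset) % 2**31)


def generate_cohort(config: CohortConfig) -> list[Participant]:
    """Generate a reproducible cohort: per participant, a spontaneous video
    phase and a guided phase with condition-specific tracking error.

    Between-subject variation: mean RR ~ Normal(850, 60) ms, guided RSA
    amplitude ~ Normal per condition, spontaneous breathing rate ~
    Normal(0.25, 0.03) Hz, spontaneous RSA ~ Normal(35, 6) ms independent of
    condition (the video phase precedes guidance).  Occasional ectopic pairs
    are injected in both phases.
    """
    participants: list[Participant] = []
    idx = 0
    for condition, n in config.group_sizes.items():
        params: ConditionParams = config.conditions[condition]
        for _ in range(n):
            rng = np.random.default_rng([config.seed, 31, idx])
            mean_rr = float(np.clip(rng.normal(850.0, 60.0), 650.0, 1100.0))
            rsa_guided = float(np.clip(
                rng.normal(params.rsa_amp_mean_ms, params.rsa_amp_sd_ms),
                20.0, 120.0))
            # spontaneous-phase traits precede guidance: condition-independent
            rsa_spont = float(np.clip(rng.normal(35.0, 6.0), 15.0, 60.0))
            breath_spont = float(np.clip(rng.normal(0.25, 0.03), 0.16, 0.34))
            seed_guided = _participant_seed(config.seed, idx, 0)
            seed_video = _participant_seed(config.seed, idx, 1)

            cfg_guided = guided_config(
                seed=seed_guided, duration_s=config.guided_duration_s,
                mean_rr_ms=mean_rr, rsa_amp_ms=rsa_guided,
                breath_jitter_sd_hz=params.breath_jitter_sd_hz)
            cfg_video = spontaneous_config(
                seed=seed_video, duration_s=config.video_duration_s,
                mean_rr_ms=mean_rr, rsa_amp_ms=rsa_spont,
                breath_freq_hz=breath_spont)

            rr_guided = generate_rr_series(cfg_guided)
            rr_video = generate_rr_series(cfg_video)
            rr_guided, ect_g = inject_ectopics(
                rr_guided, config.ectopic_rate_per_min, seed_guided)
            rr_video, ect_v = inject_ectopics(
                rr_video, config.ectopic_rate_per_min, seed_video)

            participants.append(Participant(
                participant_id=f"P{idx + 1:03d}",
                condition=condition,
                seed=seed_guided,
                rr_video=rr_video,
                rr_guided=rr_guided,
                resp_video=generate_resp_signal(cfg_video),
                resp_guided=generate_resp_signal(cfg_guided),
                ectopic_indices_guided=ect_g,
                ectopic_indices_video=ect_v,
            ))
            idx += 1
    return participants
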