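"""Emulation of the handheld guidance device.

The device paces breathing at 0.1 Hz with 5 s inspiration / 5 s expiration
phases.  Its guidance waveform (light level or vibration frequency) rises
linearly for 5 s and falls for 5 s.  Its HRV biofeedback rule checks, per
phase, that beat-wise heart rate moves monotonically in the required
direction — continuously up during inspiration, down during expiration —
and fades the feedback colour when it does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import RRSeries

__all__ = ["PhaseWindow", "FeedbackState", "phase_schedule",
           "guidance_waveform", "phase_smoothness"]

#: heart-rate equality tolerance (bpm) so float ties do not count as violations
HR_TOL_BPM = 0.1


@dataclass(frozen=True)
class PhaseWindow:
    """One 5 s breathing phase starting at ``start`` seconds."""

    start: float
    duration: float = 5.0
    kind: str = "inspiration"  # "inspiration" | "expiration"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.kind not in ("inspiration", "expiration"):
            raise ValueError("kind must be 'inspiration' or 'expiration'")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class FeedbackState:
    """Per-phase verdict: smooth, not smooth, or indeterminate (None) when
    the phase contains fewer than 2 beats."""

    phase: PhaseWindow
    smooth: bool | None
    violation_count: int | None

    @property
    def indeterminate(self) -> bool:
        return self.smooth is None


def phase_schedule(total_s: float, phase_s: float = 5.0,
                   start: float = 0.0) -> list[PhaseWindow]:
    """Alternating inspiration/expiration windows tiling ``[start, start+total_s]``."""
    if total_s <= 0 or phase_s <= 0:
        raise ValueError("durations must be positive")
    kinds = ("inspiration", "expiration")
    n = int(np.floor(total_s / phase_s))
    return [PhaseWindow(start=start + k * phase_s, duration=phase_s,
                        kind=kinds[k % 2]) for k in range(n)]


def guidance_waveform(t) -> np.ndarray | float:
    """Guidance intensity in [0, 1]: a 10 s triangle, rising over [0, 5) and
    falling over [5, 10).  Fundamental frequency 0.1 Hz."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    x = np.mod(t_arr, 10.0)
    out = np.where(x < 5.0, x / 5.0, 2.0 - x / 5.0)
    return float(out) if np.isscalar(t) else out


def phase_smoothness(rr: RRSeries, phases: list[PhaseWindow],
                     tolerance: int = 0,
                     hr_tol_bpm: float = HR_TOL_BPM) -> list[FeedbackState]:
    """Apply the device's monotonic-heart-rate rule to each phase.

    Heart rate (60000 / rr_ms, one value per interval at its starting beat)
    must rise during inspiration and fall during expiration.  A
    consecutive-beat pair violates when it moves the wrong way by more than
    ``hr_tol_bpm``; a phase is smooth when its violation count does not
    exceed ``tolerance``.  Phases with fewer than 2 beats are flagged
    indeterminate rather than judged.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    hr_times = rr.beat_times[:-1]
    hr = 60000.0 / rr.rr_ms
    states: list[FeedbackState] = []
    for phase in phases:
        sel = (hr_times >= phase.start) & (hr_times < phase.end)
        values = hr[sel]
        if values.size < 2:
            states.append(FeedbackState(phase=phase, smooth=None,
                                        violation_count=None))
            continue
        d = np.diff(values)
        if phase.kind == "inspiration":
            violations = int(np.sum(d < -hr_tol_bpm))
        else:
            violations = int(np.sum(d > hr_tol_bpm))
        states.append(FeedbackState(phase=phase, smooth=violations <= tolerance,
                                    violation_count=violations))
    return states
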