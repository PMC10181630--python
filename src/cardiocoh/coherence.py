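"""The two bespoke cardiac-coherence scores.

* ``RMSError``: root-mean-square deviation of successive oscillation-cycle
  durations (HRV crest-to-crest, or breath peak-to-peak) from the 10 s
  resonance target — how tightly the rhythm tracks the pacing.
* ``P_0.1``: the concentration index — the maximal guided-phase PSD peak
  height divided by the cumulative sum of spontaneous-phase (video) peak
  heights in the 0.04-0.4 Hz band.  A value near 1 means the power that was
  spread across the band during spontaneous breathing has accumulated at the
  guided 0.1 Hz frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedScoreError
from .preprocess import CycleSeries
from .spectral import Band, PSDResult, local_peak_heights, main_peak

__all__ = ["RMSEResult", "CoherenceScore", "rms_error", "p01_index"]


@dataclass(frozen=True)
class RMSEResult:
    """RMS deviation (s) of cycle durations from the pacing target."""

    rmse: float
    target_s: float
    n_cycles: int
    trimmed: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.n_cycles < 1:
            raise ValueError("rmse must be >= 0 and n_cycles >= 1")


@dataclass(frozen=True)
class CoherenceScore:
    """P_0.1 with its numerator (guided max peak height) and denominator
    (summed video peak heights); the guided peak location is carried along
    so proximity to 0.1 Hz can be asserted separately."""

    p01: float
    h_max_guide: float
    h_sum_video: float
    band: Band
    guide_peak_location_hz: float

    def __post_init__(self) -> None:
        if self.h_sum_video <= 0:
            raise ValueError("h_sum_video must be positive")
        if abs(self.p01 - self.h_max_guide / self.h_sum_video) > 1e-12 * max(
                1.0, self.p01):
            raise ValueError("p01 must equal h_max_guide / h_sum_video")

    @property
    def exceeds_unity(self) -> bool:
        """Flag: the guided peak outgrew the summed video peaks (allowed)."""
        return self.p01 > 1.0


def rms_error(cycles: CycleSeries, target_s: float = 10.0,
              trim: tuple[int, int] = (0, 0)) -> RMSEResult:
    """RMSError of cycle durations against the pacing target.

    ``rmse = sqrt(mean((x_n - target)^2))`` over the retained cycles.
    ``trim`` drops leading/trailing cycles (transients at guidance onset and
    offset); the default keeps all cycles.
    """
    lead, tail = trim
    if lead < 0 or tail < 0:
        raise ValueError("trim counts must be non-negative")
    x = cycles.cycle_durations[lead:cycles.N - tail if tail else None]
    if x.size == 0:
        raise ValueError("no cycles remain after trimming")
    rmse = float(np.sqrt(np.mean((x - target_s) ** 2)))
    return RMSEResult(rmse=rmse, target_s=target_s, n_cycles=int(x.size),
                      trimmed=(lead, tail))


def p01_index(guide_psd: PSDResult, video_psd: PSDResult,
              band: Band = Band()) -> CoherenceScore:
    """P_0.1 concentration index from the two phases' PSDs.

    The numerator is the height of the maximal guided-phase peak in the band
    (the band-wide maximum; its location is recorded); the denominator sums
    every strict local peak height of the video-phase PSD in the band.  Both
    PSDs must come from the same estimator settings — with density scaling
    the differing phase durations are then comparable.
    """
    if not guide_psd.same_estimator(video_psd):
        raise ValueError(
            "guide and video PSDs use different estimator settings "
            f"({guide_psd.window_name}/x{guide_psd.pad_factor} vs "
            f"{video_psd.window_name}/x{video_psd.pad_factor})")
    peak = main_peak(guide_psd, band)
    heights = local_peak_heights(video_psd, band)
    if heights.size == 0:
        raise UndefinedScoreError("video-phase PSD has no peak in the band")
    h_sum = float(np.sum(heights))
    if h_sum <= 0:
        raise UndefinedScoreError("video-phase peak heights sum to zero")
    return CoherenceScore(p01=peak.height / h_sum, h_max_guide=peak.height,
                          h_sum_video=h_sum, band=band,
                          guide_peak_location_hz=peak.location)
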