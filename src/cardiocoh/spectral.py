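"""Power spectral density estimation and dominant-peak descriptors.

A single-segment windowed periodogram of the full record is used rather than
Welch averaging: the cardiac-coherence resonance is a narrow line near
0.1 Hz, and segment averaging would broaden exactly the feature under study.
Records are zero-padded to the next power of two at least ``pad_factor``
(default 4) times the record length so that peak locations can be refined
stably by parabolic interpolation.

Density scaling (power per Hz) is mandatory so that phases of different
duration (8-min video vs. 5-min guided) are directly comparable: peak
heights are densities, not bin powers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .errors import NoPeakError
from .preprocess import RespSignal, Tachogram

__all__ = ["Band", "PSDResult", "SpectralPeak", "compute_psd", "main_peak",
           "local_peak_heights"]


@dataclass(frozen=True)
class Band:
    """Frequency band [lo, hi] in Hz; defaults to the 0.04-0.4 Hz HRV range."""

    lo: float = 0.04
    hi: float = 0.4

    def __post_init__(self) -> None:
        if not 0 <= self.lo < self.hi:
            raise ValueError("band must satisfy 0 <= lo < hi")


@dataclass
class PSDResult:
    """One-sided PSD with the estimator settings that produced it.

    ``density`` is in ms^2/Hz for tachograms (squared amplitude per Hz for
    respiration); ``df`` is the zero-padded bin spacing.  ``freqs_native`` /
    ``density_native`` hold the same estimate at the record's natural Fourier
    resolution (no zero-padding): the padded grid is for locating the main
    peak precisely, the native grid for counting peaks — on an oversampled
    grid every window sidelobe would register as a separate local maximum.
    They default to the main arrays when a PSDResult is built directly from
    an already-coarse density.
    """

    freqs: np.ndarray
    density: np.ndarray
    df: float
    window_name: str
    segment_length_s: float
    pad_factor: int
    freqs_native: np.ndarray | None = None
    density_native: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.freqs.shape != self.density.shape:
            raise ValueError("freqs and density must have matching shapes")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if self.freqs_native is None or self.density_native is None:
            self.freqs_native = self.freqs
            self.density_native = self.density
        else:
            self.freqs_native = np.asarray(self.freqs_native, dtype=float)
            self.density_native = np.asarray(self.density_native, dtype=float)

    def same_estimator(self, other: "PSDResult") -> bool:
        return (self.window_name == other.window_name
                and self.pad_factor == other.pad_factor)


@dataclass(frozen=True)
class SpectralPeak:
    """Dominant-peak descriptors: location (Hz), height (density units),
    and mid-peak-height width (Hz), the width at half the peak height."""

    location: float
    height: float
    mphw: float

    def __post_init__(self) -> None:
        if self.height <= 0 or self.mphw <= 0:
            raise ValueError("peak height and mphw must be positive")


def _next_pow2(m: int) -> int:
    return 1 << (int(m - 1).bit_length())


def compute_psd(signal: Tachogram | RespSignal, *, window: str = "hann",
                pad_factor: int = 4) -> PSDResult:
    """Single-segment windowed periodogram with density scaling.

    Tachograms must already be detrended; respiration is mean-removed here.
    Zero-pads to the next power of two >= ``pad_factor`` times the record
    length.
    """
    if isinstance(signal, Tachogram):
        if not signal.detrended:
            raise ValueError("tachogram must be detrended before PSD estimation")
        values, fs = signal.values, signal.fs
    elif isinstance(signal, RespSignal):
        values, fs = signal.samples, signal.fs
    else:
        raise TypeError("compute_psd expects a Tachogram or RespSignal")
    n = values.size
    if n < 64:
        raise ValueError("PSD estimation needs at least 64 samples")
    if pad_factor < 1:
        raise ValueError("pad_factor must be at least 1")
    nfft = _next_pow2(pad_factor * n)
    x = values - values.mean()
    freqs, density = periodogram(x, fs=fs, window=window, nfft=nfft,
                                 detrend=False, scaling="density")
    freqs_nat, density_nat = periodogram(x, fs=fs, window=window,
                                         detrend=False, scaling="density")
    return PSDResult(freqs=freqs, density=density, df=float(freqs[1]),
                     window_name=window, segment_length_s=n / fs,
                     pad_factor=pad_factor, freqs_native=freqs_nat,
                     density_native=density_nat)


def _band_slice(psd: PSDResult, band: Band) -> tuple[int, int]:
    if band.hi > psd.freqs[-1]:
        raise ValueError("band exceeds the PSD frequency range")
    lo = int(np.searchsorted(psd.freqs, band.lo, side="left"))
    hi = int(np.searchsorted(psd.freqs, band.hi, side="right"))
    if hi - lo < 3:
        raise ValueError("band covers fewer than 3 PSD bins")
    return lo, hi


def _strict_maxima(d: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Indices k with d[k] > d[k-1] and d[k] > d[k+1], band edge bins excluded.

    The band occupies bins [lo, hi); its first and last bins cannot be peaks.
    """
    k = np.arange(lo + 1, hi - 1)
    k = k[(k >= 1) & (k <= d.size - 2)]
    return k[(d[k] > d[k - 1]) & (d[k] > d[k + 1])]


def main_peak(psd: PSDResult, band: Band) -> SpectralPeak:
    """Descriptors of the maximal in-band peak.

    The location is the frequency of the maximal density bin refined by
    parabolic interpolation over its 3 surrounding bins; the height is the
    raw maximal-bin density (unrefined, so heights stay comparable across
    records with identical df); the MPHW is the width at half that height,
    each flank crossing found by linear interpolation.

    Raises :class:`NoPeakError` when the density is monotone in the band.
    """
    lo, hi = _band_slice(psd, band)
    d = psd.density
    maxima = _strict_maxima(d, lo, hi)
    if maxima.size == 0:
        raise NoPeakError("density has no strict local maximum in the band")
    i = int(maxima[np.argmax(d[maxima])])
    denom = d[i - 1] - 2.0 * d[i] + d[i + 1]
    delta = 0.0 if denom == 0 else 0.5 * (d[i - 1] - d[i + 1]) / denom
    location = psd.freqs[i] + delta * psd.df
    height = float(d[i])
    half = 0.5 * height

    j = i
    while j > 0 and d[j] > half:
        j -= 1
    if d[j] > half:
        raise NoPeakError("left flank never falls to half height")
    f_left = np.interp(half, [d[j], d[j + 1]], [psd.freqs[j], psd.freqs[j + 1]])
    j = i
    while j < d.size - 1 and d[j] > half:
        j += 1
    if d[j] > half:
        raise NoPeakError("right flank never falls to half height")
    f_right = np.interp(half, [d[j], d[j - 1]], [psd.freqs[j], psd.freqs[j - 1]])
    return SpectralPeak(location=float(location), height=height,
                        mphw=float(f_right - f_left))


#: maxima below this fraction of the band maximum are FFT round-off, not peaks
_NUMERICAL_FLOOR = 1e-10


def local_peak_heights(psd: PSDResult, band: Band, *,
                       min_prominence: float = 0.0) -> np.ndarray:
    """Heights of every strict local density maximum inside the band.

    The census runs on the native-resolution grid (see :class:`PSDResult`);
    band endpoints cannot be peaks.  ``min_prominence`` (density units)
    optionally drops shallow ripples; it defaults to 0 so that every strict
    maximum counts, matching the plain 'sum of peak heights' denominator.
    Returns an empty array when the band holds no peak.
    """
    freqs, density = psd.freqs_native, psd.density_native
    if band.hi > freqs[-1]:
        raise ValueError("band exceeds the PSD frequency range")
    lo = int(np.searchsorted(freqs, band.lo, side="left"))
    hi = int(np.searchsorted(freqs, band.hi, side="right"))
    if hi - lo < 3:
        raise ValueError("band covers fewer than 3 PSD bins")
    k = _strict_maxima(density, lo, hi)
    if k.size:
        band_max = density[lo:hi].max()
        k = k[density[k] > _NUMERICAL_FLOOR * band_max]
    if k.size and min_prominence > 0:
        from scipy.signal import peak_prominences
        prom = peak_prominences(density, k)[0]
        k = k[prom >= min_prominence]
    return density[k]
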