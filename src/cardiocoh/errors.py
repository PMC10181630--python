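"""Exception types shared across the pipeline.

Exclusions are signalled, never silent: a respiratory record that fails the
signal-to-noise guard raises :class:`UnusableSeriesError` so the cohort driver
can record an explicit exclusion reason, mirroring how low-SNR chest-belt
records are discarded from respiratory analysis.
"""


class CardiocohError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CardiocohError, ValueError):
    """A configuration field violates its invariant; names the offending field."""


class UnusableSeriesError(CardiocohError):
    """A signal fails a quality guard (e.g. respiratory SNR) and must be excluded."""


class UnrecoverableSeriesError(CardiocohError):
    """Artifact correction is impossible (e.g. every interval flagged)."""


class NoPeakError(CardiocohError):
    """The spectral density is monotone in the searched band: no peak exists."""


class UndefinedScoreError(CardiocohError):
    """A score's denominator is empty or zero (e.g. no video-phase peaks)."""


class DegenerateDataError(CardiocohError):
    """Inference is undefined (e.g. zero within-group variance with equal means)."""
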