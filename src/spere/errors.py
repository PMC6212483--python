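"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`SpeReError`,
so callers (and the CLI) can distinguish data/usage problems from genuine bugs.
"""


class SpeReError(Exception):
    """Base class for all errors raised by spere."""


class WavelengthRangeError(SpeReError, ValueError):
    """A wavelength lies outside a material's validated dispersion range."""


class StackStructureError(SpeReError, ValueError):
    """A layer stack violates its structural invariants."""


class SpectrumFormatError(SpeReError, ValueError):
    """A spectrum file or array pair is malformed."""


class CoverageError(SpeReError, ValueError):
    """Two spectra (or a spectrum and a database) do not share enough band."""


class NumericGuardError(SpeReError, ValueError):
    """An operation would divide by, or take a log of, a non-positive value."""


class DatabaseVersionError(SpeReError):
    """A persisted spectrum database has an incompatible format version."""


class DatabaseIntegrityError(SpeReError):
    """A persisted spectrum database is truncated or missing metadata."""


class LowFrequencyError(SpeReError, ValueError):
    """The spectrum covers too few fringe periods for a phasor fit."""


class PhasorFitError(SpeReError, RuntimeError):
    """The sinusoidal phasor fit failed to converge."""


class PeakTrackingError(SpeReError, RuntimeError):
    """No fringe peak was found inside the tracking window."""


class SaturationError(SpeReError, ValueError):
    """A measured shift exceeds the model's full-density ceiling."""

    def __init__(self, message: str, ceiling: float | None = None):
        super().__init__(message)
        self.ceiling = ceiling


class CapacityError(SpeReError, ValueError):
    """A barcoding request exceeds the diameter range's multiplexing capacity."""

    def __init__(self, message: str, capacity: int | None = None):
        super().__init__(message)
        self.capacity = capacity


class UndefinedSNRError(SpeReError, ValueError):
    """SNR is undefined because the background has zero variance."""


class ConfigError(SpeReError, ValueError):
    """A run configuration file is malformed or contains unknown keys."""
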