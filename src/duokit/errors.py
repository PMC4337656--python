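"""Exception hierarchy for duokit."""


class DuokitError(Exception):
    """Base class for all duokit errors."""


class FormatError(DuokitError, ValueError):
    """Input file could not be parsed."""


class SpacingError(DuokitError, ValueError):
    """Time stamps are non-monotone or irregularly spaced."""


class RebinError(DuokitError, ValueError):
    """Requested bin width incompatible with the series."""


class WindowError(DuokitError, ValueError):
    """Requested window lies outside the recording span."""


class NyquistError(DuokitError, ValueError):
    """Filter cutoff period at or below twice the bin width."""


class SpanError(DuokitError, ValueError):
    """Series too short for the requested operation."""


class BandError(DuokitError, ValueError):
    """Requested period band outside the computable range."""


class DataError(DuokitError, ValueError):
    """Too few usable samples."""


class DesignError(DuokitError, ValueError):
    """Singular or ill-posed model design."""


class NormalizationError(DuokitError, ValueError):
    """Trace is degenerate (zero range) and cannot be normalized."""


class SizeError(DuokitError, ValueError):
    """Problem size outside the supported range."""


class ParameterError(DuokitError, ValueError):
    """Invalid parameter value."""


class ConfigError(DuokitError, ValueError):
    """Invalid pipeline configuration."""
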