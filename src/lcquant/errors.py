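"""Exception hierarchy shared across the package."""


class LcquantError(Exception):
    """Base class for all lcquant errors."""


class FormatError(LcquantError):
    """Unsupported or undetectable raw-data format."""


class ArchiveError(LcquantError):
    """Zip archive does not contain exactly one supported raw file."""


class ParseError(LcquantError):
    """Raw file is corrupt or cannot be parsed."""


class ValidationError(LcquantError):
    """Tabular input violates the project's contracts."""


class DomainError(LcquantError):
    """A value is outside the mathematical domain of an operation."""


class FitError(LcquantError):
    """Calibration regression cannot be computed."""


class InversionError(LcquantError):
    """Calibration curve cannot be inverted at the requested area."""


class NormalizationError(LcquantError):
    """Internal-standard normalization is impossible for a run."""


class RangeError(LcquantError):
    """Retention-time bounds fall outside the chromatogram span."""
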