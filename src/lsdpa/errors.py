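"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
NumericalError -> 4, anything else -> 1.
"""


class LsdpaError(Exception):
    """Base class for all package errors."""


class ConfigError(LsdpaError):
    """Invalid configuration, parameter, or wavelength specification."""


class ValidationError(ConfigError):
    """A value violates a documented physical or structural invariant."""


class WavelengthRangeError(ValidationError):
    """Requested wavelength outside the covered chromophore-table range."""


class WavelengthMismatchError(ValidationError):
    """Spectrum/model wavelength grids do not match."""


class DataError(LsdpaError):
    """Missing, corrupt, inconsistent, or insufficient data."""


class GenerationError(DataError):
    """Phantom geometry could not be realized (e.g. placement failure)."""


class NormalizationError(DataError):
    """Spectrum cannot be normalized (all-zero or negative entries)."""


class NumericalError(LsdpaError):
    """Degenerate numerical situation (zero variance, non-convergence...)."""
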