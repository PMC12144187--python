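"""Exception types shared across the package."""


class PshgError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PshgError, ValueError):
    """Model parameters or data violate a precondition (non-finite, negative, ...)."""


class UndefinedPitchError(PshgError, ValueError):
    """Pitch angle requested where chi33/chi31 - chi15/chi31 + 1 <= 0."""


class DegenerateProfileError(PshgError, ValueError):
    """Polarization profile is flat; peak structure undefined."""


class InsufficientSamplingError(PshgError, ValueError):
    """Fewer polarization angles than unknown Fourier coefficients."""


class DegenerateGridError(PshgError, ValueError):
    """Polarization angle grid yields a rank-deficient design matrix."""


class NoDataError(PshgError, ValueError):
    """A statistic was requested on an empty selection of pixels."""
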