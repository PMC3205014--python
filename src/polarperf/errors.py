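"""Exception hierarchy shared across the package."""


class PolarPerfError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(PolarPerfError, ValueError):
    """An argument violates a documented precondition."""


class InvalidStateError(PolarPerfError):
    """Inputs are in a state the operation cannot accept (e.g. unnormalized maps)."""


class NormalizationError(PolarPerfError):
    """A map cannot be normalized (scale undefined)."""


class InsufficientDataError(PolarPerfError):
    """Too few maps/subjects match a selection."""


class PairingError(PolarPerfError):
    """NC/AC pairing by subject id failed."""

    def __init__(self, message, offenders=()):
        super().__init__(message)
        self.offenders = tuple(offenders)


class CalibrationError(PolarPerfError):
    """Generator calibration could not reach a target."""

    def __init__(self, message, segment=None):
        super().__init__(message)
        self.segment = segment


class FormatError(PolarPerfError):
    """A file does not conform to the expected on-disk format."""
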