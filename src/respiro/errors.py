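"""Exception hierarchy shared across the package."""


class RespiroError(ValueError):
    """Base class for all validation and format errors."""


class ValidationError(RespiroError):
    """An input violates a documented precondition."""


class FormatError(RespiroError):
    """An on-disk artifact is malformed or inconsistent with its sidecar."""


class CoverageError(ValidationError):
    """A physiological trace does not cover the requested time interval."""


class DegenerateSignalError(ValidationError):
    """A signal is constant (or otherwise degenerate) where variation is required."""


class IllPosedError(RespiroError):
    """A cross-validation fold or linear system is ill posed."""
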