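"""Exception hierarchy with stable, machine-readable error classes.

Every exception carries an ``error_class`` token that the CLI prints on a
single line, so scripted callers can dispatch on failures without parsing
prose messages.
"""

from __future__ import annotations


class CytoportError(Exception):
    """Base class for all package errors."""

    error_class = "ERROR"


class MalformedFileError(CytoportError):
    error_class = "MALFORMED_FILE"


class UnsupportedModeError(CytoportError):
    error_class = "UNSUPPORTED_MODE"


class InvalidSampleError(CytoportError):
    error_class = "INVALID_SAMPLE"


class InvalidTransformError(CytoportError):
    error_class = "INVALID_TRANSFORM"


class UnsupportedTransformError(CytoportError):
    error_class = "UNSUPPORTED_TRANSFORM"


class MalformedSpilloverError(CytoportError):
    error_class = "MALFORMED_SPILLOVER"


class SingularMatrixError(CytoportError):
    error_class = "SINGULAR_MATRIX"


class UnresolvedChannelError(CytoportError):
    error_class = "UNRESOLVED_CHANNEL"


class UnresolvedCompensationError(CytoportError):
    error_class = "UNRESOLVED_COMPENSATION"


class InvalidGateError(CytoportError):
    error_class = "INVALID_GATE"


class UnknownPopulationError(CytoportError):
    error_class = "UNKNOWN_POPULATION"


class LabelLengthError(CytoportError):
    error_class = "LABEL_LENGTH"


class GateCycleError(CytoportError):
    error_class = "GATE_CYCLE"


class UnsupportedGateError(CytoportError):
    error_class = "UNSUPPORTED_GATE"


class DanglingReferenceError(CytoportError):
    error_class = "DANGLING_REFERENCE"


class UnsupportedExportError(CytoportError):
    """Raised when a workspace holds features the target dialect cannot carry."""

    error_class = "UNSUPPORTED_EXPORT"


class MalformedContainerError(CytoportError):
    error_class = "MALFORMED_CONTAINER"


class MissingFileError(CytoportError):
    error_class = "MISSING_FILE"


class InvalidSpecError(CytoportError):
    error_class = "INVALID_SPEC"


class UsageError(CytoportError):
    error_class = "USAGE"
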