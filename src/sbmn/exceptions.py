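"""Exception hierarchy: validation, configuration, state and numerical errors
map onto distinct CLI exit codes."""


class SBMNError(Exception):
    """Base class for package errors."""

    exit_code = 1


class ValidationError(SBMNError, ValueError):
    """Malformed arguments: bad shapes, dimensions, or enum values."""

    exit_code = 2


class ConfigurationError(SBMNError):
    """Inconsistent configuration, e.g. backbone/input mismatch."""

    exit_code = 2


class StateError(SBMNError):
    """Operation illegal in the current mode, e.g. writing frozen memory."""

    exit_code = 3


class NumericalError(SBMNError):
    """Non-finite values encountered during optimization."""

    exit_code = 4
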