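"""Exception types shared across the package."""


class PpgafError(Exception):
    """Base class for all package errors."""


class ParameterError(PpgafError, ValueError):
    """A configuration field is invalid; the message names the field."""


class InputError(PpgafError, ValueError):
    """A data input violates an operation's precondition."""


class DegenerateInputError(InputError):
    """Input is degenerate for the operation (e.g. a constant signal)."""


class InsufficientBeatsError(InputError):
    """Too few beats were detected/supplied for interval-based analysis."""
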