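"""Exception hierarchy.

All package errors derive from :class:`ChromsigError` so callers can catch
one base class; the CLI maps subclasses onto exit codes (validation -> 2,
degenerate data -> 3).
"""


class ChromsigError(Exception):
    """Base class for all package errors."""


class FormatError(ChromsigError):
    """A file could not be parsed in the declared dialect."""


class ValidationError(ChromsigError):
    """Input violates a documented precondition (e.g. negative IF value)."""


class DegenerateDataError(ChromsigError):
    """Input is structurally valid but carries no usable signal
    (all-zero matrix, empty feature intersection, single-class labels)."""


class ContractError(ChromsigError):
    """Internal contract violation between components
    (e.g. vectorizing an unmeasured cell under the strict policy)."""
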