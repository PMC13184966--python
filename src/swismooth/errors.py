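"""Exception hierarchy shared across the package.

Error classes map onto the CLI exit-code contract: format/input problems
exit 2, violated preconditions exit 3.
"""


class SwismoothError(Exception):
    """Base class for all package errors."""


class FormatError(SwismoothError, ValueError):
    """Malformed or inconsistent input file / table."""


class EmptyInputError(SwismoothError, ValueError):
    """An operation received zero usable rows or values."""


class PreconditionError(SwismoothError, ValueError):
    """A documented precondition of an operation is not met."""


class InvalidBoundsError(PreconditionError):
    """Degenerate or inverted spatial bounds."""
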