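"""Exception hierarchy shared across the pipeline.

``ValidationError`` marks bad user input or data that violates a stated
invariant (CLI exit code 1); everything else is an internal error (exit 2).
"""


class SpringboardError(Exception):
    """Base class for all package errors."""


class ValidationError(SpringboardError, ValueError):
    """Input data or configuration violates a precondition or invariant."""


class ParseError(ValidationError):
    """A delimited-text export could not be parsed; names the offending line."""


class DomainError(SpringboardError, ValueError):
    """A mathematically undefined operation (zero divisor, empty domain)."""
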