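"""Exception hierarchy shared by all modules.

Exit-code mapping used by the CLI: configuration errors exit 2, input /
parse errors exit 3, domain errors exit 4.
"""


class LocohdError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(LocohdError):
    """Bad scheme name, unknown option, malformed rule table."""

    exit_code = 2


class ParseError(LocohdError):
    """Unreadable or malformed input file."""

    exit_code = 3


class DomainError(LocohdError):
    """Valid inputs that violate an operation's preconditions."""

    exit_code = 4


class EmptyStructureError(DomainError):
    """A structure ended up with no usable residues/atoms."""


class PairingError(DomainError):
    """Chain pairing between two structures failed."""
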