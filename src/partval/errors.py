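"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, FormatError and
IntegrityError -> 3.
"""


class PartvalError(Exception):
    """Base class for all package errors."""


class ConfigError(PartvalError):
    """Invalid or inconsistent configuration."""


class FormatError(PartvalError):
    """A file does not conform to the expected format (e.g. missing column)."""


class IntegrityError(PartvalError):
    """A file parses but violates structural invariants (ranks, ordering)."""
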