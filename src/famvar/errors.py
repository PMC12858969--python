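"""Exception hierarchy.

Distinct classes map to distinct CLI exit codes: validation problems
(bad values, inconsistent inputs), configuration problems (unknown
keys, impossible settings), structural problems in a pedigree, and
parse errors in input files.
"""


class FamvarError(Exception):
    """Base class for all errors raised by famvar."""


class ValidationError(FamvarError):
    """A value or combination of values violates a documented invariant."""


class ConfigurationError(FamvarError):
    """A configuration key, dialect or profile is unusable as given."""


class StructuralError(FamvarError):
    """A pedigree is malformed: dangling parent, duplicate id, cycle."""


class ParseError(FamvarError):
    """An input file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
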