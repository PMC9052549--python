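"""Exception hierarchy.

Every user-facing rejection raises a subclass of :class:`BmcTyperError` with a
message naming the offending record, row, column, or line where applicable.
"""


class BmcTyperError(Exception):
    """Base class for all errors raised by bmctyper."""


class InvalidAlignmentError(BmcTyperError):
    """A training alignment is empty, ragged, or has no usable match column."""


class InvalidSequenceError(BmcTyperError):
    """A protein sequence is empty or otherwise unusable."""


class FastaError(BmcTyperError):
    """A multi-FASTA input violates the input contract (duplicates, empties)."""


class FormatError(BmcTyperError):
    """A structured text file (HMMER3 profile, library, registry) is malformed."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class RegistryError(BmcTyperError):
    """A type registry violates its invariants or a type id is unknown."""


class EmptyResultError(BmcTyperError):
    """An operation that contractually requires content received none."""
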