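"""Exception hierarchy.

Everything raised on purpose derives from :class:`ConcatKitError`, so callers
(and the CLI) can distinguish data problems from bugs.
"""


class ConcatKitError(Exception):
    """Base class for all errors raised by concatkit."""


class TokenError(ConcatKitError):
    """A marker or sample name is not a safe token (``[A-Za-z0-9_.-]+``)."""


class AlphabetError(ConcatKitError):
    """A residue character is outside the IUPAC nucleotide alphabet."""


class DuplicateSampleError(ConcatKitError):
    """Two records in one marker share a sample name."""


class DuplicateMarkerError(ConcatKitError):
    """Two markers share a name."""


class UnknownMarkerError(ConcatKitError):
    """A named marker does not exist in the matrix."""


class InvalidOrderError(ConcatKitError):
    """A reorder request is not a permutation of the marker names."""


class EmptyInputError(ConcatKitError):
    """An input (file, block, matrix) contains no data."""


class FormatError(ConcatKitError):
    """A file does not parse under its declared format."""


class NotAlignedError(ConcatKitError):
    """An operation requiring uniform sequence length met a ragged block."""


class PartitionError(ConcatKitError):
    """Character sets overlap or fail to tile the alignment."""


class NameCollisionError(ConcatKitError):
    """A renaming/display-name map sends two samples to the same name."""


class UnknownFormatError(ConcatKitError):
    """Content sniffing could not classify an input."""


class InsufficientDataError(ConcatKitError):
    """Too few sequences for the requested statistic (quartiles need >= 4)."""


class FixtureSpecError(ConcatKitError):
    """A synthetic-data specification is internally inconsistent."""


class ExternalToolError(ConcatKitError):
    """An external program (aligner, tree builder) is missing or failed."""
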