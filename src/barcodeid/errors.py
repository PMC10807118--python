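"""Exception hierarchy.

Every user-facing failure mode gets a distinct, named exception so the CLI
can map them to stable exit codes and tests can assert on the cause.
"""


class BarcodeIdError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class ParameterError(BarcodeIdError):
    """A user parameter is out of its documented range."""

    exit_code = 2


class MissingInputError(BarcodeIdError):
    """A required input file does not exist."""

    exit_code = 3


class EmptyLibraryError(BarcodeIdError):
    """The reference library FASTA contains no sequences."""

    exit_code = 4


class DuplicateIdentifierError(BarcodeIdError):
    """Two reference sequences share the same identifier."""

    exit_code = 5


class InvalidSequenceError(BarcodeIdError):
    """A sequence contains characters outside the IUPAC nucleotide alphabet."""

    exit_code = 6


class LineageParseError(BarcodeIdError):
    """An identifier yields an empty lineage under the chosen convention."""

    exit_code = 7


class ExternalToolError(BarcodeIdError):
    """The external aligner or database builder is missing or failed."""

    exit_code = 8


class HitTableFormatError(BarcodeIdError):
    """A tabular hit file has the wrong shape or unparseable values."""

    exit_code = 9


class CheckTagError(BarcodeIdError):
    """The taxa-warning CSV is malformed."""

    exit_code = 10


class PipelineInternalError(BarcodeIdError):
    """Internal consistency violation — a bug, not a user error."""

    exit_code = 70
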