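"""Exception hierarchy shared across the package."""


class SeqComplexityError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(SeqComplexityError):
    """Raised for malformed FASTA input (missing header, empty file)."""


class ValidationError(SeqComplexityError):
    """Raised in strict mode when a sequence contains a non-IUPAC character."""


class EmptyInputError(SeqComplexityError):
    """Raised when an operation receives an empty sequence or file."""


class ParameterError(SeqComplexityError):
    """Raised when a parameter (e.g. k, read length) is out of range."""


class ConsistencyError(SeqComplexityError):
    """Raised when paired inputs (sequence vs index) disagree in shape."""


class EvaluationError(SeqComplexityError):
    """Raised when an alignment record cannot be evaluated (bad read name)."""


class InsufficientDataError(SeqComplexityError):
    """Raised when a correlation cell has fewer than three shared genomes."""


class UndefinedStatisticError(SeqComplexityError):
    """Raised when a statistic is undefined (constant input, zero length)."""
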