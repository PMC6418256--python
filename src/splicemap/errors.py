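"""Exception hierarchy shared across the toolkit."""


class SpliceMapError(Exception):
    """Base class for all splicemap errors."""


class ParseError(SpliceMapError):
    """Malformed notation or file content."""


class CoordinateError(SpliceMapError):
    """A position does not resolve within the given sequence or transcript."""


class SequenceError(SpliceMapError):
    """Invalid nucleotide content."""


class ModelError(SpliceMapError):
    """Inconsistent gene/transcript model."""


class ConfigError(SpliceMapError):
    """Invalid configuration."""


class DataError(SpliceMapError):
    """Input data inconsistent with the reference (e.g. REF allele mismatch)."""


class UsageError(SpliceMapError):
    """An operation was applied to an input outside its contract."""


class AnnotationError(SpliceMapError):
    """Invalid external annotation (e.g. domain interval beyond protein length)."""


class UndefinedResultError(SpliceMapError):
    """The requested statistic is undefined for this input (e.g. empty margin)."""
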