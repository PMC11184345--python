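"""Exception hierarchy.

Everything raised on bad *data* derives from :class:`HapnetError` so the
command line can map it to a single exit code; genuine usage mistakes
(unknown flags, bad option values) stay with click.
"""


class HapnetError(Exception):
    """Base class for all data-level errors."""


class MalformedInputError(HapnetError):
    """An identifier or file fragment that cannot be interpreted."""


class AlignmentLengthError(HapnetError):
    """Ragged alignment: a record's length differs from the first record."""


class DuplicateRecordError(HapnetError):
    """Two records share the same (individual, allele) pair."""


class AlphabetError(HapnetError):
    """A residue outside the DNA + IUPAC ambiguity alphabet."""


class ParseError(HapnetError):
    """Unparseable file content (Newick, SPART, GraphML...)."""


class DuplicateTipError(ParseError):
    """A Newick tree with two identically labelled tips."""


class CoverageError(HapnetError):
    """A spartition does not cover exactly the document's individuals."""


class PartitionLookupError(HapnetError):
    """Requested spartition name/index does not exist."""


class UnphasedInputError(HapnetError):
    """Ambiguity codes found where phased/haploid sequences are required."""


class AlreadyPhasedError(HapnetError):
    """Phasing requested on records that already carry allele tags."""


class ComplexityError(HapnetError):
    """A combinatorial cap (het-site enumeration, median candidates) exceeded."""


class EmptyInputError(HapnetError):
    """An operation that needs at least one record received none."""


class DegenerateInputError(HapnetError):
    """Too few taxa for the requested reconstruction."""


class MissingSequenceError(HapnetError):
    """A tree tip has no corresponding sequence."""


class FeasibilityError(HapnetError):
    """A simulation spec that cannot be satisfied."""
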