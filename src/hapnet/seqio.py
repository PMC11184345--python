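"""Reading and writing aligned single-locus sequences.

Sequences arrive either phased — two records per diploid individual whose
labels end in ``_a`` / ``_b`` — or unphased, one diploid consensus per
individual with IUPAC ambiguity codes at heterozygous positions.  Haploid
markers (mtDNA and the like) are simply records without allele tags.

Identifier grammar.  A FASTA header is ``individual[_a|_b][|subset]``; the
subset (candidate species) label may alternatively follow the first
whitespace run, as in plain FASTA descriptions.  Allele detection is
strictly the lowercase two-character terminal ``_a``/``_b`` so that names
like ``Sample_3`` survive untouched.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import Phylo

from .errors import (
    AlignmentLengthError,
    AlphabetError,
    DuplicateRecordError,
    DuplicateTipError,
    MalformedInputError,
    ParseError,
)

# DNA + gap + the 11 IUPAC ambiguity letters (N included).
IUPAC_TO_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
BASES_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_TO_BASES.items()}
ALPHABET = set(IUPAC_TO_BASES) | {"-"}

TABLE_HEADER = ("individual", "subset", "allele", "sequence")


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence tagged with its individual and optional allele."""

    individual: str
    sequence: str
    allele: Optional[str] = None  # "a", "b" or None
    subset: Optional[str] = None

    def __post_init__(self):
        if not self.individual or re.search(r"\s", self.individual):
            raise MalformedInputError(
                f"invalid individual identifier {self.individual!r}"
            )
        if self.allele not in (None, "a", "b"):
            raise MalformedInputError(f"allele must be a/b/None, got {self.allele!r}")
        if not self.sequence:
            raise MalformedInputError(f"empty sequence for {self.individual!r}")

    @property
    def label(self) -> str:
        """Reassembled identifier, without the subset part."""
        return self.individual + (f"_{self.allele}" if self.allele else "")


@dataclass
class Alignment:
    """An ordered, validated collection of equal-length records."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen = set()
        alleles: dict[str, set] = {}
        for rec in self.records:
            if len(rec.sequence) != self.length:
                raise AlignmentLengthError(
                    f"record {rec.label!r} has length {len(rec.sequence)}, "
                    f"expected {self.length}"
                )
            key = (rec.individual, rec.allele)
            if key in seen:
                raise DuplicateRecordError(
                    f"duplicate record for individual {rec.individual!r}"
                    + (f" allele {rec.allele!r}" if rec.allele else "")
                )
            seen.add(key)
            alleles.setdefault(rec.individual, set()).add(rec.allele)
        for ind, al in alleles.items():
            if al & {"a", "b"} and al != {"a", "b"}:
                raise DuplicateRecordError(
                    f"individual {ind!r} has alleles {sorted(map(str, al))}, "
                    "expected exactly a and b"
                )

    @property
    def length(self) -> int:
        return len(self.records[0].sequence) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other):
        return isinstance(other, Alignment) and self.records == other.records

    @property
    def individuals(self) -> list[str]:
        out, seen = [], set()
        for rec in self.records:
            if rec.individual not in seen:
                seen.add(rec.individual)
                out.append(rec.individual)
        return out


def parse_identifier(label: str) -> tuple[str, Optional[str], Optional[str]]:
    """Split a sequence label into (individual, allele, subset).

    >>> parse_identifier("Ind2_b|SpeciesA")
    ('Ind2', 'b', 'SpeciesA')
    """
    if not label or not label.strip():
        raise MalformedInputError("empty sequence label")
    label = label.strip()
    subset = None
    if "|" in label:
        name, subset = label.split("|", 1)
        subset = subset.strip() or None
    else:
        m = re.search(r"\s+", label)
        if m:
            name, subset = label[: m.start()], label[m.end():].strip() or None
        else:
            name = label
    name = name.strip()
    if not name:
        raise MalformedInputError(f"label {label!r} has no individual part")
    allele = None
    if name.endswith(("_a", "_b")):
        allele = name[-1]
        name = name[:-2]
        if not name:
            raise MalformedInputError(f"label {label!r} is only an allele suffix")
    return name, allele, subset


def _clean_sequence(raw: str, label: str) -> str:
    seq = raw.upper().replace("U", "T")
    for col, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise AlphabetError(
                f"record {label!r}: unknown residue {ch!r} at column {col + 1}"
            )
    return seq


def _records_from_fasta(text: str) -> Iterable[SequenceRecord]:
    header, chunks = None, []
    entries = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                entries.append((header, "".join(chunks)))
            header, chunks = line[1:], []
        elif header is None:
            raise ParseError("FASTA content before the first '>' header")
        else:
            chunks.append(line)
    if header is not None:
        entries.append((header, "".join(chunks)))
    for header, seq in entries:
        individual, allele, subset = parse_identifier(header)
        yield SequenceRecord(
            individual=individual,
            allele=allele,
            subset=subset,
            sequence=_clean_sequence(seq, header),
        )


def _records_from_table(text: str) -> Iterable[SequenceRecord]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return
    header = tuple(c.strip().lower() for c in lines[0].split("\t"))
    if header != TABLE_HEADER:
        raise ParseError(
            f"table header must be {TABLE_HEADER}, got {header}"
        )
    for num, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != 4:
            raise ParseError(f"line {num}: expected 4 tab-separated columns")
        individual, subset, allele, seq = (c.strip() for c in cells)
        if allele not in ("", "a", "b"):
            raise MalformedInputError(f"line {num}: allele must be empty, a or b")
        yield SequenceRecord(
            individual=individual,
            allele=allele or None,
            subset=subset or None,
            sequence=_clean_sequence(seq, individual),
        )


def read_sequences(path, format: str = "auto") -> Alignment:
    """Read an alignment from FASTA or a tab-delimited table.

    ``format="auto"`` sniffs a leading ``>`` for FASTA.
    """
    with open(path) as fh:
        text = fh.read()
    if format == "auto":
        stripped = text.lstrip()
        format = "fasta" if stripped.startswith(">") else "table"
    if format == "fasta":
        records = list(_records_from_fasta(text))
    elif format == "table":
        records = list(_records_from_table(text))
    else:
        raise ValueError(f"unknown format {format!r}")
    return Alignment(records)


def format_header(rec: SequenceRecord) -> str:
    return rec.label + (f"|{rec.subset}" if rec.subset else "")


def write_sequences(alignment: Alignment, path, format: str = "fasta") -> None:
    """Write an alignment; the exact inverse of :func:`read_sequences`."""
    buf = io.StringIO()
    if format == "fasta":
        for rec in alignment:
            buf.write(f">{format_header(rec)}\n{rec.sequence}\n")
    elif format == "table":
        buf.write("\t".join(TABLE_HEADER) + "\n")
        for rec in alignment:
            buf.write(
                f"{rec.individual}\t{rec.subset or ''}\t{rec.allele or ''}"
                f"\t{rec.sequence}\n"
            )
    else:
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_newick(path):
    """Read one Newick tree; returns a Bio.Phylo tree (polytomies allowed)."""
    try:
        tree = Phylo.read(path, "newick")
    except Exception as exc:  # NewickError and friends
        raise ParseError(f"cannot parse Newick file {path}: {exc}") from exc
    tips = [t.name for t in tree.get_terminals()]
    if len(tips) != len(set(tips)):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise DuplicateTipError(f"duplicate tip labels: {', '.join(dupes)}")
    return tree
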