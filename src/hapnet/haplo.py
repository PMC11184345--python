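"""Collapsing phased sequences into unique haplotypes and distances.

A haplotype is a unique allele sequence; its count is the number of
allele copies observed (two per diploid individual, one per haploid
record).  Ids H1, H2, ... follow first occurrence in input order so they
are stable across partition choices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import UnphasedInputError
from .phasing import TWO_FOLD
from .seqio import Alignment
from .spart import Spartition

UNASSIGNED = "unassigned"

GAP_MODES = ("complete-deletion", "pairwise", "fifth-state")
#: characters never counted as ordinary states in distance computation
_MISSING = set("NBDHVRYSWKM")


@dataclass
class Haplotype:
    id: str
    sequence: str
    members: list[tuple[str, Optional[str]]] = field(default_factory=list)
    per_subset_count: dict[str, int] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeCatalog:
    haplotypes: list[Haplotype]
    subset_of: dict[str, str] = field(default_factory=dict)  # individual -> subset

    def __iter__(self):
        return iter(self.haplotypes)

    def __len__(self):
        return len(self.haplotypes)

    def by_id(self, hap_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.id == hap_id:
                return h
        raise KeyError(hap_id)

    @property
    def total_count(self) -> int:
        return sum(h.count for h in self.haplotypes)

    def haplotypes_of(self, individual: str) -> list[str]:
        """Haplotype ids carried by an individual (one per allele copy)."""
        out = []
        for h in self.haplotypes:
            for ind, _allele in h.members:
                if ind == individual:
                    out.append(h.id)
        return out

    @property
    def individuals(self) -> list[str]:
        seen, out = set(), []
        for h in self.haplotypes:
            for ind, _ in h.members:
                if ind not in seen:
                    seen.add(ind)
                    out.append(ind)
        return out

    def expand(self) -> Alignment:
        """Re-expand the catalog into one record per member allele copy."""
        from .seqio import SequenceRecord

        records = []
        for h in self.haplotypes:
            for ind, allele in h.members:
                records.append(
                    SequenceRecord(
                        individual=ind,
                        allele=allele,
                        subset=self.subset_of.get(ind),
                        sequence=h.sequence,
                    )
                )
        # keep original input order: records were appended per haplotype,
        # so sort by first-occurrence order is not recoverable; callers that
        # need order-stability collapse again and compare catalogs instead.
        return Alignment(records)


def collapse_haplotypes(
    alignment: Alignment, partition: Optional[Spartition] = None
) -> HaplotypeCatalog:
    """Merge identical sequences into haplotypes with counts and members.

    Requires phased or haploid input: any two-fold ambiguity code is an
    error pointing at ``hapnet phase``.
    """
    for rec in alignment:
        bad = [c for c in rec.sequence if c in TWO_FOLD]
        if bad:
            raise UnphasedInputError(
                f"record {rec.label!r} contains ambiguity code {bad[0]!r}; "
                "run `hapnet phase` first"
            )
    subset_of: dict[str, str] = {}
    for rec in alignment:
        if partition is not None:
            subset = partition.assignment.get(rec.individual, UNASSIGNED)
        else:
            subset = rec.subset or UNASSIGNED
        prev = subset_of.setdefault(rec.individual, subset)
        if prev != subset:
            warnings.warn(
                f"individual {rec.individual!r} has conflicting subset labels "
                f"({prev!r} vs {subset!r}); keeping the first",
                stacklevel=2,
            )
    haplotypes: list[Haplotype] = []
    index: dict[str, Haplotype] = {}
    for rec in alignment:
        hap = index.get(rec.sequence)
        if hap is None:
            hap = Haplotype(id=f"H{len(haplotypes) + 1}", sequence=rec.sequence)
            haplotypes.append(hap)
            index[rec.sequence] = hap
        hap.members.append((rec.individual, rec.allele))
        subset = subset_of[rec.individual]
        hap.per_subset_count[subset] = hap.per_subset_count.get(subset, 0) + 1
    return HaplotypeCatalog(haplotypes, subset_of)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, int, zero diagonal
    used_columns: list[int]

    def value(self, id1: str, id2: str) -> int:
        return int(self.d[self.ids.index(id1), self.ids.index(id2)])


def used_columns_for(sequences: list[str], gap_mode: str = "complete-deletion") -> list[int]:
    """Columns retained for distance computation under a gap mode."""
    if not sequences:
        return []
    length = len(sequences[0])
    cols = []
    for col in range(length):
        chars = {s[col] for s in sequences}
        if chars & _MISSING:
            continue  # N-like characters always excluded
        if gap_mode == "complete-deletion" and "-" in chars:
            continue
        cols.append(col)
    return cols


def pairwise_distances(
    catalog: HaplotypeCatalog, gap_mode: str = "complete-deletion"
) -> DistanceMatrix:
    """Hamming distances between haplotypes over the retained columns.

    complete-deletion (default) drops every column holding a gap or an
    N-like character in any haplotype; pairwise drops such columns per
    pair; fifth-state keeps gap columns and counts ``-`` as a state
    (N-like columns stay excluded in all modes).
    """
    if gap_mode not in GAP_MODES:
        raise ValueError(f"gap_mode must be one of {GAP_MODES}")
    seqs = [h.sequence for h in catalog.haplotypes]
    n = len(seqs)
    used = used_columns_for(seqs, gap_mode)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            steps = 0
            for col in used:
                a, b = seqs[i][col], seqs[j][col]
                if gap_mode == "pairwise" and "-" in (a, b):
                    continue
                if a != b:
                    steps += 1
            d[i, j] = d[j, i] = steps
    if n and not used:
        warnings.warn("no columns usable for distances; matrix is all zero", stacklevel=2)
    return DistanceMatrix([h.id for h in catalog.haplotypes], d, used)
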