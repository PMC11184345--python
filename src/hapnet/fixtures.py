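"""Seeded synthetic diploid datasets with known truth.

The generator emulates the shape of a single-locus species-delimitation
dataset: a pool of K distinct haplotypes at an aligned locus of L bases,
diploid individuals drawing two haplotypes each under Hardy–Weinberg
random pairing, subsets (candidate species) with their own haplotype
pools, and an optional engineered heterozygote spanning two subsets'
pools to force allele sharing.  Defaults approximate a typical desk-scale
barcoding-adjacent dataset: a 500 bp locus, four haplotypes at uneven
frequencies, a few dozen individuals.

Everything is reproducible from the seed; mutations are substitutions
only, so true distances are Hamming distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import FeasibilityError
from .seqio import Alignment, BASES_TO_IUPAC, SequenceRecord
from .spart import SpartDocument, Spartition

BASES = "ACGT"


@dataclass
class SimSpec:
    seed: int = 42
    L: int = 500
    K: int = 4
    freqs: Optional[Sequence[float]] = None  # None: (0.4,0.3,0.2,0.1) for K=4, else uniform
    n: int = 40
    subsets: Optional[Sequence[int]] = None  # sizes; default one subset of n
    cross_sharing: bool = False
    mutation_scale: float = 5.0  # expected pairwise differences
    gap_columns: int = 0  # columns turned into gaps in one haplotype

    def __post_init__(self):
        if self.freqs is None:
            self.freqs = (
                (0.4, 0.3, 0.2, 0.1) if self.K == 4 else [1.0 / self.K] * self.K
            )
        if len(self.freqs) != self.K:
            raise FeasibilityError("freqs length must equal K")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise FeasibilityError("freqs must sum to 1")
        if self.subsets is None:
            self.subsets = [self.n]
        if sum(self.subsets) != self.n:
            raise FeasibilityError("subset sizes must sum to n")
        if self.L < self.K - 1:
            raise FeasibilityError(
                f"L={self.L} cannot distinguish K={self.K} haplotypes"
            )
        if self.cross_sharing and len(self.subsets) < 2:
            raise FeasibilityError("cross_sharing needs at least two subsets")


@dataclass
class SimulatedDataset:
    unphased: Alignment
    phased_truth: Alignment
    spartition: Spartition
    haplotypes: list[str]  # the K true sequences
    frequencies: list[float]

    @property
    def spart_document(self) -> SpartDocument:
        return SpartDocument(
            project="simulated",
            spartitions=[self.spartition],
            individuals=list(self.spartition.assignment),
        )


def _consensus(seq_a: str, seq_b: str) -> str:
    out = []
    for x, y in zip(seq_a, seq_b):
        if x == y:
            out.append(x)
        elif "-" in (x, y):
            out.append("N")  # base/gap conflicts cannot be coded; mask
        else:
            out.append(BASES_TO_IUPAC[frozenset((x, y))])
    return "".join(out)


def _make_haplotypes(rng: np.random.Generator, spec: SimSpec) -> list[str]:
    ancestor = "".join(rng.choice(list(BASES), size=spec.L))
    haps = [ancestor]
    attempts = 0
    while len(haps) < spec.K:
        parent = haps[int(rng.integers(len(haps)))]
        n_mut = 1 + int(rng.poisson(max(spec.mutation_scale / 2.0 - 1.0, 0.0)))
        n_mut = min(n_mut, spec.L)
        cols = rng.choice(spec.L, size=n_mut, replace=False)
        seq = list(parent)
        for col in cols:
            seq[col] = rng.choice([b for b in BASES if b != seq[col]])
        candidate = "".join(seq)
        attempts += 1
        if candidate not in haps:
            haps.append(candidate)
        elif attempts > 100 * spec.K:
            raise FeasibilityError(
                f"could not generate {spec.K} distinct haplotypes at L={spec.L}"
            )
    if spec.gap_columns:
        gap_cols = rng.choice(spec.L, size=min(spec.gap_columns, spec.L),
                              replace=False)
        seq = list(haps[-1])
        for col in gap_cols:
            seq[col] = "-"
        haps[-1] = "".join(seq)
        if haps[-1] in haps[:-1]:
            raise FeasibilityError("gap injection collapsed two haplotypes")
    return haps


def simulate_dataset(spec: SimSpec) -> SimulatedDataset:
    """Generate (unphased, truth) alignments plus the true spartition."""
    rng = np.random.default_rng(spec.seed)
    haps = _make_haplotypes(rng, spec)
    freqs = list(spec.freqs)

    # split the haplotype pool round-robin across subsets
    n_sub = len(spec.subsets)
    pools: list[list[int]] = [[] for _ in range(n_sub)]
    for k in range(spec.K):
        pools[k % n_sub].append(k)
    if any(not p for p in pools):
        raise FeasibilityError("more subsets than haplotypes")

    unphased_records, phased_records = [], []
    assignment: dict[str, str] = {}
    idx = 0
    for s, size in enumerate(spec.subsets):
        subset_name = f"S{s + 1}" if n_sub > 1 else "S1"
        pool = pools[s]
        pool_freqs = np.array([freqs[k] for k in pool])
        pool_freqs = pool_freqs / pool_freqs.sum()
        for member in range(size):
            idx += 1
            ind = f"I{idx}"
            assignment[ind] = subset_name
            ka, kb = rng.choice(pool, size=2, p=pool_freqs)
            if spec.cross_sharing and s == 1 and member == 0:
                # engineered heterozygote spanning the first two pools
                ka = pools[0][0]
                kb = pools[1][0]
            pair = sorted((haps[ka], haps[kb]))
            unphased_records.append(
                SequenceRecord(individual=ind, subset=subset_name,
                               sequence=_consensus(*pair))
            )
            for allele, seq in zip("ab", pair):
                phased_records.append(
                    SequenceRecord(individual=ind, allele=allele,
                                   subset=subset_name, sequence=seq)
                )
    spartition = Spartition(name="truth", assignment=assignment)
    return SimulatedDataset(
        unphased=Alignment(unphased_records),
        phased_truth=Alignment(phased_records),
        spartition=spartition,
        haplotypes=haps,
        frequencies=freqs,
    )
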