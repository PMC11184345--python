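"""Haplotype phasing of diploid consensus sequences.

A diploid individual sequenced at a single locus yields one consensus
sequence in which heterozygous positions appear as two-fold IUPAC
ambiguity codes (R, Y, S, W, K, M).  Phasing resolves each consensus into
the two constituent allele sequences, written out as ``<individual>_a``
and ``<individual>_b``.

The resolver is an expectation–maximisation (EM) estimator of population
haplotype frequencies under random pairing (Hardy–Weinberg), in the
tradition of multinomial gene-counting phasing.  It is a deliberately
simple, deterministic stand-in for Bayesian coalescent samplers: the
E-step weights every phase pair consistent with an individual's genotype
by the product of current haplotype frequencies, the M-step re-estimates
frequencies from those weights, and each individual finally receives its
maximum-posterior pair.

Sites whose code expands to three or four bases (including N) cannot come
from a diploid genotype at a single site; they are treated as missing —
excluded from phasing and copied verbatim to both alleles, with a warning.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

from .errors import (
    AlreadyPhasedError,
    AlphabetError,
    ComplexityError,
    EmptyInputError,
)
from .seqio import Alignment, IUPAC_TO_BASES, SequenceRecord

TWO_FOLD = {c for c, b in IUPAC_TO_BASES.items() if len(b) == 2}
MULTI_FOLD = {c for c, b in IUPAC_TO_BASES.items() if len(b) > 2}


def split_iupac(code: str) -> frozenset:
    """Expansion set of a single IUPAC character; identity on A/C/G/T."""
    try:
        return frozenset(IUPAC_TO_BASES[code])
    except KeyError:
        raise AlphabetError(f"unknown IUPAC code {code!r}") from None


@dataclass
class Genotype:
    """An unphased diploid consensus with its heterozygous columns."""

    individual: str
    sequence: str
    subset: Optional[str] = None
    het_sites: list[int] = field(default_factory=list)

    def __post_init__(self):
        expected = [i for i, c in enumerate(self.sequence) if c in TWO_FOLD]
        if not self.het_sites:
            self.het_sites = expected
        elif self.het_sites != expected:
            raise ValueError("het_sites do not match the two-fold code columns")
        fuzzy = [i for i, c in enumerate(self.sequence) if c in MULTI_FOLD]
        if fuzzy:
            warnings.warn(
                f"{self.individual}: {len(fuzzy)} column(s) with 3-4-base "
                "ambiguity codes treated as missing and copied to both alleles",
                stacklevel=2,
            )


@dataclass
class PhasePair:
    """Two phased allele sequences; hapA <= hapB lexicographically."""

    hapA: str
    hapB: str
    posterior: Optional[float] = None


def enumerate_phase_pairs(g: Genotype, cap: int = 16) -> list[PhasePair]:
    """All unordered haplotype pairs consistent with a genotype.

    With h heterozygous sites there are exactly ``max(1, 2**(h-1))``
    distinct unordered pairs (the first het site can be fixed to one base
    without loss of generality).
    """
    h = len(g.het_sites)
    if h > cap:
        raise ComplexityError(
            f"{g.individual}: {h} heterozygous sites exceed the enumeration "
            f"cap {cap}; raise it with --het-cap if this is intended"
        )
    template = list(g.sequence)
    if h == 0:
        seq = "".join(template)
        return [PhasePair(seq, seq)]
    expansions = [sorted(IUPAC_TO_BASES[g.sequence[i]]) for i in g.het_sites]
    pairs = []
    # fix the first het site of hapA to the first base: halves the space
    for choice in itertools.product(*[(0, 1)] * (h - 1)):
        a, b = template[:], template[:]
        picks = (0,) + choice
        for site, bases, pick in zip(g.het_sites, expansions, picks):
            a[site] = bases[pick]
            b[site] = bases[1 - pick]
        hapA, hapB = "".join(a), "".join(b)
        if hapB < hapA:
            hapA, hapB = hapB, hapA
        pairs.append(PhasePair(hapA, hapB))
    return pairs


@dataclass
class EMResult:
    pairs: list[PhasePair]  # max-posterior pair per input genotype
    frequencies: dict[str, float]  # haplotype sequence -> frequency
    log_likelihoods: list[float]  # one entry per EM iteration
    converged: bool


def em_phase(
    genotypes: list[Genotype],
    tol: float = 1e-8,
    max_iter: int = 1000,
    het_cap: int = 16,
) -> EMResult:
    """EM estimation of haplotype frequencies and maximum-posterior phasing.

    The complete-data model draws two haplotypes per individual i.i.d.
    from the population frequency vector; a heterozygous pair (x, y) has
    probability 2 p_x p_y, a homozygous pair p_x^2.  The log-likelihood is
    non-decreasing across iterations (a standard EM guarantee, asserted in
    the test-suite on every run).
    """
    if not genotypes:
        raise EmptyInputError("em_phase needs at least one genotype")
    lengths = {len(g.sequence) for g in genotypes}
    if len(lengths) != 1:
        raise ValueError("genotypes have differing lengths")

    support = [enumerate_phase_pairs(g, cap=het_cap) for g in genotypes]
    universe = sorted({h for pairs in support for p in pairs for h in (p.hapA, p.hapB)})
    freq = {h: 1.0 / len(universe) for h in universe}

    def pair_weight(p: PhasePair) -> float:
        w = freq[p.hapA] * freq[p.hapB]
        return w if p.hapA == p.hapB else 2.0 * w

    loglik_trace: list[float] = []
    converged = False
    responsibilities: list[list[float]] = []
    for _ in range(max_iter):
        # E-step
        loglik = 0.0
        responsibilities = []
        for pairs in support:
            weights = [pair_weight(p) for p in pairs]
            total = sum(weights)
            if total <= 0.0:
                # numerically extinct support; re-spread uniformly
                weights = [1.0] * len(pairs)
                total = float(len(pairs))
            loglik += math.log(total)
            responsibilities.append([w / total for w in weights])
        loglik_trace.append(loglik)
        if len(loglik_trace) >= 2:
            prev = loglik_trace[-2]
            if loglik - prev <= tol * max(1.0, abs(prev)):
                converged = True
                break
        # M-step
        counts = dict.fromkeys(universe, 0.0)
        for pairs, resp in zip(support, responsibilities):
            for p, r in zip(pairs, resp):
                counts[p.hapA] += r
                counts[p.hapB] += r
        total = 2.0 * len(genotypes)
        freq = {h: c / total for h, c in counts.items()}
    if not converged:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations; "
            "returning the best state reached",
            stacklevel=2,
        )

    chosen: list[PhasePair] = []
    for pairs, resp in zip(support, responsibilities):
        # ties on posterior: lexicographically smallest (hapA, hapB) wins
        best_r = max(resp)
        tied = [k for k in range(len(pairs)) if resp[k] == best_r]
        best = min(tied, key=lambda k: (pairs[k].hapA, pairs[k].hapB))
        chosen.append(PhasePair(pairs[best].hapA, pairs[best].hapB, resp[best]))
    return EMResult(chosen, freq, loglik_trace, converged)


def phase_alignment(
    alignment: Alignment,
    tol: float = 1e-8,
    max_iter: int = 1000,
    het_cap: int = 16,
    seed: int = 42,
) -> Alignment:
    """Phase every individual of an unphased alignment.

    Output carries exactly two records (alleles a and b) per individual,
    subset labels propagated.  The estimator itself is deterministic; the
    seed parameter exists for interface symmetry with the simulator and
    does not influence the result.
    """
    del seed  # deterministic by construction
    if any(rec.allele is not None for rec in alignment):
        raise AlreadyPhasedError(
            "input already carries _a/_b allele tags; phasing refused"
        )
    genotypes = [
        Genotype(individual=rec.individual, sequence=rec.sequence, subset=rec.subset)
        for rec in alignment
    ]
    result = em_phase(genotypes, tol=tol, max_iter=max_iter, het_cap=het_cap)
    records = []
    for g, pair in zip(genotypes, result.pairs):
        for allele, seq in (("a", pair.hapA), ("b", pair.hapB)):
            records.append(
                SequenceRecord(
                    individual=g.individual,
                    allele=allele,
                    subset=g.subset,
                    sequence=seq,
                )
            )
    return Alignment(records)


def has_heterozygous_codes(alignment: Alignment) -> bool:
    """True if any record contains a two-fold ambiguity code."""
    return any(c in TWO_FOLD for rec in alignment for c in rec.sequence)
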