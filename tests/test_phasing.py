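import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hapnet import phasing
from hapnet.errors import AlreadyPhasedError, AlphabetError, ComplexityError, EmptyInputError
from hapnet.fixtures import SimSpec, simulate_dataset
from hapnet.phasing import Genotype, em_phase, enumerate_phase_pairs, phase_alignment, split_iupac
from hapnet.seqio import IUPAC_TO_BASES, Alignment, SequenceRecord


@pytest.mark.parametrize("code, bases", [
    ("R", {"A", "G"}), ("Y", {"C", "T"}), ("S", {"C", "G"}),
    ("W", {"A", "T"}), ("K", {"G", "T"}), ("M", {"A", "C"}),
    ("N", {"A", "C", "G", "T"}), ("A", {"A"}), ("T", {"T"}),
])
def test_split_iupac(code, bases):
    assert split_iupac(code) == frozenset(bases)


def test_split_iupac_rejects_unknown():
    with pytest.raises(AlphabetError):
        split_iupac("X")


@pytest.mark.parametrize("seq, expected_pairs", [
    ("ACGT", 1),   # h=0
    ("ACGR", 1),   # h=1
    ("RYGT", 2),   # h=2
    ("RYWT", 4),   # h=3
])
def test_enumeration_count(seq, expected_pairs):
    pairs = enumerate_phase_pairs(Genotype(individual="x", sequence=seq))
    assert len(pairs) == expected_pairs
    # distinct unordered pairs, each consistent with the genotype
    assert len({(p.hapA, p.hapB) for p in pairs}) == expected_pairs
    for p in pairs:
        assert p.hapA <= p.hapB
        for col, code in enumerate(seq):
            assert {p.hapA[col], p.hapB[col]} == set(IUPAC_TO_BASES[code])


def test_enumeration_cap():
    seq = "R" * 17
    with pytest.raises(ComplexityError, match="het-cap"):
        enumerate_phase_pairs(Genotype(individual="x", sequence=seq))


def test_em_requires_input():
    with pytest.raises(EmptyInputError):
        em_phase([])


def test_homozygous_population_recovers_proportions():
    genos = (
        [Genotype(individual=f"a{i}", sequence="AAAA") for i in range(6)]
        + [Genotype(individual=f"b{i}", sequence="TTTT") for i in range(2)]
    )
    res = em_phase(genos)
    assert res.converged
    assert res.frequencies["AAAA"] == pytest.approx(0.75)
    assert res.frequencies["TTTT"] == pytest.approx(0.25)
    assert all(p.posterior == pytest.approx(1.0) for p in res.pairs)


def test_het_resolved_toward_common_haplotypes():
    """A single RY individual among AT/GC homozygotes phases to (AT, GC).

    Oracle: with frequency mass concentrated on AT and GC, the complete
    likelihood of the pairing (AT, GC) is 2 p_AT p_GC, strictly larger
    than 2 p_AC p_GT for the alternative; verified here by evaluating
    both products under the fitted frequencies.
    """
    genos = (
        [Genotype(individual=f"a{i}", sequence="AT") for i in range(5)]
        + [Genotype(individual=f"g{i}", sequence="GC") for i in range(5)]
        + [Genotype(individual="het", sequence="RY")]
    )
    res = em_phase(genos)
    pair = res.pairs[-1]
    assert (pair.hapA, pair.hapB) == ("AT", "GC")
    f = res.frequencies
    assert f["AT"] * f["GC"] > f.get("AC", 0.0) * f.get("GT", 0.0)


def test_loglik_monotone_and_conservation():
    spec = SimSpec(seed=11, K=4, n=30, L=40)
    data = simulate_dataset(spec)
    genos = [
        Genotype(individual=r.individual, sequence=r.sequence)
        for r in data.unphased
    ]
    res = em_phase(genos)
    diffs = [b - a for a, b in zip(res.log_likelihoods, res.log_likelihoods[1:])]
    assert all(d >= -1e-9 for d in diffs)
    # conservation of genotype at every column of every individual
    for g, p in zip(genos, res.pairs):
        for col, code in enumerate(g.sequence):
            assert {p.hapA[col], p.hapB[col]} <= set(IUPAC_TO_BASES.get(code, code))


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_frequency_recovery(seed):
    """K=4 haplotypes at (0.4, 0.3, 0.2, 0.1), n=200 diploids: EM recovers
    the true frequencies within +/-0.05 (binomial standard error scale)."""
    spec = SimSpec(seed=seed, K=4, n=200, L=60)
    data = simulate_dataset(spec)
    genos = [
        Genotype(individual=r.individual, sequence=r.sequence)
        for r in data.unphased
    ]
    res = em_phase(genos)
    for hap, truth in zip(data.haplotypes, data.frequencies):
        assert res.frequencies.get(hap, 0.0) == pytest.approx(truth, abs=0.05)


def test_single_individual_symmetry():
    """With one individual every consistent pair is equally likely."""
    res = em_phase([Genotype(individual="x", sequence="RRY")])
    assert res.pairs[0].posterior == pytest.approx(0.25)


def test_phase_alignment_contract():
    aln = Alignment([
        SequenceRecord(individual="I1", sequence="ACGR", subset="X"),
        SequenceRecord(individual="I2", sequence="ACGT"),
    ])
    phased = phase_alignment(aln)
    assert [r.label for r in phased] == ["I1_a", "I1_b", "I2_a", "I2_b"]
    assert phased.records[0].subset == "X"
    # h=1: canonical order, exact phasing
    assert (phased.records[0].sequence, phased.records[1].sequence) == ("ACGA", "ACGG")
    # homozygote duplicated verbatim
    assert phased.records[2].sequence == phased.records[3].sequence == "ACGT"


def test_phase_alignment_refuses_phased_input(toy_phased_alignment):
    with pytest.raises(AlreadyPhasedError):
        phase_alignment(toy_phased_alignment)


def test_multibase_codes_are_copied_verbatim():
    with pytest.warns(UserWarning, match="missing"):
        g = Genotype(individual="x", sequence="ANR")
    pairs = enumerate_phase_pairs(g)
    assert len(pairs) == 1
    assert pairs[0].hapA[1] == pairs[0].hapB[1] == "N"


def test_phasing_is_deterministic():
    spec = SimSpec(seed=7, K=4, n=25, L=50)
    data = simulate_dataset(spec)
    out1 = phase_alignment(data.unphased)
    out2 = phase_alignment(data.unphased)
    assert out1 == out2


@given(st.text(alphabet="ACGTRYSWKM", min_size=1, max_size=10))
def test_enumeration_is_exhaustive(seq):
    """2**(h-1) distinct pairs, and every pair expands the genotype."""
    g = Genotype(individual="x", sequence=seq)
    h = len(g.het_sites)
    pairs = enumerate_phase_pairs(g)
    assert len(pairs) == max(1, 2 ** (h - 1))
    seen = set()
    for p in pairs:
        key = frozenset((p.hapA, p.hapB))
        assert key not in seen
        seen.add(key)
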