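import numpy as np
import pytest
from hypothesis import settings

from hapnet.haplo import collapse_haplotypes
from hapnet.seqio import Alignment, SequenceRecord

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

BASES = "ACGT"


def make_alignment(sequences, individuals=None, subsets=None):
    """Haploid alignment from plain sequence strings."""
    records = []
    for i, seq in enumerate(sequences):
        records.append(
            SequenceRecord(
                individual=(individuals[i] if individuals else f"I{i + 1}"),
                subset=(subsets[i] if subsets else None),
                sequence=seq,
            )
        )
    return Alignment(records)


def random_catalog(seed, max_haplotypes=6, length=30, min_haplotypes=2):
    """A random catalog of distinct sequences, for network oracles."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(min_haplotypes, max_haplotypes + 1))
    seqs = set()
    ancestor = "".join(rng.choice(list(BASES), size=length))
    seqs.add(ancestor)
    while len(seqs) < k:
        parent = sorted(seqs)[int(rng.integers(len(seqs)))]
        n_mut = int(rng.integers(1, max(2, length // 6)))
        cols = rng.choice(length, size=n_mut, replace=False)
        s = list(parent)
        for col in cols:
            s[col] = rng.choice([b for b in BASES if b != s[col]])
        seqs.add("".join(s))
    return collapse_haplotypes(make_alignment(sorted(seqs)))


def random_binary_tree(rng, tips):
    """Random rooted binary tree over tip labels as a Bio.Phylo tree."""
    from Bio.Phylo.BaseTree import Clade, Tree

    nodes = [Clade(name=t) for t in tips]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        parent = Clade()
        parent.clades = [a, b]
        nodes.append(parent)
    return Tree(root=nodes[0], rooted=True)


@pytest.fixture
def toy_phased_alignment():
    """Two diploids and one haploid sharing haplotypes across subsets."""
    return Alignment([
        SequenceRecord(individual="I1", allele="a", subset="X", sequence="ACGT"),
        SequenceRecord(individual="I1", allele="b", subset="X", sequence="ACGT"),
        SequenceRecord(individual="I2", allele="a", subset="X", sequence="ACGT"),
        SequenceRecord(individual="I2", allele="b", subset="X", sequence="ACGA"),
        SequenceRecord(individual="I3", subset="Y", sequence="ACGT"),
    ])
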