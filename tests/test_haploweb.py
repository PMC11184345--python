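import pytest
import yaml

from hapnet.haplo import collapse_haplotypes
from hapnet.haploweb import (
    cooccurrence_graph,
    fields_for_recombination,
    read_report,
    sharing_statistics,
    stats_to_dict,
    write_report,
)
from hapnet.seqio import Alignment, SequenceRecord
from hapnet.spart import Spartition

from conftest import make_alignment
from oracles import ffr_components_unionfind


def diploids(pairs, subsets=None):
    """Alignment from {individual: (seqA, seqB)}."""
    records = []
    for i, (ind, (a, b)) in enumerate(pairs.items()):
        subset = subsets.get(ind) if subsets else None
        records.append(SequenceRecord(individual=ind, allele="a",
                                      subset=subset, sequence=a))
        records.append(SequenceRecord(individual=ind, allele="b",
                                      subset=subset, sequence=b))
    return Alignment(records)


def test_cooccurrence_pairs():
    aln = diploids({
        "I1": ("AAAA", "AAAT"),   # het: H1-H2
        "I2": ("AAAA", "AAAA"),   # homozygote: no pair
        "I3": ("AAAA", "AAAT"),   # second connector for H1-H2
    })
    cooc = cooccurrence_graph(collapse_haplotypes(aln))
    assert len(cooc.pairs) == 1
    h1, h2, inds = cooc.pairs[0]
    assert (h1, h2) == ("H1", "H2")
    assert inds == ["I1", "I3"]


def test_cooccurrence_haploid_is_empty():
    cat = collapse_haplotypes(make_alignment(["AAAA", "AAAT"]))
    with pytest.warns(UserWarning, match="haploid"):
        cooc = cooccurrence_graph(cat)
    assert cooc.pairs == []


def test_ffr_worked_example():
    aln = diploids({
        "I1": ("AAAA", "AAAT"),  # h1/h2
        "I2": ("AAAT", "AATT"),  # h2/h3
        "I3": ("TTTT", "TTTT"),  # h4/h4
    })
    cat = collapse_haplotypes(aln)
    ffrs = fields_for_recombination(cat)
    assert len(ffrs) == 2
    assert ffrs[0].haplotypes == {"H1", "H2", "H3"}
    assert ffrs[0].individuals == {"I1", "I2"}
    assert ffrs[1].haplotypes == {"H4"}
    assert ffrs[1].individuals == {"I3"}


def test_all_homozygous_distinct_one_ffr_each():
    aln = diploids({f"I{i}": (s, s) for i, s in
                    enumerate(["AAAA", "AATT", "TTTT"], 1)})
    ffrs = fields_for_recombination(collapse_haplotypes(aln))
    assert len(ffrs) == 3
    assert all(len(f.individuals) == 1 for f in ffrs)


def test_shared_homozygotes_join_one_ffr():
    """Two homozygotes for the same haplotype share a gene pool."""
    aln = diploids({"I1": ("AAAA", "AAAA"), "I2": ("AAAA", "AAAA")})
    ffrs = fields_for_recombination(collapse_haplotypes(aln))
    assert len(ffrs) == 1
    assert ffrs[0].individuals == {"I1", "I2"}


@pytest.mark.parametrize("seed", range(30))
def test_ffr_matches_unionfind_oracle(seed):
    import numpy as np

    rng = np.random.default_rng(seed)
    seqs = ["AAAA", "AAAT", "AATT", "ATTT", "TTTT"]
    pairs = {}
    for i in range(int(rng.integers(2, 10))):
        a, b = rng.choice(len(seqs), size=2)
        pairs[f"I{i}"] = (seqs[a], seqs[b])
    cat = collapse_haplotypes(diploids(pairs))
    ffrs = fields_for_recombination(cat)
    got = {(frozenset(f.haplotypes), frozenset(f.individuals)) for f in ffrs}
    assert got == ffr_components_unionfind(cat)
    # partition property: no overlap, full coverage
    all_h = [h for f in ffrs for h in f.haplotypes]
    all_i = [i for f in ffrs for i in f.individuals]
    assert len(all_h) == len(set(all_h)) == len(cat)
    assert len(all_i) == len(set(all_i)) == len(cat.individuals)
    # mutual allelic exclusivity
    for f in ffrs:
        for g in ffrs:
            if f.id != g.id:
                assert not (f.haplotypes & g.haplotypes)


def test_sharing_statistics_worked_example():
    aln = diploids(
        {"I1": ("AAAA", "AAAA"), "I2": ("AAAA", "AAAT"), "I3": ("AAAT", "AAAT")},
        subsets={"I1": "X", "I2": "X", "I3": "Y"},
    )
    cat = collapse_haplotypes(aln)
    ffrs = fields_for_recombination(cat)
    part = Spartition(name="p", assignment={"I1": "X", "I2": "X", "I3": "Y"})
    stats = sharing_statistics(cat, ffrs, part)
    assert stats.shared[("X", "Y")] == ["H2"]
    assert len(ffrs) == 1
    assert stats.concordance == {"X": False, "Y": False}


def test_disjoint_subsets_are_concordant():
    aln = diploids(
        {"I1": ("AAAA", "AAAA"), "I2": ("TTTT", "TTTT")},
        subsets={"I1": "X", "I2": "Y"},
    )
    cat = collapse_haplotypes(aln)
    ffrs = fields_for_recombination(cat)
    stats = sharing_statistics(cat, ffrs)
    assert stats.shared[("X", "Y")] == []
    assert len(ffrs) == 2
    assert stats.concordance == {"X": True, "Y": True}


def test_hs_symmetry():
    aln = diploids(
        {"I1": ("AAAA", "AAAT"), "I2": ("AAAA", "AATT")},
        subsets={"I1": "X", "I2": "Y"},
    )
    cat = collapse_haplotypes(aln)
    ffrs = fields_for_recombination(cat)
    stats = sharing_statistics(cat, ffrs)
    # stored once per unordered pair: symmetric by construction
    assert ("X", "Y") in stats.shared and ("Y", "X") not in stats.shared


def test_concordance_implies_at_least_as_many_ffrs():
    aln = diploids(
        {"I1": ("AAAA", "AAAA"), "I2": ("TTTT", "TTTT"), "I3": ("AATT", "AATT")},
        subsets={"I1": "X", "I2": "Y", "I3": "Z"},
    )
    cat = collapse_haplotypes(aln)
    ffrs = fields_for_recombination(cat)
    stats = sharing_statistics(cat, ffrs)
    if all(stats.concordance.values()):
        assert len(ffrs) >= len(stats.subsets)


def test_report_roundtrip(tmp_path):
    aln = diploids(
        {"I1": ("AAAA", "AAAA"), "I2": ("AAAA", "AAAT"), "I3": ("AAAT", "AAAT")},
        subsets={"I1": "X", "I2": "X", "I3": "Y"},
    )
    cat = collapse_haplotypes(aln)
    ffrs = fields_for_recombination(cat)
    stats = sharing_statistics(cat, ffrs)
    path = tmp_path / "report.yaml"
    write_report(stats, ffrs, cat, path)
    doc = read_report(path)
    assert doc == stats_to_dict(stats, ffrs, cat)
    assert list(doc) == ["partition", "subsets", "haplotypes",
                         "shared_haplotypes", "ffrs", "concordance"]
    assert doc["shared_haplotypes"][0]["haplotype"] == "H2"
    assert doc["ffrs"][0]["id"] == "F1"


def test_report_empty_catalog(tmp_path):
    cat = collapse_haplotypes(Alignment([]))
    ffrs = fields_for_recombination(cat)
    stats = sharing_statistics(cat, ffrs)
    path = tmp_path / "empty.yaml"
    write_report(stats, ffrs, cat, path)
    doc = yaml.safe_load(path.read_text())
    assert doc["haplotypes"] == [] and doc["ffrs"] == []
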