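import itertools

import numpy as np
import pytest

from hapnet.errors import DegenerateInputError, MissingSequenceError
from hapnet.haplo import collapse_haplotypes, pairwise_distances
from hapnet.networks import (
    build_guide_tree,
    fitch_genealogy,
    median_joining_network,
    minimum_spanning_network,
    parsimony_probability,
    tcs_connection_limit,
    tcs_network,
    _fitch_score_graph,
    _phylo_to_graph,
)

from conftest import make_alignment, random_binary_tree, random_catalog
from oracles import (
    all_minimum_spanning_trees,
    connection_limit_exact,
    exhaustive_parsimony_score,
)


def _distances_of(dm):
    return {
        frozenset((dm.ids[i], dm.ids[j])): int(dm.d[i, j])
        for i in range(len(dm.ids))
        for j in range(i + 1, len(dm.ids))
        if dm.d[i, j] > 0
    }


# ---------------------------------------------------------------------- MSN


def test_msn_triangle_keeps_all_cominimal_edges():
    cat = collapse_haplotypes(make_alignment(["AAT", "ATA", "TAA"]))
    g = minimum_spanning_network(pairwise_distances(cat), cat)
    assert g.graph.number_of_edges() == 3


def test_msn_star_instance():
    # h0 at distance 1 from each leaf; leaves pairwise distance 2
    seqs = ["AAAAA", "TAAAA", "ATAAA", "AATAA", "AAATA"]
    cat = collapse_haplotypes(make_alignment(seqs))
    dm = pairwise_distances(cat)
    g = minimum_spanning_network(dm, cat)
    edges = {frozenset(e) for e in g.graph.edges}
    assert edges == {frozenset(("H1", f"H{i}")) for i in range(2, 6)}
    # unique MST confirmed by enumeration
    weight, trees = all_minimum_spanning_trees(dm.ids, _distances_of(dm))
    assert weight == 4 and len(trees) == 1


@pytest.mark.parametrize("seed", range(20))
def test_msn_matches_mst_oracle(seed):
    """MSN(0) spans at brute-force MST weight and contains every MST edge."""
    import networkx as nx

    cat = random_catalog(seed)
    dm = pairwise_distances(cat)
    g = minimum_spanning_network(dm, cat)
    dist = _distances_of(dm)
    weight, trees = all_minimum_spanning_trees(dm.ids, dist)
    mst_of_msn = nx.minimum_spanning_tree(g.graph, weight="steps")
    assert sum(d["steps"] for _, _, d in mst_of_msn.edges(data=True)) == weight
    union_of_msts = set().union(*trees)
    msn_edges = {frozenset(e) for e in g.graph.edges}
    assert union_of_msts == msn_edges


def test_msn_epsilon_relaxation_adds_edges():
    cat = collapse_haplotypes(make_alignment(["AAAA", "TAAA", "TTAA"]))
    dm = pairwise_distances(cat)
    assert minimum_spanning_network(dm, cat, 0).graph.number_of_edges() == 2
    relaxed = minimum_spanning_network(dm, cat, 1)
    assert relaxed.graph.number_of_edges() == 3


# ---------------------------------------------------------------------- MJN


def test_mjn_triplet_median():
    cat = collapse_haplotypes(make_alignment(["TAA", "ATA", "AAT"]))
    dm = pairwise_distances(cat)
    g = median_joining_network(cat, dm)
    inferred = [n for n in g.nodes if not g.graph.nodes[n]["sampled"]]
    assert len(inferred) == 1
    assert g.total_length == 3
    weight, _ = all_minimum_spanning_trees(dm.ids, _distances_of(dm))
    assert weight == 4  # the median saves one step over the MST


def test_mjn_star_needs_no_medians():
    seqs = ["AAAAA", "TAAAA", "ATAAA", "AATAA", "AAATA"]
    cat = collapse_haplotypes(make_alignment(seqs))
    dm = pairwise_distances(cat)
    mjn = median_joining_network(cat, dm)
    msn = minimum_spanning_network(dm, cat)
    assert mjn.equivalent(msn)


@pytest.mark.parametrize("seed", range(25))
def test_mjn_never_longer_than_msn(seed):
    cat = random_catalog(seed)
    dm = pairwise_distances(cat)
    msn = minimum_spanning_network(dm, cat)
    mjn = median_joining_network(cat, dm)
    assert mjn.total_length <= msn.total_length
    assert set(mjn.sampled_nodes) == {h.id for h in cat}
    for hap in cat:
        assert mjn.graph.nodes[hap.id]["count"] == hap.count


# ---------------------------------------------------------------------- TCS


def test_connection_limit_at_threshold_one_is_zero():
    assert tcs_connection_limit(600, threshold=1.0) == 0


def test_parsimony_probability_below_one():
    for j in (1, 2, 5):
        assert parsimony_probability(j, 600) < 1.0


def test_connection_limit_monotone_in_length():
    limits = [tcs_connection_limit(L, 0.95) for L in range(100, 1001, 100)]
    assert limits == sorted(limits)


def test_connection_limit_monotone_in_threshold():
    limits = [tcs_connection_limit(600, t) for t in (0.5, 0.9, 0.95, 0.99, 1.0)]
    assert limits == sorted(limits, reverse=True)


def test_connection_limit_matches_exact_oracle():
    """Float implementation agrees with the straight-line Fraction oracle."""
    assert tcs_connection_limit(600, 0.95) == connection_limit_exact(600, 0.95)
    for j in range(1, 8):
        from oracles import parsimony_probability_exact

        exact = float(parsimony_probability_exact(j, 600))
        assert parsimony_probability(j, 600) == pytest.approx(exact, rel=1e-9)


def test_tcs_inserts_unit_step_intermediates():
    a = "A" * 100
    b = "TTT" + "A" * 97
    cat = collapse_haplotypes(make_alignment([a, b]))
    dm = pairwise_distances(cat)
    g = tcs_network(cat, dm, threshold=0.95)
    limit = tcs_connection_limit(100, 0.95)
    assert limit >= 3
    inferred = [n for n in g.nodes if not g.graph.nodes[n]["sampled"]]
    assert len(inferred) == 2
    assert g.graph.number_of_edges() == 3
    assert all(d["steps"] == 1 for _, _, d in g.graph.edges(data=True))


def test_tcs_splits_beyond_limit():
    length = 40
    limit = tcs_connection_limit(length, 0.95)
    a = "A" * length
    b = "T" * (limit + 1) + "A" * (length - limit - 1)
    cat = collapse_haplotypes(make_alignment([a, b]))
    g = tcs_network(cat, pairwise_distances(cat))
    assert len(g.components()) == 2
    assert g.graph.number_of_edges() == 0


def test_tcs_chain_agglomeration():
    # d(h1,h2)=d(h2,h3)=2, d(h1,h3)=4: no direct h1-h3 connection
    cat = collapse_haplotypes(make_alignment(["AAAAAA", "TTAAAA", "TTTTAA"]))
    g = tcs_network(cat, pairwise_distances(cat), threshold=0.5)
    inferred = [n for n in g.nodes if not g.graph.nodes[n]["sampled"]]
    assert len(inferred) == 2
    assert len(g.components()) == 1
    assert g.graph.number_of_edges() == 4
    assert not g.graph.has_edge("H1", "H3")


# --------------------------------------------------------------- guide trees


def test_nj_recovers_additive_split():
    # d(A,B)=2, d(C,D)=2, cross distances 6: split {A,B}|{C,D}
    seqs = {
        "A": "AAAAAAAA",
        "B": "TTAAAAAA",
        "C": "AAATTTTC",
        "D": "AATTTTTA",
    }
    cat = collapse_haplotypes(make_alignment(list(seqs.values())))
    tree = build_guide_tree(cat, "nj")
    tips = {t.name for t in tree.get_terminals()}
    assert tips == {"H1", "H2", "H3", "H4"}
    # H1/H2 (the A/B pair) must be sisters on one side of the root
    for clade in tree.get_nonterminals():
        names = {t.name for t in clade.get_terminals()}
        if names == {"H1", "H2"}:
            break
    else:
        pytest.fail("NJ did not recover the {A,B}|{C,D} split")


def test_three_taxa_unique_topology():
    cat = collapse_haplotypes(make_alignment(["AAAA", "ATAA", "TTTA"]))
    tree = build_guide_tree(cat, "nj")
    assert len(tree.get_terminals()) == 3


def test_guide_tree_needs_three_haplotypes():
    cat = collapse_haplotypes(make_alignment(["AAAA", "ATAA"]))
    with pytest.raises(DegenerateInputError):
        build_guide_tree(cat, "nj")


def test_mp_refinement_never_worse_than_nj():
    from hapnet.networks import _site_states

    for seed in (0, 1, 2):
        cat = random_catalog(seed, max_haplotypes=6, length=30, min_haplotypes=4)
        dm = pairwise_distances(cat)
        used = dm.used_columns
        states = {
            h.id: _site_states("".join(h.sequence[c] for c in used))
            for h in cat
        }
        nj = build_guide_tree(cat, "nj")
        mp = build_guide_tree(cat, "mp")
        nj_score = _fitch_score_graph(_phylo_to_graph(nj), states)
        mp_score = _fitch_score_graph(_phylo_to_graph(mp), states)
        assert mp_score <= nj_score


# ------------------------------------------------------------ Fitch genealogy


def test_fitch_three_tip_example():
    aln = make_alignment(["AAA", "AAA", "AAT"], individuals=["s1", "s2", "s3"])
    cat = collapse_haplotypes(aln)
    rng = np.random.default_rng(0)
    from Bio.Phylo.BaseTree import Clade, Tree

    tree = Tree.from_clade(
        Clade(clades=[
            Clade(clades=[Clade(name="s1"), Clade(name="s2")]),
            Clade(name="s3"),
        ])
    )
    g = fitch_genealogy(tree, aln, cat)
    counts = sorted(d["count"] for _, d in g.graph.nodes(data=True))
    assert counts == [1, 2]
    assert [d["steps"] for _, _, d in g.graph.edges(data=True)] == [1]


def test_fitch_missing_tip_sequence():
    aln = make_alignment(["AAA", "AAT"], individuals=["s1", "s2"])
    cat = collapse_haplotypes(aln)
    from Bio.Phylo.BaseTree import Clade, Tree

    tree = Tree.from_clade(Clade(clades=[Clade(name="s1"), Clade(name="sX")]))
    with pytest.raises(MissingSequenceError, match="sX"):
        fitch_genealogy(tree, aln, cat)


def test_fitch_homoplasy_splits_haplotype():
    aln = make_alignment(
        ["AAT", "AAA", "AAT", "AAA"], individuals=["t1", "t2", "t3", "t4"]
    )
    cat = collapse_haplotypes(aln)
    from Bio.Phylo.BaseTree import Clade, Tree

    tree = Tree.from_clade(Clade(clades=[
        Clade(clades=[Clade(name="t1"), Clade(name="t2")]),
        Clade(clades=[Clade(name="t3"), Clade(name="t4")]),
    ]))
    g = fitch_genealogy(tree, aln, cat)
    assert g.total_length == 2
    aat_nodes = [
        n for n, d in g.graph.nodes(data=True)
        if d["sequence"] == "AAT" or (d["sampled"] and "H1" in n)
    ]
    assert len(aat_nodes) == 2
    assert exhaustive_parsimony_score(
        tree, {t: s for t, s in zip(["t1", "t2", "t3", "t4"],
                                    ["AAT", "AAA", "AAT", "AAA"])}
    ) == 2


@pytest.mark.parametrize("seed", range(15))
def test_fitch_score_matches_exhaustive_oracle(seed):
    """Edge-step sum equals the brute-force minimum over all assignments."""
    rng = np.random.default_rng(seed)
    n_tips = int(rng.integers(3, 7))
    length = 8
    seqs = {}
    for i in range(n_tips):
        seqs[f"t{i}"] = "".join(rng.choice(list("ACGT"), size=length))
    aln = make_alignment(list(seqs.values()), individuals=list(seqs))
    cat = collapse_haplotypes(aln)
    tree = random_binary_tree(rng, list(seqs))
    g = fitch_genealogy(tree, aln, cat)
    assert g.total_length == exhaustive_parsimony_score(tree, seqs)
    total = sum(d["count"] for _, d in g.graph.nodes(data=True))
    assert total == n_tips


def test_fitch_counts_follow_catalog_for_haplotype_tips():
    cat = collapse_haplotypes(make_alignment(
        ["AAAA", "AAAA", "ATAA", "TTTA"],
        individuals=["i1", "i2", "i3", "i4"],
    ))
    tree = build_guide_tree(cat, "nj")
    g = fitch_genealogy(tree, make_alignment([], individuals=[]), cat)
    counts = {n: d["count"] for n, d in g.graph.nodes(data=True) if d["sampled"]}
    assert counts["H1"] == 2
    assert sum(counts.values()) == cat.total_count
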