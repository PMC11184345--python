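"""Haplotype network and genealogy reconstruction.

Four constructors over a haplotype catalog and its distance matrix:

* minimum spanning network (MSN) — the union of all minimum spanning
  trees, optionally relaxed by an integer epsilon;
* median-joining network (MJN) — MSN augmented with inferred median
  (quasi-median) vertices chosen by minimal connection cost;
* statistical parsimony (TCS) — agglomerative connection of haplotypes
  up to a probabilistically justified step limit, splitting the data
  into subnetworks beyond it;
* Fitch genealogy — parsimony ancestral states on a rooted tree with
  mutation-free branches contracted.

The statistical-parsimony connection limit is computed from an explicit
Bayesian finite-sites model documented in the methods note: a coalescent
(geometric) prior on the true number of mutations separating a pair of
sequences, Jukes–Cantor 4-state site dynamics on a locus of L sites, and
the posterior probability that the observed number of differences equals
the true number of mutations ("probability of parsimony").
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree
from Bio.Phylo.TreeConstruction import DistanceMatrix as _BioDM
from Bio.Phylo.TreeConstruction import DistanceTreeConstructor

from .errors import (
    ComplexityError,
    DegenerateInputError,
    MissingSequenceError,
)
from .haplo import DistanceMatrix, HaplotypeCatalog, used_columns_for


# ---------------------------------------------------------------------------
# graph container


@dataclass
class HaploGraph:
    """Nodes are sampled haplotypes plus inferred vertices; edges carry steps."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_node(
        self,
        node_id: str,
        sequence: Optional[str] = None,
        sampled: bool = False,
        count: int = 0,
        per_subset: Optional[dict[str, int]] = None,
    ) -> None:
        self.graph.add_node(
            node_id,
            sequence=sequence,
            sampled=sampled,
            count=count,
            per_subset=dict(per_subset or {}),
        )

    def add_edge(self, n1: str, n2: str, steps: int) -> None:
        if n1 == n2:
            raise ValueError("self-loops are not allowed")
        if steps < 1:
            raise ValueError("edge steps must be >= 1")
        self.graph.add_edge(n1, n2, steps=int(steps))

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def sampled_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["sampled"]]

    @property
    def total_length(self) -> int:
        return sum(d["steps"] for _, _, d in self.graph.edges(data=True))

    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def equivalent(self, other: "HaploGraph") -> bool:
        """Structural equality: same nodes, attributes, edges and steps."""
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        for n in self.graph.nodes:
            a, b = self.graph.nodes[n], other.graph.nodes[n]
            if (
                a["sequence"] != b["sequence"]
                or a["sampled"] != b["sampled"]
                or a["count"] != b["count"]
                or a["per_subset"] != b["per_subset"]
            ):
                return False
        edges_a = {frozenset(e): d["steps"] for *e, d in self.graph.edges(data=True)}
        edges_b = {frozenset(e): d["steps"] for *e, d in other.graph.edges(data=True)}
        return edges_a == edges_b


def _catalog_nodes(g: HaploGraph, catalog: HaplotypeCatalog) -> None:
    for hap in catalog:
        g.add_node(
            hap.id,
            sequence=hap.sequence,
            sampled=True,
            count=hap.count,
            per_subset=hap.per_subset_count,
        )


# ---------------------------------------------------------------------------
# minimum spanning network


def _msn_edges(
    ids: list[str], dist: dict[tuple[str, str], int], epsilon: int = 0
) -> list[tuple[str, str, int]]:
    """Edges of the minimum spanning network over arbitrary node ids.

    Distance levels are processed in increasing order; at each level the
    components are frozen as they stood before the level, and every edge
    within ``level + epsilon`` joining two distinct frozen components is
    admitted.  With epsilon 0 this yields exactly the union of all
    minimum spanning trees.
    """
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges_out: list[tuple[str, str, int]] = []
    pairs = sorted(
        ((w, a, b) for (a, b), w in dist.items() if w > 0),
        key=lambda t: (t[0], t[1], t[2]),
    )
    levels = sorted({w for w, _, _ in pairs})
    added = set()
    for level in levels:
        frozen = {i: find(i) for i in ids}
        if len(set(frozen.values())) == 1:
            break
        batch = []
        for w, a, b in pairs:
            if w > level + epsilon:
                break
            if frozen[a] != frozen[b] and frozenset((a, b)) not in added:
                batch.append((a, b, w))
                added.add(frozenset((a, b)))
        for a, b, w in batch:
            edges_out.append((a, b, w))
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    return edges_out


def minimum_spanning_network(
    dm: DistanceMatrix, catalog: HaplotypeCatalog, epsilon: int = 0
) -> HaploGraph:
    """Union-of-MSTs network over the sampled haplotypes."""
    g = HaploGraph()
    _catalog_nodes(g, catalog)
    dist = {}
    for i, a in enumerate(dm.ids):
        for j in range(i + 1, len(dm.ids)):
            dist[(a, dm.ids[j])] = int(dm.d[i, j])
    for a, b, w in _msn_edges(dm.ids, dist, epsilon):
        g.add_edge(a, b, w)
    return g


# ---------------------------------------------------------------------------
# median-joining network


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _quasi_medians(u: str, v: str, w: str, cap: int) -> list[str]:
    """Per-site majority consensus; all-different sites expand to all three."""
    options = []
    n_expand = 1
    for x, y, z in zip(u, v, w):
        if x == y or x == z:
            options.append((x,))
        elif y == z:
            options.append((y,))
        else:
            options.append(tuple(sorted({x, y, z})))
            n_expand *= 3
            if n_expand > cap:
                raise ComplexityError(
                    f"quasi-median expansion exceeds the cap of {cap} candidates"
                )
    return ["".join(chars) for chars in itertools.product(*options)]


def median_joining_network(
    catalog: HaplotypeCatalog,
    dm: DistanceMatrix,
    epsilon: int = 0,
    median_cap: int = 10_000,
) -> HaploGraph:
    """Median-joining network with quasi-median vertices.

    Iterates: build the MSN over the current node set; for every
    connected triple (two incident MSN edges) generate quasi-medians;
    add the novel medians of minimal connection cost (within epsilon);
    stop when no new median appears.  Finally, inferred nodes of degree
    at most two are pruned iteratively and the MSN is rebuilt.
    """
    used = dm.used_columns
    seqs: dict[str, str] = {}  # node id -> restricted sequence
    for hap in catalog:
        seqs[hap.id] = "".join(hap.sequence[c] for c in used)
    median_count = 0

    def msn_of(current: dict[str, str]):
        ids = list(current)
        dist = {
            (a, b): _hamming(current[a], current[b])
            for a, b in itertools.combinations(ids, 2)
        }
        return _msn_edges(ids, dist, epsilon), dist

    def total_of(current) -> int:
        edges, _ = msn_of(current)
        return sum(w for _, _, w in edges)

    while True:
        edges, dist = msn_of(seqs)
        adjacency: dict[str, set[str]] = {i: set() for i in seqs}
        for a, b, _ in edges:
            adjacency[a].add(b)
            adjacency[b].add(a)
        existing = set(seqs.values())
        candidates: dict[str, int] = {}
        for center in sorted(adjacency):
            for u, w in itertools.combinations(sorted(adjacency[center]), 2):
                for m in _quasi_medians(seqs[u], seqs[center], seqs[w], median_cap):
                    if m in existing:
                        continue
                    cost = (
                        _hamming(seqs[u], m)
                        + _hamming(seqs[center], m)
                        + _hamming(seqs[w], m)
                    )
                    if m not in candidates or cost < candidates[m]:
                        candidates[m] = cost
        if not candidates:
            break
        best = min(candidates.values())
        novel = sorted(m for m, c in candidates.items() if c <= best + epsilon)
        if median_count + len(novel) > median_cap:
            raise ComplexityError(
                f"median-joining generated more than {median_cap} median "
                "vertices; try epsilon=0 or reduce the input"
            )
        # admit a median only when it strictly shortens the network, so the
        # final length never exceeds the MSN's and the loop must terminate
        current_total = total_of(seqs)
        accepted = 0
        for m in novel:
            trial = dict(seqs)
            trial[f"m{median_count + 1}"] = m
            trial_total = total_of(trial)
            if trial_total < current_total:
                median_count += 1
                seqs = trial
                current_total = trial_total
                accepted += 1
        if not accepted:
            break

    # prune inferred nodes of degree <= 2, rebuilding the MSN each round
    sampled_ids = {hap.id for hap in catalog}
    while True:
        edges, _ = msn_of(seqs)
        degree = {i: 0 for i in seqs}
        for a, b, _ in edges:
            degree[a] += 1
            degree[b] += 1
        prunable = [i for i in seqs if i not in sampled_ids and degree[i] <= 2]
        if not prunable:
            break
        for i in prunable:
            del seqs[i]

    # drop obsolete medians: keep one only if removing it lengthens the network
    def total_len(current):
        edges, _ = msn_of(current)
        return sum(w for _, _, w in edges)

    changed = True
    while changed:
        changed = False
        for node in sorted(i for i in seqs if i not in sampled_ids):
            without = {k: v for k, v in seqs.items() if k != node}
            if total_len(without) <= total_len(seqs):
                del seqs[node]
                changed = True

    g = HaploGraph()
    _catalog_nodes(g, catalog)
    for node_id, seq in seqs.items():
        if node_id not in sampled_ids:
            g.add_node(node_id, sequence=None, sampled=False, count=0)
    edges, _ = msn_of(seqs)
    for a, b, w in edges:
        g.add_edge(a, b, w)
    return g


# ---------------------------------------------------------------------------
# statistical parsimony (TCS)


def parsimony_probability(
    j: int, alignment_length: int, k_extra: int = 160
) -> float:
    """Posterior probability that j observed differences arose from exactly
    j mutations.

    Prior on the true mutation count k: geometric from the pairwise
    coalescent, P(k) proportional to (theta/(1+theta))**k with theta
    estimated by the observed difference count j.  Likelihood of seeing j
    differences after k mutations: Markov chain on the number of
    differing sites, each mutation hitting one of L sites uniformly, a
    hit on an already-differing site reverting it with probability 1/3
    (Jukes–Cantor).  The sum over k is truncated at j + k_extra, far past
    any non-negligible mass at the scales involved.
    """
    if j < 1:
        return 1.0
    m = alignment_length
    if j > m:
        return 0.0
    theta = float(j)
    kmax = j + k_extra
    # A[jj] after k mutations = P(jj sites differ)
    A = [0.0] * (kmax + 2)
    A[0] = 1.0
    ratio = theta / (1.0 + theta)
    numerator = 0.0
    denominator = 0.0
    prior = 1.0 / (1.0 + theta)
    for k in range(kmax + 1):
        if k >= j:
            if k == j:
                numerator = prior * A[j]
            denominator += prior * A[j]
        # advance the chain by one mutation
        nxt = [0.0] * (kmax + 2)
        for jj in range(min(k, m) + 1):
            p = A[jj]
            if p == 0.0:
                continue
            if jj < m:
                nxt[jj + 1] += p * (m - jj) / m
            if jj > 0:
                nxt[jj - 1] += p * (jj / m) / 3.0
                nxt[jj] += p * (jj / m) * (2.0 / 3.0)
        A = nxt
        prior *= ratio
    return numerator / denominator


def tcs_connection_limit(
    alignment_length: int,
    threshold: float = 0.95,
    max_steps: int = 64,
) -> int:
    """Largest number of steps whose probability of parsimony stays at or
    above the threshold; 0 when even a single step falls below it."""
    if alignment_length < 1:
        raise ValueError("alignment_length must be >= 1")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    limit = 0
    for j in range(1, max_steps + 1):
        if parsimony_probability(j, alignment_length) >= threshold:
            limit = j
        else:
            break
    return limit


def _mutation_path(seq_a: str, seq_b: str) -> list[str]:
    """Intermediate sequences from a to b, changing sites in column order."""
    diff_cols = [i for i, (x, y) in enumerate(zip(seq_a, seq_b)) if x != y]
    out = []
    current = list(seq_a)
    for col in diff_cols[:-1]:
        current[col] = seq_b[col]
        out.append("".join(current))
    return out


def tcs_network(
    catalog: HaplotypeCatalog,
    dm: DistanceMatrix,
    threshold: float = 0.95,
) -> HaploGraph:
    """Statistical-parsimony network with unit-step intermediate nodes.

    Pairs are connected agglomeratively in increasing distance order
    (ties by haplotype id) while the distance is within the connection
    limit and the pair spans two components; a connection at distance d
    inserts d-1 inferred intermediates so that every edge is one step.
    """
    limit = tcs_connection_limit(len(dm.used_columns), threshold)
    g = HaploGraph()
    _catalog_nodes(g, catalog)
    used = dm.used_columns
    restricted = {
        hap.id: "".join(hap.sequence[c] for c in used) for hap in catalog
    }
    pairs = sorted(
        (
            (int(dm.d[i, j]), dm.ids[i], dm.ids[j])
            for i in range(len(dm.ids))
            for j in range(i + 1, len(dm.ids))
            if 0 < dm.d[i, j] <= limit
        ),
        key=lambda t: (t[0], t[1], t[2]),
    )
    parent = {i: i for i in dm.ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n_inferred = 0
    for d, a, b in pairs:
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        chain = [a]
        for _seq in _mutation_path(restricted[a], restricted[b]):
            n_inferred += 1
            node_id = f"i{n_inferred}"
            g.add_node(node_id, sequence=None, sampled=False, count=0)
            chain.append(node_id)
        chain.append(b)
        for n1, n2 in zip(chain, chain[1:]):
            g.add_edge(n1, n2, 1)
        parent[ra] = rb
    return g


# ---------------------------------------------------------------------------
# guide trees (NJ, parsimony NNI refinement)


def _phylo_to_graph(tree: Tree) -> nx.Graph:
    g = nx.Graph()
    counter = itertools.count(1)

    def walk(clade) -> str:
        if not clade.clades:
            return clade.name
        name = f"__int{next(counter)}"
        for child in clade.clades:
            g.add_edge(name, walk(child))
        return name

    root_name = walk(tree.root)
    # suppress a degree-2 root: splice its two neighbours together
    if g.degree(root_name) == 2:
        n1, n2 = list(g.neighbors(root_name))
        g.remove_node(root_name)
        g.add_edge(n1, n2)
    return g


def _graph_to_phylo(g: nx.Graph, tips: list[str]) -> Tree:
    """Root the unrooted graph on the edge leading to the first tip."""
    first = sorted(tips)[0]
    anchor = next(iter(g.neighbors(first)))

    def build(node, came_from) -> Clade:
        children = [n for n in g.neighbors(node) if n != came_from]
        if not children:
            return Clade(name=node)
        clade = Clade(name=None if str(node).startswith("__int") else str(node))
        # an internal node that is also a labelled taxon keeps its name
        for child in sorted(children, key=str):
            clade.clades.append(build(child, node))
        return clade

    root = Clade()
    root.clades.append(Clade(name=first))
    root.clades.append(build(anchor, first))
    tree = Tree(root=root, rooted=True)
    return tree


def _fitch_score_graph(g: nx.Graph, tip_states: dict[str, list[str]]) -> int:
    """Parsimony score of an unrooted tree given per-site tip states."""
    tips = sorted(tip_states)
    root = tips[0]
    n_sites = len(tip_states[root])
    order = list(nx.dfs_postorder_nodes(g, source=root))
    parent_of = dict(nx.dfs_predecessors(g, source=root))
    score = 0
    for site in range(n_sites):
        sets: dict[str, frozenset] = {}
        for node in order:
            children = [c for c, p in parent_of.items() if p == node]
            if not children:
                sets[node] = frozenset(tip_states[node][site])
            else:
                child_sets = [sets[c] for c in children]
                if node in tip_states:
                    child_sets.append(frozenset(tip_states[node][site]))
                counts: dict[str, int] = {}
                for s in child_sets:
                    for state in s:
                        counts[state] = counts.get(state, 0) + 1
                k = max(counts.values())
                sets[node] = frozenset(s for s, c in counts.items() if c == k)
                score += len(child_sets) - k
        del sets
    return score


def _site_states(sequence: str) -> list[str]:
    from .seqio import IUPAC_TO_BASES

    return [
        IUPAC_TO_BASES.get(c, "ACGT") if c != "-" else "ACGT" for c in sequence
    ]


def build_guide_tree(catalog: HaplotypeCatalog, method: str = "nj") -> Tree:
    """Neighbor-joining tree, optionally refined by parsimony NNI search.

    ``nj``: canonical neighbor joining on the haplotype distance matrix,
    midpoint-rooted.  ``mp``: the NJ topology is hill-climbed with
    nearest-neighbour interchanges on the Fitch parsimony score until no
    move improves it (ties and iteration order are lexicographic, so the
    search is deterministic).
    """
    from .haplo import pairwise_distances

    if len(catalog) < 3:
        raise DegenerateInputError(
            f"guide tree needs at least 3 haplotypes, got {len(catalog)}"
        )
    dm = pairwise_distances(catalog)
    names = list(dm.ids)
    matrix = [[float(dm.d[i, j]) for j in range(i + 1)] for i in range(len(names))]
    nj_tree = DistanceTreeConstructor().nj(_BioDM(names, matrix))
    for clade in nj_tree.get_nonterminals():
        clade.name = None  # drop biopython's Inner labels
    if method == "nj":
        try:
            nj_tree.root_at_midpoint()
        except Exception:
            pass  # negative NJ branches can defeat midpoint rooting
        nj_tree.rooted = True
        return nj_tree
    if method != "mp":
        raise ValueError(f"unknown guide-tree method {method!r}")

    used = dm.used_columns
    tip_states = {
        hap.id: _site_states("".join(hap.sequence[c] for c in used))
        for hap in catalog
    }
    g = _phylo_to_graph(nj_tree)
    best = _fitch_score_graph(g, tip_states)
    improved = True
    while improved:
        improved = False
        internal_edges = sorted(
            (str(u), str(v))
            for u, v in g.edges
            if g.degree(u) >= 3 and g.degree(v) >= 3
        )
        for u, v in internal_edges:
            if not g.has_edge(u, v):
                continue
            au = sorted(set(g.neighbors(u)) - {v}, key=str)
            av = sorted(set(g.neighbors(v)) - {u}, key=str)
            if len(au) < 2 or len(av) < 2:
                continue
            for x, y in ((au[1], av[0]), (au[1], av[1])):
                g.remove_edge(u, x)
                g.remove_edge(v, y)
                g.add_edge(u, y)
                g.add_edge(v, x)
                score = _fitch_score_graph(g, tip_states)
                if score < best:
                    best = score
                    improved = True
                    break
                # revert
                g.remove_edge(u, y)
                g.remove_edge(v, x)
                g.add_edge(u, x)
                g.add_edge(v, y)
            if improved:
                break
    return _graph_to_phylo(g, names)


# ---------------------------------------------------------------------------
# Fitch genealogy


def _ensure_rooted(tree: Tree) -> Tree:
    """Midpoint-root a tree whose root is a polytomy, when lengths allow."""
    if len(tree.root.clades) <= 2:
        return tree
    lengths = [cl.branch_length for cl in tree.find_clades() if cl.branch_length]
    if lengths:
        try:
            tree.root_at_midpoint()
            return tree
        except Exception:
            pass
    # no usable lengths: root on the first tip's edge
    first = tree.get_terminals()[0]
    tree.root_with_outgroup(first)
    return tree


def fitch_genealogy(
    tree: Tree,
    alignment,
    catalog: HaplotypeCatalog,
) -> HaploGraph:
    """Haplotype genealogy: parsimony states on the tree, zero branches
    contracted, counts aggregated onto the surviving nodes.

    Tree tips may be record labels (``Ind1_a``) or haplotype ids; each tip
    must resolve to a sequence.  The sum of steps over the genealogy's
    edges equals the tree's parsimony score, and a haplotype can appear in
    more than one node when homoplasy forces independent origins.
    """
    tree = _ensure_rooted(tree)
    # resolve tips
    rec_by_label = {rec.label: rec for rec in alignment}
    hap_by_id = {hap.id: hap for hap in catalog}
    hap_by_seq = {hap.sequence: hap for hap in catalog}
    used = used_columns_for([hap.sequence for hap in catalog])

    tip_info: dict[str, tuple[str, int, dict[str, int]]] = {}
    for term in tree.get_terminals():
        label = term.name
        if label in rec_by_label:
            rec = rec_by_label[label]
            hap = hap_by_seq.get(rec.sequence)
            hap_id = hap.id if hap else label
            subset = catalog.subset_of.get(rec.individual, "unassigned")
            tip_info[label] = (hap_id, 1, {subset: 1})
            seq = rec.sequence
        elif label in hap_by_id:
            hap = hap_by_id[label]
            tip_info[label] = (hap.id, hap.count, dict(hap.per_subset_count))
            seq = hap.sequence
        else:
            raise MissingSequenceError(f"tree tip {label!r} has no sequence")
        tip_info[label] += (tuple("".join(seq[c] for c in used)),)

    # index clades
    clades = list(tree.find_clades(order="level"))
    children = {id(c): list(c.clades) for c in clades}
    postorder = list(tree.find_clades(order="postorder"))

    n_sites = len(used)
    # Hartigan bottom-up / top-down, one site at a time
    state: dict[int, list[str]] = {id(c): [""] * n_sites for c in clades}
    score = 0
    for site in range(n_sites):
        vu: dict[int, frozenset] = {}
        for clade in postorder:
            if not clade.clades:
                ch = tip_info[clade.name][3][site]
                vu[id(clade)] = (
                    frozenset(ch) if ch in "ACGT" else frozenset("ACGT")
                )
            else:
                counts: dict[str, int] = {}
                for child in clade.clades:
                    for s in vu[id(child)]:
                        counts[s] = counts.get(s, 0) + 1
                k = max(counts.values())
                vu[id(clade)] = frozenset(s for s, c in counts.items() if c == k)
                score += len(clade.clades) - k
        # top-down assignment, preferring the parent's state
        root = tree.root
        state[id(root)][site] = min(vu[id(root)])
        for clade in clades:
            ps = state[id(clade)][site]
            for child in clade.clades:
                cs = vu[id(child)]
                state[id(child)][site] = ps if ps in cs else min(cs)

    # branch steps, then contract zero-step branches with union-find
    parent_uf: dict[int, int] = {id(c): id(c) for c in clades}

    def find(x):
        while parent_uf[x] != x:
            parent_uf[x] = parent_uf[parent_uf[x]]
            x = parent_uf[x]
        return x

    branches = []  # (parent clade, child clade, steps)
    for clade in clades:
        for child in clade.clades:
            steps = sum(
                1
                for site in range(n_sites)
                if state[id(clade)][site] != state[id(child)][site]
            )
            branches.append((clade, child, steps))
            if steps == 0:
                parent_uf[find(id(clade))] = find(id(child))

    groups: dict[int, list] = {}
    for clade in clades:
        groups.setdefault(find(id(clade)), []).append(clade)

    # name and attribute the genealogy nodes
    node_of_group: dict[int, str] = {}
    g = HaploGraph()
    name_counts: dict[str, int] = {}
    n_anon = 0
    hap_order = {hap.id: i for i, hap in enumerate(catalog)}
    for root_id in sorted(groups, key=lambda r: min(
        clades.index(c) for c in groups[r]
    )):
        members = groups[root_id]
        tips = [c for c in members if not c.clades]
        if tips:
            hap_ids = sorted(
                {tip_info[t.name][0] for t in tips},
                key=lambda h: hap_order.get(h, len(hap_order)),
            )
            base = "+".join(hap_ids)
            count = sum(tip_info[t.name][1] for t in tips)
            per_subset: dict[str, int] = {}
            for t in tips:
                for s, c in tip_info[t.name][2].items():
                    per_subset[s] = per_subset.get(s, 0) + c
            seqs = {
                hap_by_id[h].sequence for h in hap_ids if h in hap_by_id
            }
            sequence = seqs.pop() if len(seqs) == 1 else None
            sampled = True
        else:
            n_anon += 1
            base, count, per_subset, sequence, sampled = f"n{n_anon}", 0, {}, None, False
        name_counts[base] = name_counts.get(base, 0) + 1
        node_id = base if name_counts[base] == 1 else f"{base}.{name_counts[base]}"
        node_of_group[root_id] = node_id
        g.add_node(node_id, sequence=sequence, sampled=sampled, count=count,
                   per_subset=per_subset)

    for parent, child, steps in branches:
        if steps == 0:
            continue
        n1 = node_of_group[find(id(parent))]
        n2 = node_of_group[find(id(child))]
        if n1 == n2:
            continue
        g.add_edge(n1, n2, steps)
    assert g.total_length == score, "edge steps must sum to the parsimony score"
    return g
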