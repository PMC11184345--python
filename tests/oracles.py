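"""Independent brute-force oracles used to validate the algorithms.

Each oracle takes a deliberately different computational route from the
implementation it checks: exhaustive enumeration for spanning trees and
ancestral assignments, exact rational arithmetic for the parsimony
probability, a plain union-find for FFR components.
"""

from __future__ import annotations

import itertools
from fractions import Fraction


# -- spanning trees ---------------------------------------------------------

def all_minimum_spanning_trees(ids, dist):
    """All MSTs by exhaustive enumeration (feasible for <= ~7 nodes).

    ``dist`` maps frozenset({a, b}) -> positive weight.  Returns
    (min_weight, list of edge-sets), each edge-set a set of frozensets.
    """
    edges = sorted(dist, key=sorted)
    n = len(ids)
    best_weight = None
    best_trees = []
    for combo in itertools.combinations(edges, n - 1):
        # connectivity check by repeated merging
        comps = {i: {i} for i in ids}
        ok = True
        for e in combo:
            a, b = tuple(e)
            if comps[a] is comps[b]:
                ok = False
                break
            merged = comps[a] | comps[b]
            for node in merged:
                comps[node] = merged
        if not ok or len(comps[ids[0]]) != n:
            continue
        weight = sum(dist[e] for e in combo)
        if best_weight is None or weight < best_weight:
            best_weight = weight
            best_trees = [set(combo)]
        elif weight == best_weight:
            best_trees.append(set(combo))
    return best_weight, best_trees


# -- exhaustive parsimony ---------------------------------------------------

def exhaustive_parsimony_score(tree, tip_sequences):
    """Minimum mutation count over all internal-state assignments.

    ``tree`` is a Bio.Phylo tree; ``tip_sequences`` maps tip name ->
    sequence (equal lengths, alphabet ACGT).  Sites are independent, so
    the minimum is summed per site.
    """
    internals = tree.get_nonterminals()
    terminals = tree.get_terminals()
    length = len(next(iter(tip_sequences.values())))
    branches = []
    for clade in internals:
        for child in clade.clades:
            branches.append((clade, child))
    total = 0
    for site in range(length):
        tip_state = {id(t): tip_sequences[t.name][site] for t in terminals}
        best = None
        for assign in itertools.product("ACGT", repeat=len(internals)):
            state = {id(c): s for c, s in zip(internals, assign)}
            state.update(tip_state)
            changes = sum(
                1 for p, c in branches if state[id(p)] != state[id(c)]
            )
            if best is None or changes < best:
                best = changes
        total += best
    return total


# -- parsimony probability (exact rational arithmetic) ----------------------

def parsimony_probability_exact(j, length, k_extra=160):
    """Straight-line exact-fraction version of the probability of parsimony.

    Same model as the implementation (geometric coalescent prior with
    theta = j, Jukes-Cantor finite-sites likelihood), evaluated with
    Fractions and plain loops.
    """
    if j < 1:
        return Fraction(1)
    m = length
    theta = Fraction(j)
    ratio = theta / (1 + theta)
    kmax = j + k_extra
    chain = {0: Fraction(1)}
    prior = 1 / (1 + theta)
    numerator = Fraction(0)
    denominator = Fraction(0)
    for k in range(kmax + 1):
        if k >= j:
            a_j = chain.get(j, Fraction(0))
            if k == j:
                numerator = prior * a_j
            denominator += prior * a_j
        nxt = {}
        for jj, p in chain.items():
            if jj < m:
                nxt[jj + 1] = nxt.get(jj + 1, Fraction(0)) + p * Fraction(m - jj, m)
            if jj > 0:
                nxt[jj - 1] = nxt.get(jj - 1, Fraction(0)) + p * Fraction(jj, 3 * m)
                nxt[jj] = nxt.get(jj, Fraction(0)) + p * Fraction(2 * jj, 3 * m)
        chain = nxt
        prior = prior * ratio
    return numerator / denominator


def connection_limit_exact(length, threshold, max_steps=64):
    limit = 0
    thr = Fraction(threshold).limit_denominator(10**6)
    for j in range(1, max_steps + 1):
        if parsimony_probability_exact(j, length) >= thr:
            limit = j
        else:
            break
    return limit


# -- union-find over the individual/haplotype bipartite graph ---------------

def ffr_components_unionfind(catalog):
    """FFR partition via union-find, independent of the graph library."""
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for hap in catalog:
        find(("hap", hap.id))
        for ind, _allele in hap.members:
            union(("hap", hap.id), ("ind", ind))
    groups = {}
    for node in parent:
        groups.setdefault(find(node), set()).add(node)
    out = []
    for members in groups.values():
        haps = frozenset(n[1] for n in members if n[0] == "hap")
        inds = frozenset(n[1] for n in members if n[0] == "ind")
        out.append((haps, inds))
    return set(out)
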