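# Methods

This note records the models implemented in `hapnet`, the parameters
that matter, the deliberate design choices where the design was open,
and what the synthetic data do and do not establish.

## Input model and identifiers

Sequences must be pre-aligned; the package performs no alignment.  The
residue alphabet is A, C, G, T, N, `-` plus the eleven IUPAC ambiguity
letters; `U` is mapped to `T` on input.  Alignment columns are 0-based
internally and 1-based in every user-facing message.

A label is parsed as `individual[_a|_b][|subset]`.  Allele detection is
strictly the terminal lowercase `_a`/`_b`, so `Sample_3` or `x_A`
remain individual names.  The subset (candidate species) label is taken
after the first `|`, or else after the first whitespace run of a FASTA
description; this pipe convention follows the MolD-style headers common
in taxonomy pipelines and is a package convention, not a universal
standard.  Tab-delimited tables carry the same information in columns
`individual / subset / allele / sequence`.

## Phasing: EM over haplotype frequencies

Bayesian samplers in the PHASE tradition infer phase from approximate
coalescent priors by MCMC.  `hapnet` deliberately uses a simpler,
fully deterministic estimator: maximum-likelihood haplotype frequencies
under Hardy–Weinberg random pairing, fitted by
expectation–maximisation, with maximum-posterior pair assignment.  The
contract is the same (diploid consensus in, two `_a`/`_b` haploids
out), the machinery is not, and no attempt is made to reproduce PHASE
posteriors.

* A genotype with h heterozygous sites (two-fold codes only) has
  exactly max(1, 2^(h−1)) consistent unordered pairs; they are
  enumerated exhaustively up to a cap (default h ≤ 16, adjustable via
  `--het-cap`).  At desk scale (hundreds of sequences, 500–1000 bp,
  few heterozygous sites each) this is instantaneous.
* Initial frequencies are uniform over every haplotype appearing in
  any consistent pair; ties in the final maximum-posterior assignment
  break lexicographically.  No randomness enters, so results are
  identical across runs regardless of seed.
* Convergence: relative log-likelihood improvement below `tol`
  (default 1e-8) or `max_iter` (default 1000); the log-likelihood is
  non-decreasing by the standard EM argument and the test-suite
  asserts it on every run.
* Codes expanding to three or four bases (including N) cannot arise
  from one diploid site; such columns are treated as missing, copied
  verbatim to both alleles, and flagged with a warning.
* A single heterozygous site is phase-invariant, so h ≤ 1 individuals
  are always phased exactly; with a single individual all pairs are
  equally likely and the lexicographic rule picks the canonical one.

## Haplotype collapsing and distances

Identical sequences merge into haplotypes labelled H1, H2, … by first
occurrence in input order (never by frequency, so ids are stable across
partition choices).  Counts are allele copies: two per diploid, one per
haploid record.

Distances are Hamming counts over a retained column set.  The default
`complete-deletion` mode drops every column containing `-` or an N-like
character in any haplotype, which gives all network algorithms a single
shared column set; `pairwise` drops per pair; `fifth-state` counts the
gap as a state (N-like columns are always excluded).  Two distinct
haplotypes can collide at distance 0 when they differ only at excluded
columns; such pairs are never joined by an edge and stay separate
nodes.

## Minimum spanning network

Distance values are processed in increasing order; at each level the
components are frozen as they stood before the level and every edge
within `level + ε` joining two frozen components is admitted.  At ε = 0
this is exactly the union of all minimum spanning trees (verified
against exhaustive spanning-tree enumeration in the tests); ε > 0
relaxes the network with near-minimal alternative connections.

## Median joining

Candidate medians are quasi-medians of connected triples (two incident
MSN edges): per-site majority where at least two sequences agree, with
all-different sites expanding combinatorially (capped at 10 000
candidates, a hard error beyond).  Candidates are ranked by connection
cost d(u,m)+d(v,m)+d(w,m), and a median is admitted only when adding it
strictly shortens the rebuilt network.  This admission rule makes the
iteration a strictly decreasing integer sequence — termination and the
invariant "MJN total length ≤ MSN total length" both follow — at the
price of not generating the full quasi-median closure that a maximal
median-joining variant would; inferred vertices of degree ≤ 2 and
medians whose removal does not lengthen the network are pruned
afterwards.  Sampled haplotypes are always retained.

## Statistical parsimony and the connection limit

The connection limit is the largest step count j whose *probability of
parsimony* stays at or above the threshold (default 0.95).  The
published statistical-parsimony framework defines this probability as
the chance that haplotypes j observed steps apart are connected by
exactly j mutations; `hapnet` computes it from an explicit Bayesian
finite-sites model chosen for transparency and testability:

* prior on the true number of mutations k separating a random pair:
  the pairwise-coalescent geometric, P(k) ∝ (θ/(1+θ))^k, with θ
  estimated by the observed difference count j;
* likelihood of observing j differences after k mutations: a Markov
  chain on the number of differing sites, each mutation hitting one of
  L sites uniformly and reverting an already-differing site with
  probability 1/3 (Jukes–Cantor states);
* probability of parsimony = posterior P(k = j | j observed), with the
  k-sum truncated at j + 160 (the tail is negligible at these scales).

The resulting limits (e.g. 7 steps at L = 600, threshold 0.95) are
more conservative than those of the legacy TCS program; the model
behind the legacy numbers is not reproduced here, and the documented
model above is the package's own.  The limit is monotone
non-decreasing in L and non-increasing in the threshold, and the
threshold-1.0 limit is 0 (no step count is ever certain).  An exact
rational-arithmetic reimplementation of the same computation lives in
the test-suite as an independent oracle.

Network construction is agglomerative: pairs in increasing distance
order (ties broken lexicographically by haplotype id), joined only when
within the limit and in different components; a connection at distance
d inserts d−1 inferred intermediates, placed by changing differing
sites in ascending column order (an arbitrary but deterministic
shortest mutational path), so every edge is one step.  Epsilon is not
applied to TCS.

## Guide trees and the Fitch genealogy

Neighbor joining uses the canonical algorithm on the haplotype distance
matrix (via Biopython) with midpoint rooting.  The `mp` option refines
the NJ topology by nearest-neighbour-interchange hill-climbing on the
parsimony score, with lexicographic edge/move order, until no move
improves; the final tree is rooted on the first tip's edge.

Ancestral states are computed per site with Hartigan's generalisation
of the Fitch algorithm, which is exact on polytomies as well as binary
trees.  The top-down pass prefers the parent's state whenever it is in
the child's optimal set (ties otherwise break alphabetically), which
attains the minimum total change count; the test-suite confirms the
edge-step sum equals the brute-force minimum over all internal
assignments on small trees.  Branches with zero inferred changes are
contracted; surviving nodes aggregate the counts and subset counts of
the allele copies they contain.  Under homoplasy one haplotype can
appear in several genealogy nodes (independent origins); tips, and
therefore counts, are never duplicated.  Unrooted user trees are
midpoint-rooted when branch lengths allow, otherwise rooted on the
first tip's edge.

## Haplowebs, FFRs, and the report

Co-occurrence pairs connect the two distinct haplotypes of each
heterozygote; pairs supported by a single individual are drawn dotted.
FFRs are connected components of the bipartite individual–haplotype
membership graph — both heterozygous co-occurrence *and* haplotype
sharing between individuals flow through it, so two homozygotes for the
same haplotype share an FFR.  By construction the FFRs partition the
individuals and the sampled haplotypes, and distinct FFRs share no
haplotype (mutual allelic exclusivity).

Against a spartition, the report lists haplotypes shared by each subset
pair (HS), FFR composition, and per-subset concordance (all of the
subset's individuals in one FFR containing no other subset).
Individuals present in the sequences but absent from the SPART file are
placed in subset `unassigned` with a warning.  The YAML report is a
plain YAML 1.1 subset (no anchors or tags) with fixed key order —
`partition, subsets, haplotypes, shared_haplotypes, ffrs, concordance`
— so reruns diff cleanly; the exact statistics schema is this
package's own.

## Layout and export

Layouts are per-component seeded Fruchterman–Reingold runs, components
then placed left to right with a fixed gap, so a given graph and seed
always give identical coordinates.  Node area (not radius) is
proportional to count with a 6-unit radius floor; inferred vertices are
fixed small discs.  Colours come from a fixed qualitative palette in
subset order, overridable by a `subset<TAB>#RRGGBB` file.  GraphML
carries every node/edge attribute and reads back into an equal graph;
SVG 1.1 is emitted directly (one circle per node, one path per edge,
tick marks or step labels, optional co-occurrence curves and one grey
hull per FFR), so element counts are pure functions of graph size and
options.  PNG/PDF rasterisation and interactive editing are out of
scope.

## Synthetic data

`fixtures.simulate_dataset` emulates a desk-scale single-locus study: K
distinct haplotypes derived from a random ancestor by substitutions
(default expected scale ≈ 5 pairwise differences), diploid individuals
drawing two haplotypes under Hardy–Weinberg from their subset's pool,
IUPAC consensus for the unphased view, and an optional engineered
heterozygote spanning two subsets' pools.  Defaults — L = 500 bp, K =
4 at frequencies (0.4, 0.3, 0.2, 0.1), n = 40 — mirror the scale the
package targets; the EM recovery checks use n = 200, where ±0.05
roughly equals three binomial standard errors on the rarest haplotype.
The simulator has no coalescent structure, no recombination, no indel
process (gap columns can be injected mechanically for distance-mode
tests), and no sequencing error; passing tests therefore demonstrate
algorithmic correctness on clean data, not robustness to real-world
noise or to model misspecification in the phasing step.

Oracle-driven checks run at small problem sizes by design — networks
of ≤ 6 haplotypes against exhaustive spanning-tree enumeration, trees
of ≤ 6 tips against exhaustive ancestral assignments — because the
oracles are exponential; the algorithms themselves run comfortably at
the package's target scale.

## Known limitations

* The phasing model ignores linkage to a coalescent genealogy; rare
  haplotypes supported only by ambiguous individuals can be assigned
  by the lexicographic tie-break rather than by evidence.
* The statistical-parsimony limits follow the documented model above
  and are intentionally conservative; they should not be quoted as
  TCS-program limits.
* The median-joining variant is the length-reducing one described
  above, not the full quasi-median closure.
* SPART support models names, assignments and order; optional fields
  (dates, scores) are preserved opaquely but not interpreted.
* Tight-span-walker reconstruction, NEXUS/Phylip input, amino-acid
  haplotypes, indel coding and multi-marker FFR intersection are out
  of scope.
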