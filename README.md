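# hapnet

Single-locus haplotype analysis for species delimitation and population
genetics: phasing of diploid consensus sequences, collapsing to unique
haplotypes, haplotype network and genealogy reconstruction, haploweb /
fields-for-recombination (FFR) computation against SPART species
partitions, and deterministic GraphML/SVG export — as an importable
library plus a thin `hapnet` command line.

## The problem

At a single nuclear locus, a diploid individual carries two alleles.
Direct (Sanger-style) sequencing yields one consensus per individual in
which heterozygous positions appear as two-fold IUPAC ambiguity codes
(R, Y, S, W, K, M).  Relationships among alleles are commonly shown as a
**haplotype network**: nodes are unique allele sequences sized by
frequency, edges are weighted by mutational steps, and inferred
(unsampled) vertices may be added.  For species delimitation, the
network can be extended into a **haploweb** by connecting haplotypes
that co-occur within heterozygous individuals; the connected groups of
individuals and haplotypes — mutually exclusive in their allele content
against all other groups — are **fields for recombination** (FFRs), a
visual proxy for gene pools.  Haplotype sharing (HS) between subsets of
a species partition, and whether each subset forms its own FFR, are the
quantities this package computes and reports.

## Methods at a glance

* **Phasing** — an expectation–maximisation estimator of population
  haplotype frequencies under Hardy–Weinberg random pairing.  With
  genotype *g* and consistent ordered pair (h₁, h₂), the E-step weights
  each pair by p(h₁)·p(h₂)·(2 − 𝟙[h₁=h₂]), the M-step re-estimates
  frequencies from the expected pair counts, and each individual
  receives its maximum-posterior pair, written `ind_a` / `ind_b`.
* **Minimum spanning network (MSN)** — the union of all minimum
  spanning trees of the haplotype distance matrix (components frozen
  per distance level), optionally relaxed by an integer ε.
* **Median joining (MJN)** — quasi-medians (per-site majority of
  connected triples) are admitted as inferred vertices when they
  shorten the network; obsolete medians are pruned.
* **Statistical parsimony (TCS)** — haplotypes are connected
  agglomeratively up to a *connection limit*: the largest step count j
  whose probability of parsimony P(j | L) stays at or above the chosen
  threshold (default 0.95).  P is the posterior probability that j
  observed differences arose from exactly j mutations, under a
  geometric (pairwise-coalescent) prior on the mutation count and
  Jukes–Cantor finite-sites dynamics on L sites (see
  `docs/methods.md`).  Pairs beyond the limit stay in separate
  subnetworks; a connection at distance d inserts d−1 single-step
  intermediate vertices.
* **Fitch genealogy** — parsimony ancestral states (Hartigan's
  generalisation, so polytomies are exact) on a user tree or a
  neighbor-joining / NNI-refined maximum-parsimony guide tree;
  mutation-free branches are contracted and node sizes aggregate the
  allele copies they contain.

## Worked example

```python
from hapnet import Alignment, SequenceRecord, phase_alignment

records = (
    [SequenceRecord(individual=f"hom{i}", sequence="AATTC") for i in range(5)]
    + [SequenceRecord(individual=f"hom{i+5}", sequence="AGTTC") for i in range(4)]
    + [SequenceRecord(individual="het1", sequence="ARTTC")]  # R = A/G
)
phased = phase_alignment(Alignment(records))
```

Running `python examples/01_phase_diploids.py` prints:

```
het1_a AATTC
het1_b AGTTC
estimated haplotype frequencies:
  AATTC  0.550
  AGTTC  0.450
EM iterations: 3, converged: True
```

The heterozygote resolves to the two haplotypes already common in the
population, and the frequencies are the EM estimates of each
haplotype's share of the 2n = 20 allele copies.  Continuing with the
network step (`python examples/02_build_networks.py`, a simulated
4-haplotype population at a 200 bp locus):

```
haplotypes: [('H1', 28), ('H2', 10), ('H3', 8), ('H4', 14)]
connection limit at 95% for L=200: 4
MSN: 4 nodes, total length 9, edges [('H1', 'H3', 4), ('H1', 'H4', 3), ('H2', 'H4', 2)]
TCS: 10 nodes, total length 9, edges [('H1', 'i2', 1), ...]
```

`H1`–`H4` are unique haplotypes with their allele-copy counts; the TCS
network replaces the 4-step and 3-step MSN edges with chains of
single-step inferred intermediates (`i1`…`i6`), all within the 4-step
connection limit.  `examples/03_haploweb_ffr.py` and
`examples/04_spart_and_render.py` walk through haploweb/FFR statistics
and SPART + export.

From the shell, the same pipeline is one command:

```
hapnet --seed 42 haploweb --input data.fasta --spart parts.spart \
       --partition split --report report.yaml --out-graph net.graphml
```

Unphased input is detected (any two-fold ambiguity code) and phased
automatically; haploid data skip phasing.  Exit codes: 0 success, 1
usage error, 2 data error.

## Layout

```
src/hapnet/      seqio, spart, phasing, haplo, networks, haploweb,
                 render, fixtures, cli
examples/        one narrative script per capability
tests/           pytest suite incl. independent oracles
docs/methods.md  models, parameter choices, limitations
```
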