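"""Haplowebs, fields for recombination, and haplotype-sharing statistics.

A haploweb augments a haplotype network with connections between
haplotypes that co-occur within heterozygous individuals.  Following the
idea of mutual allelic exclusivity, the individuals and haplotypes split
into *fields for recombination* (FFRs): connected components of the
bipartite individual–haplotype membership graph.  Two homozygotes for
the same haplotype share a gene pool just as a heterozygote links its two
haplotypes, so both kinds of co-membership flow through the same graph.

Against a species partition, the module reports which haplotypes are
shared between subsets (HS), how FFRs are composed, and whether each
subset is concordant — all its individuals in one FFR that contains no
other subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import yaml

from .haplo import HaplotypeCatalog, UNASSIGNED
from .spart import Spartition


@dataclass
class CoOccurrence:
    """Haplotype pairs linked by heterozygous individuals."""

    pairs: list[tuple[str, str, list[str]]] = field(default_factory=list)

    def connectors(self, h1: str, h2: str) -> list[str]:
        key = frozenset((h1, h2))
        for a, b, inds in self.pairs:
            if frozenset((a, b)) == key:
                return inds
        return []


@dataclass
class FFR:
    id: str
    haplotypes: set[str]
    individuals: set[str]
    subsets: set[str]


@dataclass
class SharingStats:
    partition_name: str
    subsets: list[str]
    shared: dict[tuple[str, str], list[str]]  # subset pair -> haplotype ids
    concordance: dict[str, bool]


def cooccurrence_graph(catalog: HaplotypeCatalog) -> CoOccurrence:
    """Pairs of distinct haplotypes carried by the same heterozygote."""
    diploid = any(allele == "b" for h in catalog for _, allele in h.members)
    if not diploid:
        warnings.warn(
            "catalog holds no b alleles (haploid data); no co-occurrence",
            stacklevel=2,
        )
        return CoOccurrence()
    by_individual: dict[str, dict[str, str]] = {}
    for hap in catalog:
        for ind, allele in hap.members:
            if allele in ("a", "b"):
                by_individual.setdefault(ind, {})[allele] = hap.id
    links: dict[frozenset, list[str]] = {}
    order: list[frozenset] = []
    for ind in catalog.individuals:
        alleles = by_individual.get(ind, {})
        if set(alleles) != {"a", "b"}:
            continue
        ha, hb = alleles["a"], alleles["b"]
        if ha == hb:
            continue
        key = frozenset((ha, hb))
        if key not in links:
            links[key] = []
            order.append(key)
        links[key].append(ind)
    pairs = []
    for key in order:
        h1, h2 = sorted(key)
        pairs.append((h1, h2, links[key]))
    return CoOccurrence(pairs)


def fields_for_recombination(
    catalog: HaplotypeCatalog, cooc: Optional[CoOccurrence] = None
) -> list[FFR]:
    """Connected components of the bipartite individual–haplotype graph.

    The co-occurrence pairs are implied by shared individuals, so the
    components are independent of whether ``cooc`` is supplied; it is
    accepted for interface completeness.
    """
    del cooc
    g = nx.Graph()
    for hap in catalog:
        g.add_node(("hap", hap.id))
        for ind, _allele in hap.members:
            g.add_edge(("hap", hap.id), ("ind", ind))
    hap_order = {hap.id: i for i, hap in enumerate(catalog)}
    components = []
    for comp in nx.connected_components(g):
        haps = {n[1] for n in comp if n[0] == "hap"}
        inds = {n[1] for n in comp if n[0] == "ind"}
        components.append((haps, inds))
    components.sort(key=lambda c: min(hap_order[h] for h in c[0]))
    ffrs = []
    for i, (haps, inds) in enumerate(components, start=1):
        subsets = {catalog.subset_of.get(ind, UNASSIGNED) for ind in inds}
        ffrs.append(FFR(id=f"F{i}", haplotypes=haps, individuals=inds,
                        subsets=subsets))
    return ffrs


def sharing_statistics(
    catalog: HaplotypeCatalog,
    ffrs: list[FFR],
    partition: Optional[Spartition] = None,
) -> SharingStats:
    """Haplotype sharing between subsets and per-subset FFR concordance."""
    if partition is not None:
        subset_of = {
            ind: partition.assignment.get(ind, UNASSIGNED)
            for ind in catalog.individuals
        }
        unmatched = [i for i, s in subset_of.items() if s == UNASSIGNED
                     and i not in partition.assignment]
        if unmatched:
            warnings.warn(
                f"{len(unmatched)} individual(s) absent from the spartition "
                f"were placed in subset '{UNASSIGNED}'",
                stacklevel=2,
            )
        name = partition.name
    else:
        subset_of = dict(catalog.subset_of)
        name = "record-labels"
    subsets: list[str] = []
    for ind in catalog.individuals:
        s = subset_of.get(ind, UNASSIGNED)
        if s not in subsets:
            subsets.append(s)

    # per-subset haplotype counts under *this* partition
    counts: dict[str, dict[str, int]] = {h.id: {} for h in catalog}
    for hap in catalog:
        for ind, _allele in hap.members:
            s = subset_of.get(ind, UNASSIGNED)
            counts[hap.id][s] = counts[hap.id].get(s, 0) + 1

    shared: dict[tuple[str, str], list[str]] = {}
    for i, x in enumerate(subsets):
        for y in subsets[i + 1:]:
            hs = [h.id for h in catalog
                  if counts[h.id].get(x, 0) > 0 and counts[h.id].get(y, 0) > 0]
            shared[(x, y)] = hs

    ffr_of: dict[str, str] = {}
    for ffr in ffrs:
        for ind in ffr.individuals:
            ffr_of[ind] = ffr.id
    concordance: dict[str, bool] = {}
    for s in subsets:
        members = [ind for ind in catalog.individuals
                   if subset_of.get(ind, UNASSIGNED) == s]
        homes = {ffr_of[ind] for ind in members if ind in ffr_of}
        if len(homes) != 1:
            concordance[s] = False
            continue
        home = next(iter(homes))
        ffr = next(f for f in ffrs if f.id == home)
        others = {subset_of.get(ind, UNASSIGNED) for ind in ffr.individuals} - {s}
        concordance[s] = not others and set(members) == ffr.individuals
    return SharingStats(name, subsets, shared, concordance)


def stats_to_dict(
    stats: SharingStats, ffrs: list[FFR], catalog: HaplotypeCatalog
) -> dict:
    """The report document, keys in fixed order (plain YAML, no tags)."""
    hap_order = {hap.id: i for i, hap in enumerate(catalog)}
    shared_entries = []
    for (x, y), haps in stats.shared.items():
        for h in haps:
            hap = catalog.by_id(h)
            shared_entries.append({
                "haplotype": h,
                "subsets": [x, y],
                "individuals": sorted({ind for ind, _ in hap.members}),
            })
    return {
        "partition": stats.partition_name,
        "subsets": list(stats.subsets),
        "haplotypes": [
            {
                "id": hap.id,
                "sequence": hap.sequence,
                "count": hap.count,
                "per_subset": dict(hap.per_subset_count),
            }
            for hap in catalog
        ],
        "shared_haplotypes": shared_entries,
        "ffrs": [
            {
                "id": ffr.id,
                "haplotypes": sorted(ffr.haplotypes, key=lambda h: hap_order[h]),
                "individuals": sorted(ffr.individuals),
                "subsets": sorted(ffr.subsets),
            }
            for ffr in ffrs
        ],
        "concordance": {s: bool(v) for s, v in stats.concordance.items()},
    }


def write_report(
    stats: SharingStats,
    ffrs: list[FFR],
    catalog: HaplotypeCatalog,
    path,
) -> None:
    """Emit the descriptive HS/FFR statistics as a YAML text file."""
    doc = stats_to_dict(stats, ffrs, catalog)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=False)


def read_report(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
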