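"""Reciprocal-best-hit orthology, family clustering and gene classification.

Orthologue calls follow the operational RBH definition: genes a in species
A and b in species B are orthologous counterparts when b is a's best
BLASTP hit in B, a is b's best hit in A, and both e-values are < 0.01.

Family clustering here is a deliberately simple single-linkage surrogate
(connected components of the sub-1e-7 hit graph), NOT a tree-aware method:
it exists so the downstream classifier and Venn counter have a family
table of the right shape, and it accepts externally produced family tables
in the same structure.

The classifier buckets every gene of every species into exactly one of
seven orthology categories (the familiar comparative-genomics barplot):
universal single-copy (1:1:1), universal any-copy (N:N:N), clade-specific,
species-specific duplications (SD), homology-only, unblast, and others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .io_formats import HitRecord

RBH_EVALUE_MAX = 0.01
FAMILY_EVALUE_MAX = 1e-7

CATEGORIES = (
    "single_copy_111", "universal_NNN", "clade_specific",
    "species_specific_dup", "homology", "unblast", "others",
)


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit orthologue pair between two species."""

    geneA: str
    geneB: str
    evalueAB: float
    evalueBA: float
    identity: float  # percent, from the A->B alignment

    def __post_init__(self) -> None:
        if self.evalueAB < 0 or self.evalueBA < 0:
            raise ValueError("e-values must be >= 0")


@dataclass
class FamilyTable:
    """Gene families as per-species member lists.

    families: family id -> {species -> [gene, ...]}; every family has
    at least 2 members overall; a gene belongs to at most one family.
    """

    families: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    unassigned: list[str] = field(default_factory=list)

    def family_of(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for fid, members in self.families.items():
            for genes in members.values():
                for g in genes:
                    if g in out:
                        raise ValueError(f"gene {g!r} appears in multiple families")
                    out[g] = fid
        return out


def _hit_sort_key(h: HitRecord):
    # best hit: minimal e-value; ties by higher bitscore, higher identity,
    # then lexicographic subject id — a deterministic chain.
    return (h.evalue, -h.bitscore, -h.identity, h.subject)


def best_hits(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Best hit per query, after collapsing duplicate (query, subject) rows.

    When the same (query, subject) appears more than once, the last row
    wins and a warning is emitted.
    """
    rows: dict[tuple[str, str], HitRecord] = {}
    dup_seen = False
    for h in hits:
        key = (h.query, h.subject)
        if key in rows:
            dup_seen = True
        rows[key] = h
    if dup_seen:
        warnings.warn("duplicate (query, subject) hit rows: last occurrence kept")
    best: dict[str, HitRecord] = {}
    for h in rows.values():
        cur = best.get(h.query)
        if cur is None or _hit_sort_key(h) < _hit_sort_key(cur):
            best[h.query] = h
    return best


def reciprocal_best_hits(
    hitsAB: Iterable[HitRecord],
    hitsBA: Iterable[HitRecord],
    evalue_max: float = RBH_EVALUE_MAX,
) -> list[OrthologPair]:
    """Call orthologue pairs as reciprocal best hits with e-value < evalue_max.

    The e-value cutoff is strict (<), matching "e-values < 0.01". Output
    is sorted by geneA and forms a partial matching: each gene appears in
    at most one pair.
    """
    bestAB = best_hits(hitsAB)
    bestBA = best_hits(hitsBA)
    pairs: list[OrthologPair] = []
    for a, hab in sorted(bestAB.items()):
        b = hab.subject
        hba = bestBA.get(b)
        if hba is None or hba.subject != a:
            continue
        if hab.evalue < evalue_max and hba.evalue < evalue_max:
            pairs.append(OrthologPair(a, b, hab.evalue, hba.evalue, hab.identity))
    return pairs


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

def cluster_families(
    hits: Iterable[HitRecord],
    genes_by_species: Mapping[str, Sequence[str]],
    evalue_max: float = FAMILY_EVALUE_MAX,
) -> FamilyTable:
    """Single-linkage family surrogate: components of the sub-threshold hit graph.

    An undirected edge joins two genes when either direction of their hits
    has e-value < evalue_max; families are the connected components with
    at least 2 members. Genes in no family (including genes with no hits
    at all) are listed as unassigned. This is a stand-in for tree-aware
    family construction and inherits single-linkage chaining behaviour.
    """
    species_of = {g: sp for sp, genes in genes_by_species.items() for g in genes}
    graph = nx.Graph()
    graph.add_nodes_from(species_of)
    for h in hits:
        if h.evalue < evalue_max and h.query != h.subject:
            if h.query in species_of and h.subject in species_of:
                graph.add_edge(h.query, h.subject)
    table = FamilyTable()
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: c[0])
    n = 0
    for comp in components:
        if len(comp) < 2:
            table.unassigned.extend(comp)
            continue
        n += 1
        fid = f"F{n:06d}"
        members: dict[str, list[str]] = {}
        for g in comp:
            members.setdefault(species_of[g], []).append(g)
        table.families[fid] = members
    table.unassigned.sort()
    return table


# ---------------------------------------------------------------------------
# Category classification
# ---------------------------------------------------------------------------

def _cross_species_genes(
    hits: Iterable[HitRecord],
    species_of: Mapping[str, str],
    evalue_max: float,
) -> set[str]:
    """Genes with at least one cross-species hit below evalue_max (either direction)."""
    out: set[str] = set()
    for h in hits:
        spq, sps = species_of.get(h.query), species_of.get(h.subject)
        if spq is None or sps is None or spq == sps:
            continue
        if h.evalue < evalue_max:
            out.add(h.query)
            out.add(h.subject)
    return out


def classify_genes(
    families: FamilyTable,
    hits: Iterable[HitRecord],
    genes_by_species: Mapping[str, Sequence[str]],
    species_list: Optional[Sequence[str]] = None,
    clade_defs: Optional[Mapping[str, Sequence[str]]] = None,
    evalue_max: float = FAMILY_EVALUE_MAX,
) -> dict[str, str]:
    """Assign every gene exactly one orthology category.

    Categories, in priority order (first match wins):

    - single_copy_111: the gene's family has exactly one member in every
      species where it is present, and at most 1 of the considered
      species is absent.
    - universal_NNN: family present in all species with at most 1 absence
      tolerated, any copy number.
    - clade_specific:<name>: family confined to the named clade's species
      with at most 1 absence inside the clade (clades tried in the given
      order; requires the clade to have >= 2 species).
    - species_specific_dup: family whose members all come from one species
      (>= 2 members).
    - homology: gene not in any family but with a cross-species hit below
      evalue_max (either direction).
    - unblast: gene with no cross-species hit below evalue_max.
    - others: family members that fit none of the family categories.
    """
    if species_list is None:
        species_list = list(genes_by_species)
    clade_defs = clade_defs or {}
    species_set = set(species_list)
    species_of = {g: sp for sp, genes in genes_by_species.items() for g in genes}
    for fid, members in families.families.items():
        unknown = set(members) - species_set
        if unknown:
            raise ValueError(f"family {fid} contains species not in species_list: {unknown}")

    hits = list(hits)
    with_cross_hit = _cross_species_genes(hits, species_of, evalue_max)

    family_category: dict[str, str] = {}
    for fid, members in families.families.items():
        present = set(members)
        n_absent = len(species_set) - len(present)
        copy_counts = [len(genes) for genes in members.values()]
        if n_absent <= 1 and all(c == 1 for c in copy_counts):
            family_category[fid] = "single_copy_111"
            continue
        if n_absent <= 1:
            family_category[fid] = "universal_NNN"
            continue
        assigned = False
        for clade, clade_species in clade_defs.items():
            clade_set = set(clade_species)
            if len(clade_set) < 2:
                continue
            if present <= clade_set and len(clade_set - present) <= 1:
                family_category[fid] = f"clade_specific:{clade}"
                assigned = True
                break
        if assigned:
            continue
        if len(present) == 1:
            family_category[fid] = "species_specific_dup"
            continue
        family_category[fid] = "others"

    categories: dict[str, str] = {}
    family_of = families.family_of()
    for sp in species_list:
        for g in genes_by_species[sp]:
            fid = family_of.get(g)
            if fid is not None:
                categories[g] = family_category[fid]
            elif g in with_cross_hit:
                categories[g] = "homology"
            else:
                categories[g] = "unblast"
    return categories


def category_counts(
    categories: Mapping[str, str],
    genes_by_species: Mapping[str, Sequence[str]],
) -> dict[str, dict[str, int]]:
    """Per-species category tallies (the stacked-barplot numbers)."""
    out: dict[str, dict[str, int]] = {}
    for sp, genes in genes_by_species.items():
        counts: dict[str, int] = {}
        for g in genes:
            counts[categories[g]] = counts.get(categories[g], 0) + 1
        out[sp] = counts
    return out


# ---------------------------------------------------------------------------
# Venn counts and identity distributions
# ---------------------------------------------------------------------------

def family_venn(
    families: FamilyTable, species_subset: Sequence[str]
) -> dict[tuple[str, ...], int]:
    """Count families per Venn region over a subset of 2-4 species.

    Each family is assigned to the region given by the exact set of subset
    species it contains; families with no member in the subset are not
    counted. All 2^n - 1 regions are present in the output (zero counts
    included), keyed by the sorted species tuple.
    """
    if not 2 <= len(species_subset) <= 4:
        raise ValueError("species_subset must contain 2-4 species")
    if len(set(species_subset)) != len(species_subset):
        raise ValueError("species_subset contains duplicates")
    subset = sorted(species_subset)
    from itertools import combinations

    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(subset) + 1):
        for combo in combinations(subset, r):
            counts[combo] = 0
    for members in families.families.values():
        region = tuple(sorted(set(members) & set(subset)))
        if region:
            counts[region] += 1
    return counts


def identity_distribution(
    pairs: Sequence[OrthologPair], bin_width: float = 1.0
) -> dict:
    """Histogram and summary of orthologue percent identities.

    Bins tile [0, 100] with the given width; ``mass`` is the per-bin
    probability mass (sums to 1). Suitable for overlaying species pairs.
    """
    if not pairs:
        raise ValueError("empty orthologue pair list")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    idents = np.array([p.identity for p in pairs], dtype=float)
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    if edges[-1] < 100.0:
        edges = np.append(edges, 100.0)
    counts, edges = np.histogram(idents, bins=edges)
    return {
        "bin_edges": edges.tolist(),
        "counts": counts.tolist(),
        "mass": (counts / counts.sum()).tolist(),
        "mean": float(idents.mean()),
        "median": float(np.median(idents)),
        "n": len(pairs),
    }
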