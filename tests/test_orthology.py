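"""RBH, family clustering, category classification, Venn and identity tests.

The randomized checks compare against brute-force oracles written in a
deliberately naive style, independent of the library implementations.
"""

import warnings
from itertools import combinations

import numpy as np
import pytest

from ichneukit.io_formats import HitRecord
from ichneukit.orthology import (
    FamilyTable, OrthologPair, classify_genes, cluster_families,
    family_venn, identity_distribution, reciprocal_best_hits,
)


def _hit(q, s, ev, bits=100.0, ident=50.0, ln=100):
    return HitRecord(q, s, ident, ln, ev, bits)


class TestRBH:
    def test_mutual_best_pair_emitted(self):
        pairs = reciprocal_best_hits([_hit("a1", "b1", 1e-50)], [_hit("b1", "a1", 1e-50)])
        assert [(p.geneA, p.geneB) for p in pairs] == [("a1", "b1")]

    def test_evalue_threshold_is_strict(self):
        pairs = reciprocal_best_hits([_hit("a1", "b1", 0.02)], [_hit("b1", "a1", 0.02)])
        assert pairs == []
        # exactly at the cutoff is also excluded
        pairs = reciprocal_best_hits([_hit("a1", "b1", 0.01)], [_hit("b1", "a1", 0.01)])
        assert pairs == []

    def test_non_reciprocal_best_not_emitted(self):
        ab = [_hit("a1", "b1", 1e-50), _hit("a2", "b1", 1e-60)]
        ba = [_hit("b1", "a2", 1e-60)]
        pairs = reciprocal_best_hits(ab, ba)
        assert [(p.geneA, p.geneB) for p in pairs] == [("a2", "b1")]

    def test_tiebreak_chain(self):
        # equal e-value: higher bitscore wins; then identity; then subject id
        ab = [_hit("a", "b1", 1e-10, bits=90), _hit("a", "b2", 1e-10, bits=95)]
        ba = [_hit("b2", "a", 1e-10)]
        assert reciprocal_best_hits(ab, ba)[0].geneB == "b2"
        ab = [_hit("a", "b1", 1e-10, bits=90, ident=40),
              _hit("a", "b2", 1e-10, bits=90, ident=60)]
        ba = [_hit("b2", "a", 1e-10)]
        assert reciprocal_best_hits(ab, ba)[0].geneB == "b2"
        ab = [_hit("a", "b2", 1e-10), _hit("a", "b1", 1e-10)]
        ba = [_hit("b1", "a", 1e-10)]
        assert reciprocal_best_hits(ab, ba)[0].geneB == "b1"

    def test_duplicate_rows_warn_and_last_wins(self):
        ab = [_hit("a", "b1", 1e-5), _hit("a", "b1", 1e-50)]
        ba = [_hit("b1", "a", 1e-50)]
        with pytest.warns(UserWarning, match="duplicate"):
            pairs = reciprocal_best_hits(ab, ba)
        assert pairs[0].evalueAB == 1e-50

    def test_output_is_partial_matching(self):
        rng = np.random.default_rng(0)
        ab, ba = _random_tables(rng, 20, 20)
        pairs = reciprocal_best_hits(ab, ba)
        assert len({p.geneA for p in pairs}) == len(pairs)
        assert len({p.geneB for p in pairs}) == len(pairs)

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            ab, ba = _random_tables(rng, rng.integers(1, 15), rng.integers(1, 15))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = {(p.geneA, p.geneB) for p in reciprocal_best_hits(ab, ba)}
            assert got == _oracle_rbh(ab, ba)


def _random_tables(rng, na, nb, p_hit=0.3):
    genesA = [f"a{i}" for i in range(na)]
    genesB = [f"b{i}" for i in range(nb)]
    ab, ba = [], []
    for a in genesA:
        for b in genesB:
            if rng.random() < p_hit:
                ab.append(_hit(a, b, float(10.0 ** -rng.integers(0, 30)),
                               bits=float(rng.integers(50, 300)),
                               ident=float(rng.integers(20, 100))))
            if rng.random() < p_hit:
                ba.append(_hit(b, a, float(10.0 ** -rng.integers(0, 30)),
                               bits=float(rng.integers(50, 300)),
                               ident=float(rng.integers(20, 100))))
    return ab, ba


def _oracle_rbh(ab, ba, evalue_max=0.01):
    """Exhaustive reciprocal-minima enumeration (last duplicate row wins)."""
    def best(table, q):
        rows = {}
        for h in table:
            rows[(h.query, h.subject)] = h
        cands = [h for h in rows.values() if h.query == q]
        if not cands:
            return None
        return min(cands, key=lambda h: (h.evalue, -h.bitscore, -h.identity, h.subject))

    out = set()
    for h in ab:
        a = h.query
        ha = best(ab, a)
        if ha is None:
            continue
        hb = best(ba, ha.subject)
        if hb is not None and hb.subject == a:
            if ha.evalue < evalue_max and hb.evalue < evalue_max:
                out.add((a, ha.subject))
    return out


class TestFamilies:
    GENES = {"A": ["a1", "a2"], "B": ["b1", "b2"], "C": ["c1"]}

    def test_single_linkage_chain(self):
        hits = [_hit("a1", "b1", 1e-20), _hit("b1", "c1", 1e-20)]
        table = cluster_families(hits, self.GENES)
        (members,) = table.families.values()
        assert sorted(g for gs in members.values() for g in gs) == ["a1", "b1", "c1"]

    def test_isolated_gene_unassigned(self):
        hits = [_hit("a1", "b1", 1e-20)]
        table = cluster_families(hits, self.GENES)
        assert "a2" in table.unassigned and "c1" in table.unassigned

    def test_threshold_excludes_weak_edges(self):
        hits = [_hit("a1", "b1", 1e-5)]  # above 1e-7 cutoff
        table = cluster_families(hits, self.GENES)
        assert table.families == {}

    def test_spurious_bridge_merges_cliques(self):
        # documented single-linkage behaviour: one edge joins two cliques
        genes = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        hits = [_hit("a1", "a2", 1e-30), _hit("b1", "b2", 1e-30), _hit("a2", "b1", 1e-8)]
        table = cluster_families(hits, genes)
        assert len(table.families) == 1

    def test_components_match_bruteforce(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            genes = {sp: [f"{sp}{i}" for i in range(rng.integers(1, 8))]
                     for sp in "ABC"}
            allg = [g for gs in genes.values() for g in gs]
            hits = []
            for q, s in combinations(allg, 2):
                if rng.random() < 0.15:
                    hits.append(_hit(q, s, float(10.0 ** -rng.integers(0, 20))))
            table = cluster_families(hits, genes)
            got = {frozenset(g for gs in m.values() for g in gs)
                   for m in table.families.values()}
            assert got == _oracle_components(allg, hits)


def _oracle_components(genes, hits, evalue_max=1e-7):
    """Repeated-merge connected components, no graph library."""
    comps = [{g} for g in genes]
    edges = [(h.query, h.subject) for h in hits if h.evalue < evalue_max]
    changed = True
    while changed:
        changed = False
        for q, s in edges:
            ci = next(c for c in comps if q in c)
            cj = next(c for c in comps if s in c)
            if ci is not cj:
                comps.remove(cj)
                ci.update(cj)
                changed = True
    return {frozenset(c) for c in comps if len(c) >= 2}


def _family_table(assignments, genes_by_species):
    """assignments: list of gene sets."""
    species_of = {g: sp for sp, gs in genes_by_species.items() for g in gs}
    table = FamilyTable()
    for i, fam in enumerate(assignments):
        members = {}
        for g in sorted(fam):
            members.setdefault(species_of[g], []).append(g)
        table.families[f"F{i:06d}"] = members
    return table


class TestClassification:
    def test_universal_single_copy(self):
        species = [f"s{i}" for i in range(19)]
        genes = {sp: [f"{sp}_g"] for sp in species}
        table = _family_table([{f"{sp}_g" for sp in species}], genes)
        cats = classify_genes(table, [], genes, species)
        assert all(c == "single_copy_111" for c in cats.values())

    def test_one_absent_genome_tolerated(self):
        species = ["s0", "s1", "s2", "s3"]
        genes = {sp: ([f"{sp}_g"] if sp != "s3" else []) for sp in species}
        table = _family_table([{"s0_g", "s1_g", "s2_g"}], genes)
        cats = classify_genes(table, [], genes, species)
        assert cats["s0_g"] == "single_copy_111"

    def test_multi_copy_universal(self):
        species = ["s0", "s1", "s2"]
        genes = {"s0": ["x1", "x2"], "s1": ["y1"], "s2": ["z1"]}
        table = _family_table([{"x1", "x2", "y1", "z1"}], genes)
        cats = classify_genes(table, [], genes, species)
        assert cats["x1"] == "universal_NNN"

    def test_clade_specific(self):
        species = ["s0", "s1", "s2", "s3"]
        genes = {"s0": ["a"], "s1": ["b"], "s2": [], "s3": []}
        table = _family_table([{"a", "b"}], genes)
        cats = classify_genes(table, [], genes, species,
                              clade_defs={"waspclade": ["s0", "s1"]})
        assert cats["a"] == "clade_specific:waspclade"

    def test_species_specific_duplication(self):
        species = ["s0", "s1", "s2", "s3"]
        genes = {"s0": ["a1", "a2", "a3", "a4"], "s1": [], "s2": [], "s3": []}
        table = _family_table([{"a1", "a2", "a3", "a4"}], genes)
        cats = classify_genes(table, [], genes, species)
        assert all(c == "species_specific_dup" for c in cats.values())

    def test_homology_vs_unblast(self):
        species = ["s0", "s1"]
        genes = {"s0": ["a1", "a2"], "s1": ["b1"]}
        hits = [_hit("a1", "b1", 1e-9)]  # sub-threshold cross-species hit, no family
        cats = classify_genes(FamilyTable(), hits, genes, species)
        assert cats["a1"] == "homology"
        assert cats["a2"] == "unblast"

    def test_partition_covers_every_gene(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            genes = {sp: [f"{sp}{i}" for i in range(rng.integers(1, 10))]
                     for sp in "ABCD"}
            allg = [g for gs in genes.values() for g in gs]
            hits = [
                _hit(q, s, float(10.0 ** -rng.integers(0, 20)))
                for q, s in combinations(allg, 2) if rng.random() < 0.1
            ]
            table = cluster_families(hits, genes)
            cats = classify_genes(table, hits, genes, list("ABCD"),
                                  clade_defs={"AB": ["A", "B"]})
            assert set(cats) == set(allg)


class TestVenn:
    def test_simple_partition(self):
        genes = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        table = _family_table([{"a1", "b1"}, {"b2"}, {"a2"}], genes)
        counts = family_venn(table, ["A", "B"])
        assert counts[("A", "B")] == 1
        assert counts[("A",)] == 1
        assert counts[("B",)] == 1

    def test_family_outside_subset_not_counted(self):
        genes = {"A": ["a1"], "B": ["b1"], "C": ["c1", "c2"]}
        table = _family_table([{"c1", "c2"}], genes)
        counts = family_venn(table, ["A", "B"])
        assert sum(counts.values()) == 0

    def test_region_counts_sum_to_touching_families(self):
        rng = np.random.default_rng(4)
        species = list("WXYZ")
        genes = {sp: [f"{sp}{i}" for i in range(6)] for sp in species}
        fams = []
        for i in range(15):
            fam = {g for sp in species for g in
                   rng.choice(genes[sp], size=rng.integers(0, 3), replace=False)}
            if len(fam) >= 2:
                fams.append(fam)
        table = _family_table(fams, genes)
        counts = family_venn(table, species)
        touching = sum(
            1 for m in table.families.values() if set(m) & set(species)
        )
        assert sum(counts.values()) == touching

    def test_matches_bruteforce_region_assignment(self):
        rng = np.random.default_rng(5)
        species = list("WXYZ")
        genes = {sp: [f"{sp}{i}" for i in range(5)] for sp in species}
        species_of = {g: sp for sp, gs in genes.items() for g in gs}
        fams = []
        for _ in range(20):
            allg = [g for gs in genes.values() for g in gs]
            fam = set(rng.choice(allg, size=rng.integers(2, 6), replace=False))
            fams.append(fam)
        table = _family_table(fams, genes)
        counts = family_venn(table, species)
        oracle = {}
        for fam in fams:
            region = tuple(sorted({species_of[g] for g in fam}))
            oracle[region] = oracle.get(region, 0) + 1
        for region, n in oracle.items():
            assert counts[region] == n

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            family_venn(FamilyTable(), [])


class TestIdentityDistribution:
    def _pairs(self, idents):
        return [OrthologPair(f"a{i}", f"b{i}", 1e-20, 1e-20, x)
                for i, x in enumerate(idents)]

    def test_constant_identities(self):
        dist = identity_distribution(self._pairs([60.0] * 10), bin_width=1.0)
        assert dist["mean"] == 60.0
        assert max(dist["mass"]) == 1.0

    def test_normal_sample_mean_recovered(self):
        rng = np.random.default_rng(6)
        idents = np.clip(rng.normal(60, 8, size=500), 0, 100)
        dist = identity_distribution(self._pairs(idents.tolist()), bin_width=2.0)
        assert abs(dist["mean"] - 60) < 1.5

    def test_bin_layout_and_normalization(self):
        rng = np.random.default_rng(7)
        idents = rng.uniform(0, 100, size=200)
        dist = identity_distribution(self._pairs(idents.tolist()), bin_width=5.0)
        assert len(dist["counts"]) == 20
        assert sum(dist["mass"]) == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            identity_distribution([])
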