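"""Interactome construction, summaries, ranking, hub filtering, overlaps."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from helpers import brute_force_interactome
from crossddi.cancer_catalog import DUAL, OCG, TSG, CancerCatalog, CancerGene
from crossddi.core_io import DDIEntry, DDITable, DomainAnnotation, ProteinRecord, ValidationError
from crossddi.interactome import (
    build_interactome,
    cross_species_overlaps,
    filter_tsg_hubs,
    rank_domains_by_interactions,
    summarize_interactome,
    write_interactome,
)


def _annotations(protein_domains):
    return [DomainAnnotation(p, acc) for p, accs in protein_domains.items() for acc in accs]


def _catalog(gene_domains, roles=None):
    roles = roles or {}
    return CancerCatalog(
        [CancerGene(g, roles.get(g, TSG), frozenset(accs)) for g, accs in gene_domains.items()]
    )


def _ddi(pairs):
    return DDITable([DDIEntry.make(a, b) for a, b in pairs])


class TestBuildInteractome:
    def test_toy_example(self, toy_interactome_inputs):
        annotations, catalog, ddi = toy_interactome_inputs
        inter = build_interactome(annotations, catalog, ddi, "spX")
        got = {(i.protein_id, i.gene_symbol): i.supporting_pairs for i in inter}
        assert got == {
            ("p1", "g1"): {("A", "X")},
            ("p2", "g1"): {("A", "X")},
            ("p2", "g2"): {("B", "Y")},
        }
        assert sum(len(i.supporting_pairs) for i in inter) == 3

    def test_protein_without_domains_never_interacts(self):
        inter = build_interactome(
            _annotations({"p1": set()}), _catalog({"g1": {"X"}}), _ddi([("A", "X")])
        )
        assert inter == []

    def test_self_pair_supports_interaction(self):
        inter = build_interactome(
            _annotations({"p1": {"A"}}), _catalog({"g1": {"A"}}), _ddi([("A", "A")])
        )
        assert len(inter) == 1
        assert inter[0].supporting_pairs == {("A", "A")}

    def test_empty_ddi_table_yields_empty_interactome(self):
        assert build_interactome(_annotations({"p1": {"A"}}), _catalog({"g1": {"A"}}),
                                 DDITable([])) == []

    def test_matches_brute_force_on_random_instances(self):
        """Exact agreement with naive triple-loop enumeration, many instances."""
        rng = random.Random(1234)
        domains = [f"PF{i:05d}" for i in range(20)]
        for _ in range(250):
            protein_domains = {
                f"p{i}": set(rng.sample(domains, rng.randint(0, 6)))
                for i in range(rng.randint(1, 50))
            }
            gene_domains = {
                f"g{i}": set(rng.sample(domains, rng.randint(0, 4)))
                for i in range(rng.randint(1, 30))
            }
            pairs = {
                tuple(sorted(rng.sample(domains, 2)))
                for _ in range(rng.randint(0, 40))
            }
            inter = build_interactome(
                _annotations(protein_domains), _catalog(gene_domains), _ddi(pairs)
            )
            got = {(i.protein_id, i.gene_symbol): set(i.supporting_pairs) for i in inter}
            assert got == brute_force_interactome(protein_domains, gene_domains, pairs)

    def test_adding_inputs_never_removes_interactions(self):
        """Interactions are monotone in DDI entries, annotations and genes."""
        rng = random.Random(99)
        domains = [f"PF{i:05d}" for i in range(10)]
        protein_domains = {f"p{i}": set(rng.sample(domains, 3)) for i in range(10)}
        gene_domains = {f"g{i}": set(rng.sample(domains, 2)) for i in range(8)}
        pairs = [tuple(sorted(rng.sample(domains, 2))) for _ in range(12)]

        def keys(pd, gd, pr):
            return {
                (i.protein_id, i.gene_symbol)
                for i in build_interactome(_annotations(pd), _catalog(gd), _ddi(pr))
            }

        base = keys(protein_domains, gene_domains, pairs[:6])
        assert base <= keys(protein_domains, gene_domains, pairs)  # more DDI entries
        richer = {**protein_domains, "p_new": set(domains[:4])}
        assert base <= keys(richer, gene_domains, pairs[:6])  # more annotations
        more_genes = {**gene_domains, "g_new": set(domains[:3])}
        assert base <= keys(protein_domains, more_genes, pairs[:6])  # more genes

    def test_deterministic_output_bytes(self, tmp_path):
        annotations = _annotations({"p2": {"B", "A"}, "p1": {"A"}})
        catalog = _catalog({"g2": {"Y"}, "g1": {"X"}})
        ddi = _ddi([("B", "Y"), ("A", "X")])
        paths = []
        for run in range(2):
            inter = build_interactome(annotations, catalog, ddi, "spX")
            p = tmp_path / f"run{run}.tsv"
            write_interactome(inter, catalog, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestSummaries:
    def test_toy_counts(self, toy_interactome_inputs):
        annotations, catalog, ddi = toy_interactome_inputs
        proteome = {
            p: ProteinRecord(p, "spX", 10) for p in ("p1", "p2", "p3")
        }
        inter = build_interactome(annotations, catalog, ddi, "spX")
        s = summarize_interactome(inter, proteome, catalog, annotations)
        assert s.n_proteins_total == 3
        assert s.n_proteins_with_domains == 2
        assert s.n_interacting_proteins == 2
        assert s.n_cancer_partners == 2
        assert s.n_interactions == 3
        assert s.n_domain_links == 3
        assert s.partner_counts_by_role == {TSG: 2, OCG: 1, DUAL: 0}

    def test_empty_interactome_summary(self):
        s = summarize_interactome([], {}, _catalog({}), [], species_id="spX")
        assert s.n_interactions == 0 and s.n_domain_links == 0

    def test_protein_counted_in_every_role_group_it_touches(self):
        catalog = _catalog({"g1": {"X"}, "g2": {"Y"}}, roles={"g1": TSG, "g2": DUAL})
        inter = build_interactome(
            _annotations({"p1": {"A", "B"}}), catalog, _ddi([("A", "X"), ("B", "Y")])
        )
        s = summarize_interactome(inter, {"p1": ProteinRecord("p1", "s", 5)}, catalog,
                                  _annotations({"p1": {"A", "B"}}))
        assert s.partner_counts_by_role == {TSG: 1, OCG: 0, DUAL: 1}

    def test_role_groups_cover_exactly_the_interacting_proteins(self, default_dataset):
        """Union of the three role groups equals the interacting protein set."""
        from crossddi.pipeline import run_pipeline

        out, _ = default_dataset
        result = run_pipeline(out)
        for species, inter in result.interactomes.items():
            interacting = {i.protein_id for i in inter}
            union = set()
            for role in (TSG, OCG, DUAL):
                group = {
                    i.protein_id for i in inter if result.catalog[i.gene_symbol].role == role
                }
                assert len(group) == result.summaries[species].partner_counts_by_role[role]
                union |= group
            assert union == interacting
            s = result.summaries[species]
            assert s.n_interactions == len(inter)
            assert s.n_domain_links == sum(len(i.supporting_pairs) for i in inter)
            assert s.n_interacting_proteins <= s.n_proteins_with_domains <= s.n_proteins_total


class TestRanking:
    def test_counts_and_tie_break(self, toy_interactome_inputs):
        annotations, catalog, ddi = toy_interactome_inputs
        inter = build_interactome(annotations, catalog, ddi, "spX")
        ranked = rank_domains_by_interactions(inter, {}, k=10)
        assert [(acc, n) for acc, n, _, _ in ranked] == [("A", 2), ("B", 1)]
        top1 = rank_domains_by_interactions(inter, {}, k=1)
        assert top1[0][0] == "A"

    def test_equal_counts_break_lexicographically(self):
        inter = build_interactome(
            _annotations({"p1": {"B"}, "p2": {"A"}}),
            _catalog({"g1": {"X"}}),
            _ddi([("A", "X"), ("B", "X")]),
        )
        ranked = rank_domains_by_interactions(inter, {}, k=2)
        assert [acc for acc, *_ in ranked] == ["A", "B"]

    def test_k_must_be_positive(self):
        with pytest.raises(ValidationError):
            rank_domains_by_interactions([], {}, k=0)


class TestTsgHubs:
    def _hub_instance(self, n_tsg, n_dual=0, n_ocg=0):
        genes = {f"t{i}": {"X"} for i in range(n_tsg)}
        roles = {f"t{i}": TSG for i in range(n_tsg)}
        genes.update({f"d{i}": {"X"} for i in range(n_dual)})
        roles.update({f"d{i}": DUAL for i in range(n_dual)})
        genes.update({f"o{i}": {"X"} for i in range(n_ocg)})
        roles.update({f"o{i}": OCG for i in range(n_ocg)})
        inter = build_interactome(
            _annotations({"hub": {"A"}}), _catalog(genes, roles), _ddi([("A", "X")])
        )
        return inter, _catalog(genes, roles)

    def test_threshold_is_inclusive(self):
        inter, catalog = self._hub_instance(n_tsg=100)
        assert filter_tsg_hubs(inter, catalog, min_tsg_partners=100) == {"hub"}

    def test_ocg_partners_do_not_count(self):
        inter, catalog = self._hub_instance(n_tsg=99, n_ocg=5)
        assert filter_tsg_hubs(inter, catalog, min_tsg_partners=100) == set()

    def test_dual_partners_count_only_with_flag(self):
        inter, catalog = self._hub_instance(n_tsg=99, n_dual=2)
        assert filter_tsg_hubs(inter, catalog, 100, include_dual=False) == set()
        assert filter_tsg_hubs(inter, catalog, 100, include_dual=True) == {"hub"}


class TestCrossSpeciesOverlaps:
    def test_identical_interactomes(self, toy_interactome_inputs):
        annotations, catalog, ddi = toy_interactome_inputs
        a = build_interactome(annotations, catalog, ddi, "sp1")
        b = build_interactome(annotations, catalog, ddi, "sp2")
        genes, domains = cross_species_overlaps({"sp1": a, "sp2": b})
        assert genes.loc["sp1", "sp2"] == genes.loc["sp1", "sp1"] == 2
        assert domains.loc["sp1", "sp2"] == domains.loc["sp1", "sp1"] == 2

    def test_disjoint_domain_vocabularies(self):
        a = build_interactome(_annotations({"p1": {"A"}}), _catalog({"g1": {"X"}}),
                              _ddi([("A", "X")]), "sp1")
        b = build_interactome(_annotations({"q1": {"B"}}), _catalog({"g1": {"Y"}}),
                              _ddi([("B", "Y")]), "sp2")
        genes, domains = cross_species_overlaps({"sp1": a, "sp2": b})
        assert domains.loc["sp1", "sp2"] == 0
        assert genes.loc["sp1", "sp2"] == 1  # same partner gene either way

    def test_planted_overlaps_match_brute_force_sets(self):
        rng = random.Random(7)
        domains = [f"PF{i:05d}" for i in range(12)]
        gene_domains = {f"g{i}": set(rng.sample(domains, 2)) for i in range(10)}
        catalog = _catalog(gene_domains)
        pairs = {tuple(sorted(rng.sample(domains, 2))) for _ in range(20)}
        inters = {}
        for s in ("sp1", "sp2", "sp3"):
            pd = {f"{s}_p{i}": set(rng.sample(domains, 3)) for i in range(15)}
            inters[s] = build_interactome(_annotations(pd), catalog, _ddi(pairs), s)
        genes, doms = cross_species_overlaps(inters)
        gene_sets = {s: {i.gene_symbol for i in inters[s]} for s in inters}
        dom_sets = {s: {a for i in inters[s] for a, _ in i.supporting_pairs} for s in inters}
        for r in inters:
            for c in inters:
                assert genes.loc[r, c] == len(gene_sets[r] & gene_sets[c])
                assert doms.loc[r, c] == len(dom_sets[r] & dom_sets[c])

    def test_needs_two_interactomes(self):
        with pytest.raises(ValidationError):
            cross_species_overlaps({"sp1": []})
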