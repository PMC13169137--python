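"""Bipartite gene-pathway network, modules, hubs and layout export."""

import numpy as np
import pytest

from cisburden.enrichment import EnrichmentResult, GeneSet
from cisburden.errors import ConfigurationError
from cisburden.network import (
    MODULE_LABELS, UNASSIGNED, assign_modules, build_network, export_layout,
    find_hubs, load_category_map,
)


def result(sid, padj=0.01, name=None):
    return EnrichmentResult(sid, name or sid, 1, 5, 5, 20, padj, frozenset(), p_adjusted=padj)


def random_fixture(seed, n_genes=30, n_sets=10, density=0.3):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n_genes)]
    membership = rng.random((n_genes, n_sets)) < density
    sets = [
        GeneSet(f"S{j}", f"S{j}", frozenset(genes[i] for i in range(n_genes) if membership[i, j]))
        for j in range(n_sets)
    ]
    prioritized = set(rng.choice(genes, size=n_genes // 2, replace=False))
    significant = [result(s.set_id) for s in sets]
    return genes, membership, sets, prioritized, significant


class TestBuildNetwork:
    def test_membership_intersection(self):
        sets = [GeneSet("S", "S", frozenset({"A", "B"}))]
        net = build_network([result("S")], sets, {"A", "C"})
        assert net.edges == {("A", "S")}
        assert net.gene_nodes == {"A"} and net.pathway_nodes == {"S"}

    def test_no_significant_sets_empty_network(self):
        net = build_network([], [], {"A"})
        assert net.is_empty and net.gene_nodes == set()

    def test_unknown_set_reference_fatal(self):
        with pytest.raises(ConfigurationError):
            build_network([result("MISSING")], [], {"A"})

    def test_edge_set_equals_membership_matrix_support(self):
        genes, membership, sets, prioritized, significant = random_fixture(0)
        net = build_network(significant, sets, prioritized)
        expected = {
            (genes[i], f"S{j}")
            for i in range(len(genes)) for j in range(len(sets))
            if membership[i, j] and genes[i] in prioritized
        }
        assert net.edges == expected

    def test_bipartite_and_degree_sum_identities(self):
        for seed in range(10):
            _, _, sets, prioritized, significant = random_fixture(seed)
            net = build_network(significant, sets, prioritized)
            # two-coloring: every edge joins a gene node to a pathway node
            assert all(g in net.gene_nodes and s in net.pathway_nodes for g, s in net.edges)
            assert net.gene_nodes.isdisjoint(net.pathway_nodes)
            assert sum(net.gene_degree.values()) == len(net.edges)
            assert sum(net.pathway_degree.values()) == len(net.edges)
            for g in net.gene_nodes:
                assert net.gene_degree[g] == sum(1 for e in net.edges if e[0] == g)


class TestAssignModules:
    def test_single_adjacency(self):
        sets = [GeneSet("S", "immune pathway", frozenset({"A"}))]
        net = build_network([result("S")], sets, {"A"})
        modules = assign_modules(net, {"S": "immune"})
        assert modules.gene_modules["A"] == {"immune"}

    def test_union_semantics(self):
        sets = [GeneSet("S1", "x", frozenset({"A"})), GeneSet("S2", "y", frozenset({"A"}))]
        net = build_network([result("S1"), result("S2")], sets, {"A"})
        modules = assign_modules(net, {"S1": "immune", "S2": "metabolic"})
        assert modules.gene_modules["A"] == {"immune", "metabolic"}

    def test_name_pattern_matching(self):
        sets = [GeneSet("S1", "Steroid hormone biosynthesis", frozenset({"A"}))]
        net = build_network([result("S1", name="Steroid hormone biosynthesis")], sets, {"A"})
        modules = assign_modules(net, {"steroid": "endocrine"})
        assert modules.pathway_module["S1"] == "endocrine"

    def test_uncovered_pathways_unassigned(self):
        sets = [GeneSet(f"S{i}", f"S{i}", frozenset({"A"})) for i in range(10)]
        net = build_network([result(f"S{i}") for i in range(10)], sets, {"A"})
        cat = {f"S{i}": MODULE_LABELS[i % 4] for i in range(8)}
        modules = assign_modules(net, cat)
        unassigned = [s for s, m in modules.pathway_module.items() if m == UNASSIGNED]
        assert sorted(unassigned) == ["S8", "S9"]

    def test_bad_label_in_map_rejected(self, tmp_path):
        path = tmp_path / "map.yaml"
        path.write_text("S1: not_a_module\n")
        with pytest.raises(ConfigurationError):
            load_category_map(path)


class TestFindHubs:
    def test_max_degree_is_hub(self):
        sets = [GeneSet(f"S{i}", f"S{i}", frozenset({"g1"} | ({"g2"} if i == 0 else set())))
                for i in range(3)]
        net = build_network([result(f"S{i}") for i in range(3)], sets, {"g1", "g2"})
        modules = assign_modules(net, {f"S{i}": "immune" for i in range(3)})
        hubs = find_hubs(net, modules, top_n=1)
        assert hubs.per_module["immune"] == [("g1", 3)]

    def test_alphabetical_tie_break(self):
        sets = [GeneSet("S", "S", frozenset({"b", "a"}))]
        net = build_network([result("S")], sets, {"a", "b"})
        modules = assign_modules(net, {"S": "metabolic"})
        hubs = find_hubs(net, modules, top_n=2)
        assert hubs.per_module["metabolic"] == [("a", 1), ("b", 1)]

    def test_within_module_degree_le_overall(self):
        _, _, sets, prioritized, significant = random_fixture(4)
        net = build_network(significant, sets, prioritized)
        cat = {s.set_id: MODULE_LABELS[i % 4] for i, s in enumerate(sets)}
        modules = assign_modules(net, cat)
        hubs = find_hubs(net, modules, top_n=50)
        for label, ranking in hubs.per_module.items():
            for gene, within in ranking:
                assert within <= net.gene_degree[gene]

    def test_ranking_equals_bruteforce_adjacency_count(self):
        for seed in range(8):
            _, _, sets, prioritized, significant = random_fixture(seed)
            net = build_network(significant, sets, prioritized)
            cat = {s.set_id: MODULE_LABELS[i % 4] for i, s in enumerate(sets)}
            modules = assign_modules(net, cat)
            hubs = find_hubs(net, modules, top_n=10**6)
            for label, ranking in hubs.per_module.items():
                brute = {}
                for g, s in net.edges:
                    if modules.pathway_module[s] == label:
                        brute[g] = brute.get(g, 0) + 1
                assert dict(ranking) == brute
                degrees = [d for _, d in ranking]
                assert degrees == sorted(degrees, reverse=True)

    def test_edge_order_invariance(self):
        _, _, sets, prioritized, significant = random_fixture(5)
        net1 = build_network(significant, sets, prioritized)
        net2 = build_network(list(reversed(significant)), sets, prioritized)
        cat = {s.set_id: MODULE_LABELS[i % 4] for i, s in enumerate(sets)}
        h1 = find_hubs(net1, assign_modules(net1, cat))
        h2 = find_hubs(net2, assign_modules(net2, cat))
        assert h1.per_module == h2.per_module


class TestExportLayout:
    def test_seeded_determinism(self):
        _, _, sets, prioritized, significant = random_fixture(6)
        net = build_network(significant, sets, prioritized)
        modules = assign_modules(net, {})
        a = export_layout(net, modules, seed=42)
        b = export_layout(net, modules, seed=42)
        assert a.equals(b)
        c = export_layout(net, modules, seed=43)
        assert not a[["x", "y"]].equals(c[["x", "y"]])

    def test_empty_network_empty_table(self):
        layout = export_layout(build_network([], [], set()), assign_modules(build_network([], [], set()), {}), seed=0)
        assert layout.empty

    def test_nodes_match_network(self):
        _, _, sets, prioritized, significant = random_fixture(7)
        net = build_network(significant, sets, prioritized)
        layout = export_layout(net, assign_modules(net, {}), seed=1)
        assert set(layout["node"]) == net.gene_nodes | net.pathway_nodes
        by_type = layout.groupby("node_type")["node"].apply(set).to_dict()
        assert by_type.get("gene", set()) == net.gene_nodes
        assert by_type.get("pathway", set()) == net.pathway_nodes
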