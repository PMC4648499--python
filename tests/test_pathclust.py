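"""Association matrix, cosine distances, clustering, module extraction."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from crosspath.enrich import EnrichmentRecord
from crosspath.iocore import PathwayAnnotation
from crosspath.pathclust import (
    AssociationMatrix,
    ClusterConfig,
    build_association_matrix,
    cluster_pathways,
    extract_common_module,
    pathway_cosine_distance,
)


def record(pid, significant=True):
    return EnrichmentRecord(pathway_id=pid, k=1, m=1, n=1, N=10,
                            p_raw=0.01, p_adj=0.01, direction="enriched",
                            significant=significant)


def pathway(pid, genes):
    return PathwayAnnotation(pid, pid, "functional", frozenset(genes))


def matrix_from_dict(cols: dict[str, set[str]]) -> AssociationMatrix:
    genes = sorted(set().union(*cols.values()))
    table = pd.DataFrame(0, index=genes, columns=sorted(cols), dtype=np.int8)
    for pid, gs in cols.items():
        table.loc[sorted(gs), pid] = 1
    return AssociationMatrix(table=table)


class TestAssociationMatrix:
    def test_membership_restricted_to_cfnn(self, triangle):
        db = [pathway("P", {"B", "C", "D"})]
        am = build_association_matrix(triangle, [record("P")], db)
        assert set(am.genes) == {"B", "C"}
        assert am.associated_genes_of("P") == {"B", "C"}

    def test_identical_pathways_identical_columns(self, triangle):
        db = [pathway("P", {"A", "B"}), pathway("Q", {"A", "B"})]
        am = build_association_matrix(triangle, [record("P"), record("Q")], db)
        assert (am.table["P"] == am.table["Q"]).all()

    def test_gene_outside_significant_pathways_absent(self, triangle):
        db = [pathway("P", {"A"}), pathway("Q", {"B"})]
        am = build_association_matrix(
            triangle, [record("P"), record("Q", significant=False)], db)
        assert set(am.genes) == {"A"}

    def test_no_associated_genes_rejected(self, triangle):
        db = [pathway("P", {"X", "Y"})]
        with pytest.raises(ValueError):
            build_association_matrix(triangle, [record("P")], db)


class TestCosineDistance:
    def test_identical_columns_distance_zero(self):
        am = matrix_from_dict({"P": {"a", "b"}, "Q": {"a", "b"}})
        d = pathway_cosine_distance(am)
        assert d.loc["P", "Q"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_columns_distance_one(self):
        am = matrix_from_dict({"P": {"a"}, "Q": {"b"}})
        d = pathway_cosine_distance(am)
        assert d.loc["P", "Q"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        am = matrix_from_dict({"P": {"a", "b"}, "Q": {"a"}})
        d = pathway_cosine_distance(am)
        assert d.loc["P", "Q"] == pytest.approx(1 - 1 / math.sqrt(2),
                                                abs=1e-12)
        assert d.loc["Q", "P"] == d.loc["P", "Q"]
        assert d.loc["P", "P"] == 0.0


class TestClusterPathways:
    def test_identical_pathways_merge(self):
        am = matrix_from_dict({"P": {"a", "b"}, "Q": {"a", "b"}})
        clusters = cluster_pathways(pathway_cosine_distance(am))
        assert clusters == [frozenset({"P", "Q"})]

    def test_all_orthogonal_stay_singletons(self):
        am = matrix_from_dict({"P": {"a"}, "Q": {"b"}, "R": {"c"}})
        clusters = cluster_pathways(
            pathway_cosine_distance(am),
            ClusterConfig(cut_distance=0.5, linkage="average"),
        )
        assert sorted(map(sorted, clusters)) == [["P"], ["Q"], ["R"]]

    def test_planted_two_block_structure_recovered(self):
        rng = np.random.default_rng(5)
        shared_a = {f"a{i}" for i in range(8)}
        shared_b = {f"b{i}" for i in range(8)}
        cols = {}
        for i in range(5):
            cols[f"A{i}"] = set(rng.choice(sorted(shared_a), 6, replace=False))
            cols[f"B{i}"] = set(rng.choice(sorted(shared_b), 6, replace=False))
        clusters = cluster_pathways(
            pathway_cosine_distance(matrix_from_dict(cols)))
        assert len(clusters) == 2
        assert frozenset(f"A{i}" for i in range(5)) in clusters
        assert frozenset(f"B{i}" for i in range(5)) in clusters

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(6)
        cols = {f"P{i}": set(rng.choice([f"g{j}" for j in range(12)], 5,
                                        replace=False))
                for i in range(8)}
        am1 = matrix_from_dict(cols)
        reordered = am1.table[list(reversed(am1.pathways))]
        am2 = AssociationMatrix(table=reordered)
        c1 = cluster_pathways(pathway_cosine_distance(am1))
        c2 = cluster_pathways(pathway_cosine_distance(am2))
        assert sorted(map(sorted, c1)) == sorted(map(sorted, c2))

    def test_ward_linkage_supports_published_cut(self):
        am = matrix_from_dict({"P": {"a", "b"}, "Q": {"a", "b"},
                               "R": {"c"}, "S": {"d"}})
        clusters = cluster_pathways(
            pathway_cosine_distance(am),
            ClusterConfig(cut_distance=1.1, linkage="ward"),
        )
        assert any({"P", "Q"} <= c for c in clusters)


class TestExtractCommonModule:
    def test_singleton_cluster_identity(self, triangle):
        am = matrix_from_dict({"P": {"A", "B"}})
        mod = extract_common_module(frozenset({"P"}), am, triangle)
        assert mod.common_genes == {"A", "B"}
        assert set(mod.subnetwork.nodes) == {"A", "B"}

    def test_disjoint_associated_genes_give_empty_module(self, triangle):
        am = matrix_from_dict({"P": {"A"}, "Q": {"B"}})
        mod = extract_common_module(frozenset({"P", "Q"}), am, triangle)
        assert mod.common_genes == frozenset()
        assert mod.avg_cc is None

    def test_planted_clique_module_has_cc_one(self):
        clique_genes = [f"m{i}" for i in range(6)]
        cfnn = nx.complete_graph(6)
        cfnn = nx.relabel_nodes(cfnn, dict(enumerate(clique_genes)))
        cfnn.add_edge("m0", "x")  # a neighbor outside the module
        cols = {f"P{i}": set(clique_genes) | {f"extra{i}"} for i in range(4)}
        am = matrix_from_dict(cols)
        mod = extract_common_module(frozenset(cols), am, cfnn)
        assert mod.common_genes == set(clique_genes)
        assert mod.avg_cc == 1.0

    def test_module_is_subgraph_of_cfnn(self, small_dataset):
        from crosspath.enrich import enrich_pathways
        from crosspath.iocore import GenePanel
        from crosspath.overlap import build_cfnn, intersect_panels
        ds = small_dataset
        cfnn = build_cfnn(ds.network, intersect_panels(ds.panels))
        records = enrich_pathways(
            GenePanel.from_iterable("cfnn", cfnn.nodes), ds.pathways)
        am = build_association_matrix(cfnn, records, ds.pathways)
        clusters = (cluster_pathways(pathway_cosine_distance(am))
                    if len(am.pathways) > 1 else [frozenset(am.pathways)])
        for i, cluster in enumerate(clusters):
            mod = extract_common_module(cluster, am, cfnn, i + 1)
            assert set(mod.subnetwork.nodes) <= set(cfnn.nodes)
            assert set(map(frozenset, mod.subnetwork.edges)) <= \
                set(map(frozenset, cfnn.edges))
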