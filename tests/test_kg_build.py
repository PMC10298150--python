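"""Graph transforms, merge algebra, and semantic validation."""

from collections import Counter
from itertools import permutations

import pytest

from kgxpress.errors import CategoryConflictError
from kgxpress.formats_io import GafAnnotation
from kgxpress.graph import KGEdge, KGNode, KnowledgeGraph
from kgxpress.kg_build import (
    merge,
    transform_annotations,
    transform_orthology,
    validate,
)

# the aspect -> (predicate, object category) semantics, restated
# independently of the implementation's routing table
EXPECTED_ROUTING = {
    "C": ("active in", "cellular component"),
    "F": ("enables", "molecular function"),
    "P": ("regulates", "biological process"),
    "A": ("expressed in", "anatomical entity"),
    "G": ("expressed in", "life stage"),
    "T": ("has phenotype", "phenotypic feature"),
}


def gaf(gene, term, aspect, taxon="NCBITaxon:3702"):
    return GafAnnotation(
        gene_id=gene, gene_symbol=gene, qualifier="", term_id=term,
        taxon=taxon, evidence_code="IEA", aspect=aspect,
    )


class TestTransformAnnotations:
    def test_cellular_component_routes_to_active_in(self):
        g, problems = transform_annotations([gaf("AT1G01010", "GO:0005886", "C")])
        assert problems == []
        triples = {(e.subject, e.predicate, e.object) for e in g.edges}
        assert ("AT1G01010", "active in", "GO:0005886") in triples
        assert ("AT1G01010", "in taxon", "NCBITaxon:3702") in triples
        assert g.nodes["AT1G01010"].category == "genomic entity"
        assert g.nodes["GO:0005886"].category == "cellular component"

    def test_empty_input_is_empty_graph(self):
        g, problems = transform_annotations([])
        assert len(g.nodes) == 0 and len(g.edges) == 0 and problems == []

    def test_unknown_aspect_is_record_level_error(self):
        g, problems = transform_annotations(
            [gaf("g1", "GO:0005886", "C"), gaf("g2", "GO:0005886", "Z")]
        )
        assert len(problems) == 1
        assert "g2" in problems[0]
        assert "g2" not in g.nodes

    def test_generator_gaf_transforms_to_manifest_edges(self, default_bundle):
        bundle, truth = default_bundle
        for taxon, records in bundle.gaf_records.items():
            g, problems = transform_annotations(records)
            assert problems == []
            expected = Counter()
            for r in records:
                predicate, category = EXPECTED_ROUTING[r.aspect]
                expected[(r.gene_id, predicate, r.term_id)] += 1
                assert g.nodes[r.term_id].category == category
            observed = Counter(
                (e.subject, e.predicate, e.object)
                for e in g.edges
                if e.predicate != "in taxon"
            )
            assert observed == expected
            assert validate(g).ok


class TestTransformOrthology:
    def test_symmetric_pairs_collapse_to_canonical_order(self):
        edges = transform_orthology([("B", "A"), ("A", "B")])
        assert len(edges) == 1
        assert (edges[0].subject, edges[0].object) == ("A", "B")

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            transform_orthology([("A", "A")])

    def test_property_distinct_assertions_are_kept(self):
        edges = transform_orthology(
            [("A", "B", {"annotation": "x"}), ("B", "A", {"annotation": "y"})]
        )
        assert len(edges) == 2

    def test_planted_pairs_stored_once_each(self, default_bundle):
        bundle, truth = default_bundle
        edges = transform_orthology([(a, b) for a, b, _ in bundle.ortholog_rows])
        assert len(edges) == len(truth.ortholog_pairs)
        assert {(e.subject, e.object) for e in edges} == set(
            tuple(p) for p in truth.ortholog_pairs
        )


def toy_graph(node_ids, edge_pairs, category="genomic entity"):
    return KnowledgeGraph(
        nodes=[KGNode(i, category) for i in node_ids],
        edges=[KGEdge(a, "orthologous to", b) for a, b in edge_pairs],
    )


class TestMerge:
    def test_merge_with_self_is_idempotent(self):
        g = toy_graph(["A", "B", "C"], [("A", "B"), ("B", "C")])
        merged, report = merge([g, g])
        assert merged == g
        assert report.duplicate_edges_removed == 2

    def test_shared_node_counts_by_inclusion_exclusion(self):
        g1 = toy_graph(["A", "B"], [("A", "B")])
        g2 = toy_graph(["B", "C"], [("B", "C")])
        merged, report = merge([g1, g2])
        assert report.merged_nodes == 3  # 2 + 2 - 1
        assert report.merged_edges == 2

    def test_category_conflict_is_hard_error(self):
        g1 = KnowledgeGraph(nodes=[KGNode("X", "genomic entity")])
        g2 = KnowledgeGraph(nodes=[KGNode("X", "organism taxon")])
        with pytest.raises(CategoryConflictError):
            merge([g1, g2])

    def test_name_conflict_reported_not_fatal(self):
        g1 = KnowledgeGraph(nodes=[KGNode("X", "genomic entity", name="alpha")])
        g2 = KnowledgeGraph(nodes=[KGNode("X", "genomic entity", name="beta")])
        merged, report = merge([g1, g2])
        assert report.name_conflicts == ["X"]
        assert merged.nodes["X"].name == "alpha"  # deterministic winner

    def test_overlapping_sources_union_sizes(self, rng):
        ids = [f"N{i:03d}" for i in range(60)]
        graphs = []
        for _ in range(3):
            chosen = sorted(rng.choice(60, size=30, replace=False).tolist())
            node_ids = [ids[i] for i in chosen]
            pairs = [(node_ids[j], node_ids[j + 1]) for j in range(0, 28, 2)]
            graphs.append(toy_graph(node_ids, pairs))
        merged, report = merge(graphs)
        expected_nodes = set().union(*(g.nodes for g in graphs))
        expected_edges = {
            (e.subject, e.object) for g in graphs for e in g.edges
        }
        assert set(merged.nodes) == expected_nodes
        assert {(e.subject, e.object) for e in merged.edges} == expected_edges
        assert report.merged_nodes == len(expected_nodes)

    def test_merge_is_order_insensitive_and_associative(self, rng):
        ids = [f"N{i:02d}" for i in range(20)]
        graphs = []
        for _ in range(3):
            chosen = sorted(rng.choice(20, size=10, replace=False).tolist())
            node_ids = [ids[i] for i in chosen]
            pairs = [(node_ids[j], node_ids[j + 1]) for j in range(0, 8, 2)]
            graphs.append(toy_graph(node_ids, pairs))
        reference, _ = merge(list(graphs))
        for order in permutations(range(3)):
            permuted, _ = merge([graphs[i] for i in order])
            assert permuted == reference
        nested, _ = merge([merge([graphs[0], graphs[1]])[0], graphs[2]])
        assert nested == reference


class TestValidate:
    def test_missing_endpoint_is_integrity_violation(self):
        g = KnowledgeGraph(nodes=[KGNode("A", "genomic entity")])
        g.add_edge(KGEdge("A", "orthologous to", "GHOST"))
        report = validate(g)
        assert len(report.violations) == 1
        assert "GHOST" in report.violations[0]

    def test_unknown_predicate_is_vocabulary_violation(self):
        g = toy_graph(["A", "B"], [])
        g.add_edge(KGEdge("A", "causes", "B"))
        report = validate(g)
        assert len(report.violations) == 1
        assert "predicate" in report.violations[0]

    def test_domain_range_mismatch_is_flagged(self):
        g = KnowledgeGraph(
            nodes=[KGNode("A", "organism taxon"), KGNode("B", "organism taxon")],
            edges=[KGEdge("A", "orthologous to", "B")],
        )
        assert not validate(g).ok

    def test_own_transforms_validate_clean(self, default_bundle):
        bundle, _ = default_bundle
        graph = bundle.build_graph()
        report = validate(graph)
        assert report.ok, report.violations
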