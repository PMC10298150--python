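"""Transforms from typed inputs to graph elements, plus merge and validation.

Annotation records become ``genomic entity`` nodes wired to ontology-term
nodes; the GAF aspect routes the predicate (cellular component ->
``active in``, molecular function -> ``enables``, biological process ->
``regulates``, plant anatomy -> ``expressed in``, growth stage ->
``expressed in``, trait -> ``has phenotype``). Orthology pairs are stored
once in canonical lexicographic order and treated as symmetric at query
time. Merging takes the id-union of nodes and deduplicates edges on
(subject, predicate, object, canonicalized properties).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import CategoryConflictError
from .formats_io import GafAnnotation
from .graph import (
    CATEGORIES,
    DOMAIN_RANGE,
    PREDICATES,
    KGEdge,
    KGNode,
    KnowledgeGraph,
    canonical_properties,
)

#: GAF aspect code -> (predicate, object-node category). C/F/P are the GO
#: aspects; A/G/T are the extension aspects used for plant anatomy, growth
#: stage, and trait annotations.
ASPECT_ROUTING: dict[str, tuple[str, str]] = {
    "C": ("active in", "cellular component"),
    "F": ("enables", "molecular function"),
    "P": ("regulates", "biological process"),
    "A": ("expressed in", "anatomical entity"),
    "G": ("expressed in", "life stage"),
    "T": ("has phenotype", "phenotypic feature"),
}


@dataclass
class MergeReport:
    source_nodes: list[int] = field(default_factory=list)
    source_edges: list[int] = field(default_factory=list)
    merged_nodes: int = 0
    merged_edges: int = 0
    duplicate_edges_removed: int = 0
    name_conflicts: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "source_nodes": self.source_nodes,
            "source_edges": self.source_edges,
            "merged_nodes": self.merged_nodes,
            "merged_edges": self.merged_edges,
            "duplicate_edges_removed": self.duplicate_edges_removed,
            "name_conflicts": self.name_conflicts,
        }


@dataclass
class ValidationReport:
    """Every violation found in a graph; empty list means conformant."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def transform_annotations(
    gaf_records: Iterable[GafAnnotation],
    term_labels: Mapping[str, str] | None = None,
    provided_by: str = "annotations",
) -> tuple[KnowledgeGraph, list[str]]:
    """Build the annotation subgraph from GAF records.

    Returns the graph plus a list of record-level errors (unknown aspects);
    offending records are skipped, everything else is transformed. Each
    gene gets a ``genomic entity`` node and an ``in taxon`` edge; each
    annotation becomes one aspect-routed edge to a term node.
    """
    labels = term_labels or {}
    graph = KnowledgeGraph()
    problems: list[str] = []
    for rec in gaf_records:
        routing = ASPECT_ROUTING.get(rec.aspect)
        if routing is None:
            problems.append(f"unknown aspect {rec.aspect!r} on gene {rec.gene_id}")
            continue
        predicate, term_category = routing
        graph.add_node(
            KGNode(rec.gene_id, category="genomic entity", name=rec.gene_symbol,
                   provided_by=provided_by)
        )
        graph.add_node(
            KGNode(rec.taxon, category="organism taxon", name=labels.get(rec.taxon, ""),
                   provided_by=provided_by)
        )
        graph.add_node(
            KGNode(rec.term_id, category=term_category, name=labels.get(rec.term_id, ""),
                   provided_by=provided_by)
        )
        graph.add_edge(KGEdge(rec.gene_id, "in taxon", rec.taxon, provided_by=provided_by))
        graph.add_edge(KGEdge(rec.gene_id, predicate, rec.term_id, provided_by=provided_by))
    return graph, problems


def transform_orthology(
    pairs: Iterable[tuple],
    provided_by: str = "orthology",
) -> list[KGEdge]:
    """One ``orthologous to`` edge per unordered pair, canonically ordered.

    Each item is ``(gene_a, gene_b)`` or ``(gene_a, gene_b, properties)``.
    The lexicographically smaller id becomes the subject, so (A, B) and
    (B, A) collapse to one stored edge; pairs differing only in their
    property maps (e.g. two annotation records for the same pair) remain
    distinct edges. Self-pairs are rejected.
    """
    edges: list[KGEdge] = []
    seen: set[tuple] = set()
    for item in pairs:
        if len(item) == 2:
            a, b = item
            props: dict[str, str] = {}
        else:
            a, b, props = item
            props = dict(props)
        if a == b:
            raise ValueError(f"self-pair rejected: ({a!r}, {b!r})")
        subject, obj = (a, b) if a <= b else (b, a)
        key = (subject, obj, canonical_properties({str(k): str(v) for k, v in props.items()}))
        if key in seen:
            continue
        seen.add(key)
        edges.append(
            KGEdge(subject, "orthologous to", obj, provided_by=provided_by, properties=props)
        )
    return edges


def merge(graphs: Sequence[KnowledgeGraph]) -> tuple[KnowledgeGraph, MergeReport]:
    """Union nodes by id and deduplicate edges across all source graphs.

    A node id appearing with two categories is a hard error. A node id
    appearing with two non-empty names keeps the lexicographically first
    name (for determinism) and the conflict is listed in the report.
    """
    report = MergeReport()
    merged = KnowledgeGraph()
    for g in graphs:
        report.source_nodes.append(len(g.nodes))
        report.source_edges.append(len(g.edges))
        for node in g.nodes.values():
            existing = merged.nodes.get(node.id)
            if existing is not None:
                if existing.category != node.category:
                    raise CategoryConflictError(
                        f"node {node.id!r}: category conflict "
                        f"{existing.category!r} vs {node.category!r}"
                    )
                if existing.name and node.name and existing.name != node.name:
                    if node.id not in report.name_conflicts:
                        report.name_conflicts.append(node.id)
                    winner = min(existing.name, node.name)
                    merged.nodes[node.id] = KGNode(
                        id=node.id, category=node.category, name=winner,
                        provided_by=existing.provided_by,
                    )
                    continue
            merged.add_node(node)
        for edge in g.edges:
            fresh = KGEdge(edge.subject, edge.predicate, edge.object,
                           provided_by=edge.provided_by, properties=dict(edge.properties))
            if not merged.add_edge(fresh):
                report.duplicate_edges_removed += 1
    report.name_conflicts.sort()
    report.merged_nodes = len(merged.nodes)
    report.merged_edges = len(merged.edges)
    return merged, report


def validate(graph: KnowledgeGraph) -> ValidationReport:
    """Check referential integrity and the closed semantic vocabularies."""
    report = ValidationReport()
    for node in graph.nodes.values():
        if node.category not in CATEGORIES:
            report.violations.append(f"node {node.id}: unknown category {node.category!r}")
    for e in graph.edges:
        missing = [x for x in (e.subject, e.object) if x not in graph.nodes]
        for node_id in missing:
            report.violations.append(
                f"edge ({e.subject}, {e.predicate}, {e.object}): missing node {node_id!r}"
            )
        if e.predicate not in PREDICATES:
            report.violations.append(
                f"edge ({e.subject}, {e.predicate}, {e.object}): unknown predicate"
            )
            continue
        if missing:
            continue
        triple = (graph.nodes[e.subject].category, e.predicate, graph.nodes[e.object].category)
        if triple not in DOMAIN_RANGE:
            report.violations.append(
                f"edge ({e.subject}, {e.predicate}, {e.object}): "
                f"category pair {triple[0]!r} -> {triple[2]!r} not allowed for this predicate"
            )
    return report


def ensure_nodes_for_edges(
    graph: KnowledgeGraph,
    edges: Iterable[KGEdge],
    categories: Mapping[str, str],
    provided_by: str = "",
) -> None:
    """Add stub nodes for edge endpoints not yet in the graph.

    ``categories`` maps node id -> category; endpoints absent from both the
    graph and the mapping raise, since a node without a category cannot be
    validated.
    """
    for e in edges:
        for endpoint in (e.subject, e.object):
            if endpoint in graph.nodes:
                continue
            category = categories.get(endpoint)
            if category is None:
                raise KeyError(f"no category known for node {endpoint!r}")
            graph.add_node(KGNode(endpoint, category=category, provided_by=provided_by))
        graph.add_edge(e)
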