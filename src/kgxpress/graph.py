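"""Core knowledge-graph containers and the closed Biolink-style vocabularies.

Nodes carry one of ten semantic categories (anatomical entity, genomic
entity, environmental exposure, ...) and edges one of nine predicates
(``in taxon``, ``orthologous to``, ``increases expression of``, ...).
Each predicate is constrained to the (subject category, object category)
combinations of the semantic model; anything outside the closed sets is a
validation error, not a silent pass-through.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import CategoryConflictError

# -- closed vocabularies ----------------------------------------------------

CATEGORIES = frozenset(
    {
        "anatomical entity",
        "life stage",
        "phenotypic feature",
        "genomic entity",
        "environmental exposure",
        "organismal entity",
        "organism taxon",
        "cellular component",
        "molecular function",
        "biological process",
    }
)

PREDICATES = frozenset(
    {
        "in taxon",
        "active in",
        "regulates",
        "enables",
        "expressed in",
        "has phenotype",
        "orthologous to",
        "increases expression of",
        "decreases expression of",
    }
)

#: Allowed (subject category, predicate, object category) triples.
DOMAIN_RANGE: frozenset[tuple[str, str, str]] = frozenset(
    {
        ("genomic entity", "in taxon", "organism taxon"),
        ("genomic entity", "active in", "cellular component"),
        ("genomic entity", "regulates", "biological process"),
        ("genomic entity", "enables", "molecular function"),
        ("genomic entity", "expressed in", "anatomical entity"),
        ("genomic entity", "expressed in", "life stage"),
        ("genomic entity", "has phenotype", "phenotypic feature"),
        ("genomic entity", "orthologous to", "genomic entity"),
        ("organism taxon", "has phenotype", "phenotypic feature"),
        ("organismal entity", "in taxon", "organism taxon"),
        ("organismal entity", "has phenotype", "phenotypic feature"),
        ("environmental exposure", "increases expression of", "genomic entity"),
        ("environmental exposure", "decreases expression of", "genomic entity"),
    }
)

EXPRESSION_PREDICATES = frozenset({"increases expression of", "decreases expression of"})

#: Biolink CURIEs for the Cypher export of the homolog-pair query.
BIOLINK_CURIES = {
    "in taxon": "biolink:in_taxon",
    "active in": "biolink:active_in",
    "regulates": "biolink:regulates",
    "enables": "biolink:enables",
    "expressed in": "biolink:expressed_in",
    "has phenotype": "biolink:has_phenotype",
    "orthologous to": "biolink:orthologous_to",
    "increases expression of": "biolink:increases_expression_of",
    "decreases expression of": "biolink:decreases_expression_of",
}


def normalize_property_value(value: object) -> str:
    """Canonical string form of an edge-property value for dedup hashing.

    Numeric strings are normalized ("2.50" and "2.5" hash alike); anything
    else is stripped of surrounding whitespace and kept verbatim.
    """
    s = str(value).strip()
    try:
        f = float(s)
    except (TypeError, ValueError):
        return s
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


def canonical_properties(properties: dict[str, str]) -> tuple[tuple[str, str], ...]:
    """Sorted, value-normalized view of a property map used as a dedup key."""
    return tuple(sorted((k, normalize_property_value(v)) for k, v in properties.items()))


@dataclass(frozen=True)
class KGNode:
    """A typed graph node: CURIE or prefixed gene id plus a semantic category."""

    id: str
    category: str
    name: str = ""
    provided_by: str = ""


@dataclass
class KGEdge:
    """A typed edge with provenance and an open key->value property map."""

    subject: str
    predicate: str
    object: str
    provided_by: str = ""
    properties: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.properties = {str(k): str(v) for k, v in self.properties.items()}

    def dedup_key(self) -> tuple:
        """Identity for deduplication: endpoints, predicate, canonical properties.

        Provenance is deliberately excluded; duplicate assertions from two
        sources collapse to one edge with merged ``provided_by``.
        """
        return (self.subject, self.predicate, self.object, canonical_properties(self.properties))

    def full_key(self) -> tuple:
        return (self.subject, self.predicate, self.object, self.provided_by,
                canonical_properties(self.properties))


class KnowledgeGraph:
    """An id-keyed node set plus a deduplicated edge multiset."""

    def __init__(self, nodes: Iterable[KGNode] = (), edges: Iterable[KGEdge] = ()):
        self.nodes: dict[str, KGNode] = {}
        self.edges: list[KGEdge] = []
        self._edge_keys: set[tuple] = set()
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(e)

    # -- construction -------------------------------------------------------

    def add_node(self, node: KGNode) -> None:
        existing = self.nodes.get(node.id)
        if existing is None:
            self.nodes[node.id] = node
            return
        if existing.category != node.category:
            raise CategoryConflictError(
                f"node {node.id!r} declared both {existing.category!r} and {node.category!r}"
            )
        # keep the richer record: prefer one with a name
        if not existing.name and node.name:
            self.nodes[node.id] = KGNode(
                id=node.id, category=node.category, name=node.name,
                provided_by=existing.provided_by or node.provided_by,
            )

    def add_edge(self, edge: KGEdge) -> bool:
        """Add an edge unless an identical one (up to provenance) exists.

        Returns True if the edge was new. Duplicate assertions merge their
        provenance tags (pipe-joined, sorted).
        """
        key = edge.dedup_key()
        if key in self._edge_keys:
            for e in self.edges:
                if e.dedup_key() == key:
                    tags = {t for t in e.provided_by.split("|") if t}
                    tags.update(t for t in edge.provided_by.split("|") if t)
                    e.provided_by = "|".join(sorted(tags))
                    break
            return False
        self._edge_keys.add(key)
        self.edges.append(edge)
        return True

    # -- views ---------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def iter_edges(self, predicate: str | None = None) -> Iterator[KGEdge]:
        for e in self.edges:
            if predicate is None or e.predicate == predicate:
                yield e

    def node_category(self, node_id: str) -> str | None:
        node = self.nodes.get(node_id)
        return node.category if node else None

    def taxon_of(self, gene_id: str) -> str | None:
        """Taxon CURIE a gene is annotated ``in taxon`` to, if any."""
        for e in self.edges:
            if e.predicate == "in taxon" and e.subject == gene_id:
                return e.object
        return None

    def taxon_index(self) -> dict[str, str]:
        """One pass over ``in taxon`` edges: subject id -> taxon CURIE."""
        index: dict[str, str] = {}
        for e in self.edges:
            if e.predicate == "in taxon":
                index.setdefault(e.subject, e.object)
        return index

    # -- equality (round-trip tests rely on this) ----------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and sorted(e.full_key() for e in self.edges)
            == sorted(e.full_key() for e in other.edges)
        )

    def __repr__(self) -> str:
        return f"KnowledgeGraph(nodes={len(self.nodes)}, edges={len(self.edges)})"
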