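"""Native homolog-pair query over the knowledge graph.

The motif: an environmental exposure with an ``increases/decreases
expression of`` edge to each of two genes that are ``orthologous to`` one
another. The query is the in-memory equivalent of the Cypher pattern

    MATCH (e {id:'<exposure>'})-[r]->(g), (g)-[q:`biolink:orthologous_to`]-(h),
          (e {id:'<exposure>'})-[s]->(h) RETURN *

with orthology treated as symmetric regardless of stored direction. A
deliberately naive brute-force enumeration over edge triples ships
alongside as the correctness oracle for tests.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from typing import Iterable

from .graph import BIOLINK_CURIES, EXPRESSION_PREDICATES, KnowledgeGraph, canonical_properties

CONCORDANCE_SIMILAR = "similar"
CONCORDANCE_CONTRASTING = "contrasting"

#: Drought exposure term used throughout the worked analyses.
DROUGHT_EXPOSURE = "PECO:0007404"

ARABIDOPSIS_TAXON = "NCBITaxon:3702"
POPLAR_TAXON = "NCBITaxon:3694"


def classify_concordance(direction_a: str, direction_b: str) -> str:
    """``similar`` when both genes move the same way, else ``contrasting``."""
    return CONCORDANCE_SIMILAR if direction_a == direction_b else CONCORDANCE_CONTRASTING


@dataclass(frozen=True)
class HomologExpressionPair:
    """An exposure plus an ortholog pair with per-gene expression directions.

    Genes are stored in canonical (lexicographic) order. ``experiments_a``
    and ``experiments_b`` list the experiment ids supporting each gene's
    direction; ``evidence`` carries the canonicalized property map of the
    matched orthology edge, which distinguishes repeated assertions of the
    same pair (e.g. two annotation records).
    """

    exposure: str
    gene_a: str
    gene_b: str
    taxon_a: str
    taxon_b: str
    direction_a: str
    direction_b: str
    concordance: str
    experiments_a: tuple[str, ...] = ()
    experiments_b: tuple[str, ...] = ()
    evidence: tuple = ()

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def _make_pair(
    exposure: str,
    gene_a: str,
    gene_b: str,
    dir_a: str,
    dir_b: str,
    taxa: dict[str, str],
    exps_a: Iterable[str] = (),
    exps_b: Iterable[str] = (),
    evidence: tuple = (),
) -> HomologExpressionPair:
    if gene_b < gene_a:
        gene_a, gene_b = gene_b, gene_a
        dir_a, dir_b = dir_b, dir_a
        exps_a, exps_b = exps_b, exps_a
    return HomologExpressionPair(
        exposure=exposure,
        gene_a=gene_a,
        gene_b=gene_b,
        taxon_a=taxa.get(gene_a, ""),
        taxon_b=taxa.get(gene_b, ""),
        direction_a=dir_a,
        direction_b=dir_b,
        concordance=classify_concordance(dir_a, dir_b),
        experiments_a=tuple(sorted(set(exps_a))),
        experiments_b=tuple(sorted(set(exps_b))),
        evidence=evidence,
    )


def _direction_index(
    graph: KnowledgeGraph, exposure: str
) -> dict[str, dict[str, set[str]]]:
    """gene id -> direction -> set of supporting experiment ids."""
    index: dict[str, dict[str, set[str]]] = {}
    for e in graph.edges:
        if e.subject != exposure or e.predicate not in EXPRESSION_PREDICATES:
            continue
        direction = "increased" if e.predicate == "increases expression of" else "decreased"
        exps = index.setdefault(e.object, {}).setdefault(direction, set())
        exp_id = e.properties.get("experiment_id", "")
        if exp_id:
            exps.add(exp_id)
    return index


def find_exposure_homolog_pairs(
    graph: KnowledgeGraph,
    exposure: str,
    cross_taxon_only: bool = False,
    dedup: bool = True,
) -> list[HomologExpressionPair]:
    """All ortholog pairs in which both genes respond to the exposure.

    A gene with both an increase and a decrease edge under the exposure
    (different experiments) contributes one row per direction combination,
    each tagged with its supporting experiment ids. With ``dedup`` False,
    repeated orthology assertions for the same pair (distinct edge
    properties) each yield a row; with ``dedup`` True rows collapse on
    (exposure, canonical pair, direction combination).

    An absent exposure node yields an empty result with a warning rather
    than an error.
    """
    if exposure not in graph.nodes:
        warnings.warn(f"exposure node {exposure!r} absent from graph", stacklevel=2)
    directions = _direction_index(graph, exposure)
    taxa = graph.taxon_index()
    rows: list[HomologExpressionPair] = []
    for orth in graph.iter_edges("orthologous to"):
        g, h = orth.subject, orth.object
        if g not in directions or h not in directions:
            continue
        if cross_taxon_only:
            tg, th = taxa.get(g), taxa.get(h)
            if tg is None or th is None or tg == th:
                continue
        evidence = canonical_properties(orth.properties)
        for dir_g, exps_g in sorted(directions[g].items()):
            for dir_h, exps_h in sorted(directions[h].items()):
                rows.append(
                    _make_pair(exposure, g, h, dir_g, dir_h, taxa, exps_g, exps_h, evidence)
                )
    if dedup:
        rows = _dedup_rows(rows)
    return sorted(rows, key=_row_sort_key)


def _dedup_rows(rows: list[HomologExpressionPair]) -> list[HomologExpressionPair]:
    """Collapse rows on (exposure, pair, direction combination)."""
    merged: dict[tuple, HomologExpressionPair] = {}
    for row in rows:
        key = (row.exposure, row.gene_a, row.gene_b, row.direction_a, row.direction_b)
        prev = merged.get(key)
        if prev is None:
            merged[key] = HomologExpressionPair(
                **{**row.__dict__, "evidence": (row.evidence,)}
            )
        else:
            merged[key] = HomologExpressionPair(
                **{
                    **prev.__dict__,
                    "experiments_a": tuple(sorted(set(prev.experiments_a + row.experiments_a))),
                    "experiments_b": tuple(sorted(set(prev.experiments_b + row.experiments_b))),
                    "evidence": tuple(sorted(set(prev.evidence + (row.evidence,)))),
                }
            )
    return list(merged.values())


def _row_sort_key(row: HomologExpressionPair) -> tuple:
    return (row.exposure, row.gene_a, row.gene_b, row.direction_a, row.direction_b, row.evidence)


def brute_force_pairs(
    graph: KnowledgeGraph,
    exposure: str,
    cross_taxon_only: bool = False,
    dedup: bool = True,
) -> list[HomologExpressionPair]:
    """Exhaustive nested-loop oracle with the same result contract.

    For every orthology edge, scans the full edge list for expression
    edges from the exposure to each endpoint and emits every qualifying
    combination. Intended for graphs up to ~10^4 edges; shares no indexing
    code with :func:`find_exposure_homolog_pairs`.
    """
    taxa: dict[str, str] = {}
    for e in graph.edges:
        if e.predicate == "in taxon" and e.subject not in taxa:
            taxa[e.subject] = e.object
    rows: list[HomologExpressionPair] = []
    for orth in graph.edges:
        if orth.predicate != "orthologous to":
            continue
        g, h = orth.subject, orth.object
        if cross_taxon_only and (g not in taxa or h not in taxa or taxa[g] == taxa[h]):
            continue
        combos: dict[tuple[str, str], tuple[set[str], set[str]]] = {}
        for e1 in graph.edges:
            if e1.subject != exposure or e1.predicate not in EXPRESSION_PREDICATES:
                continue
            if e1.object != g:
                continue
            d1 = "increased" if e1.predicate == "increases expression of" else "decreased"
            for e2 in graph.edges:
                if e2.subject != exposure or e2.predicate not in EXPRESSION_PREDICATES:
                    continue
                if e2.object != h:
                    continue
                d2 = "increased" if e2.predicate == "increases expression of" else "decreased"
                exps_g, exps_h = combos.setdefault((d1, d2), (set(), set()))
                if e1.properties.get("experiment_id"):
                    exps_g.add(e1.properties["experiment_id"])
                if e2.properties.get("experiment_id"):
                    exps_h.add(e2.properties["experiment_id"])
        evidence = canonical_properties(orth.properties)
        for (d1, d2), (exps_g, exps_h) in sorted(combos.items()):
            rows.append(_make_pair(exposure, g, h, d1, d2, taxa, exps_g, exps_h, evidence))
    if dedup:
        rows = _dedup_rows(rows)
    return sorted(rows, key=_row_sort_key)


def cypher_for_exposure(exposure: str) -> str:
    """Equivalent Cypher text for users who load the KGX files into Neo4j."""
    orth = BIOLINK_CURIES["orthologous to"]
    return (
        f"MATCH (e {{id:'{exposure}'}})-[r]->(g), "
        f"(g)-[q:`{orth}`]-(h), "
        f"(e {{id:'{exposure}'}})-[s]->(h) RETURN *"
    )


# -- printed drought fixture ------------------------------------------------


def load_table3_fixture() -> list[HomologExpressionPair]:
    """The 16 printed A. thaliana x P. trichocarpa drought pair rows.

    Rows are returned exactly as printed, including the one duplicated
    pair (distinguished by its annotation text, carried in ``evidence``);
    deduplicate downstream when double counting matters.
    """
    taxa_by_prefix = {"AT": ARABIDOPSIS_TAXON, "POPTR": POPLAR_TAXON}
    rows: list[HomologExpressionPair] = []
    data = importlib.resources.files("kgxpress.data").joinpath("table3.tsv").read_text()
    lines = data.strip().split("\n")
    header = lines[0].split("\t")
    for line in lines[1:]:
        rec = dict(zip(header, line.split("\t")))
        gene_a, gene_b = rec["gene_a"], rec["gene_b"]
        taxa = {
            gene_a: taxa_by_prefix["AT" if gene_a.startswith("AT") else "POPTR"],
            gene_b: taxa_by_prefix["POPTR" if gene_b.startswith("POPTR") else "AT"],
        }
        rows.append(
            _make_pair(
                DROUGHT_EXPOSURE,
                gene_a,
                gene_b,
                rec["direction_a"],
                rec["direction_b"],
                taxa,
                evidence=canonical_properties({"annotation": rec["annotation"]}),
            )
        )
    return rows
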