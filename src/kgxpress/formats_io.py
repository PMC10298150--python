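"""Readers and writers for the external formats the pipeline touches.

Covers GAF 2.x annotation files, ontology term slices (JSON arrays of
``{id, label, namespace}``), differential-expression TSV exports, and the
KGX-style node/edge TSV exchange format. Every other module consumes the
record types produced here.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

from .errors import EmptyAnnotationSetError, GraphValidationError, TableParseError
from .graph import KGEdge, KGNode, KnowledgeGraph

CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_.]*:\S+$")


def is_curie(value: str) -> bool:
    return bool(CURIE_RE.match(value))


# -- domain types -----------------------------------------------------------


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology term: CURIE id, human label, and its prefix namespace."""

    id: str
    label: str
    namespace: str

    def __post_init__(self) -> None:
        if not is_curie(self.id):
            raise ValueError(f"not a CURIE: {self.id!r}")
        prefix = self.id.split(":", 1)[0]
        if self.namespace != prefix:
            raise ValueError(f"namespace {self.namespace!r} != prefix of {self.id!r}")


@dataclass(frozen=True)
class GafAnnotation:
    """One gene-to-term association from a GAF 2.x file.

    Only the interpreted columns are modeled; the remaining columns of the
    source line are carried as opaque text in ``extras``.
    """

    gene_id: str
    gene_symbol: str
    qualifier: str
    term_id: str
    taxon: str
    evidence_code: str
    aspect: str
    extras: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class DiffExprRecord:
    """One gene x comparison row of a differential-expression table."""

    gene_id: str
    taxon: str
    exposure_term: str
    log2fc: float
    p_value: float
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")


class GafReadResult(NamedTuple):
    records: list[GafAnnotation]
    skipped: list[tuple[int, str]]  # (1-based line number, reason)


# -- GAF --------------------------------------------------------------------

# GAF 2.x column indices (0-based)
_GAF_GENE, _GAF_SYMBOL, _GAF_QUALIFIER = 1, 2, 3
_GAF_TERM, _GAF_EVIDENCE, _GAF_ASPECT, _GAF_TAXON = 4, 6, 8, 12
_GAF_MIN_COLUMNS = 13


def _parse_gaf_taxon(cell: str) -> str:
    """'taxon:3702' or 'taxon:3702|taxon:...' -> 'NCBITaxon:3702'."""
    first = cell.split("|")[0].strip()
    if first.lower().startswith("taxon:"):
        return "NCBITaxon:" + first.split(":", 1)[1]
    return first


def read_gaf(path: str | Path) -> GafReadResult:
    """Read a GAF 2.x file; ``!``-prefixed lines are comments.

    Malformed lines (too few columns, empty gene/term/aspect, non-CURIE
    term or taxon) are reported with their line numbers and skipped rather
    than aborting the run. A file with zero valid records raises
    :class:`EmptyAnnotationSetError`.
    """
    path = Path(path)
    records: list[GafAnnotation] = []
    skipped: list[tuple[int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < _GAF_MIN_COLUMNS:
                skipped.append((lineno, f"expected >= {_GAF_MIN_COLUMNS} columns, got {len(cols)}"))
                continue
            gene = cols[_GAF_GENE].strip()
            term = cols[_GAF_TERM].strip()
            aspect = cols[_GAF_ASPECT].strip()
            taxon = _parse_gaf_taxon(cols[_GAF_TAXON])
            if not gene:
                skipped.append((lineno, "empty gene id"))
                continue
            if not term or not is_curie(term):
                skipped.append((lineno, f"missing or invalid term CURIE: {term!r}"))
                continue
            if not aspect:
                skipped.append((lineno, "empty aspect"))
                continue
            if not is_curie(taxon):
                skipped.append((lineno, f"invalid taxon CURIE: {taxon!r}"))
                continue
            records.append(
                GafAnnotation(
                    gene_id=gene,
                    gene_symbol=cols[_GAF_SYMBOL].strip(),
                    qualifier=cols[_GAF_QUALIFIER].strip(),
                    term_id=term,
                    taxon=taxon,
                    evidence_code=cols[_GAF_EVIDENCE].strip(),
                    aspect=aspect,
                    extras=tuple(cols[_GAF_MIN_COLUMNS:]),
                )
            )
    if not records:
        raise EmptyAnnotationSetError(f"empty annotation set: no valid records in {path}")
    return GafReadResult(records, skipped)


# -- ontology term slices ---------------------------------------------------


def read_ontology_terms(path: str | Path) -> list[OntologyTerm]:
    """Read a JSON array of ``{id, label, namespace}`` term objects."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return [OntologyTerm(id=t["id"], label=t.get("label", ""), namespace=t["namespace"]) for t in raw]


def write_ontology_terms(terms: Sequence[OntologyTerm], path: str | Path) -> None:
    payload = [{"id": t.id, "label": t.label, "namespace": t.namespace} for t in terms]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


# -- expression tables ------------------------------------------------------

#: Default column-name mapping for GXA-style exports; overridable because
#: header spellings vary across Atlas releases.
DEFAULT_EXPRESSION_COLUMNS = {
    "gene_id": "gene_id",
    "log2fc": "log2foldchange",
    "p_value": "p_value",
}


def read_expression_table(
    path: str | Path,
    exposure_term: str,
    taxon: str,
    columns: dict[str, str] | None = None,
    experiment_id: str = "",
) -> list[DiffExprRecord]:
    """Read a differential-expression TSV, stamping exposure and taxon.

    ``columns`` maps the logical names ``gene_id``/``log2fc``/``p_value``
    to the header names actually present. Unparseable numeric cells raise
    :class:`TableParseError` naming the offending row and column — missing
    data must be handled explicitly upstream, never dropped silently.
    """
    colmap = dict(DEFAULT_EXPRESSION_COLUMNS)
    if columns:
        colmap.update(columns)
    records: list[DiffExprRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise TableParseError(f"no header in {path}")
        for logical in ("gene_id", "log2fc", "p_value"):
            if colmap[logical] not in reader.fieldnames:
                raise TableParseError(
                    f"column {colmap[logical]!r} (for {logical}) missing from {path}; "
                    f"header has {reader.fieldnames}"
                )
        for rownum, row in enumerate(reader, start=2):  # 1-based incl. header
            gene = (row[colmap["gene_id"]] or "").strip()
            values: dict[str, float] = {}
            for logical in ("log2fc", "p_value"):
                cell = (row[colmap[logical]] or "").strip()
                try:
                    values[logical] = float(cell)
                except ValueError:
                    raise TableParseError(
                        f"{path}: row {rownum}, column {colmap[logical]!r}: "
                        f"cannot parse {cell!r} as a number",
                        row=rownum,
                        column=colmap[logical],
                    ) from None
            records.append(
                DiffExprRecord(
                    gene_id=gene,
                    taxon=taxon,
                    exposure_term=exposure_term,
                    log2fc=values["log2fc"],
                    p_value=values["p_value"],
                    experiment_id=experiment_id,
                )
            )
    return records


# -- KGX TSV ----------------------------------------------------------------

NODE_CORE_COLUMNS = ["id", "category", "name", "provided_by"]
EDGE_CORE_COLUMNS = ["subject", "predicate", "object", "provided_by"]


def write_kgx_tsv(graph: KnowledgeGraph, directory: str | Path) -> tuple[Path, Path]:
    """Write ``nodes.tsv`` and ``edges.tsv`` in KGX style.

    Core columns come first in a fixed order; edge-property columns are
    appended alphabetically so identical graphs produce byte-identical
    files. Cells must be tab-free (enforced).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    node_path = directory / "nodes.tsv"
    edge_path = directory / "edges.tsv"

    def check(value: str) -> str:
        if "\t" in value or "\n" in value:
            raise ValueError(f"cell contains a tab or newline: {value!r}")
        return value

    with open(node_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(NODE_CORE_COLUMNS) + "\n")
        for node_id in sorted(graph.nodes):
            n = graph.nodes[node_id]
            fh.write("\t".join(check(v) for v in (n.id, n.category, n.name, n.provided_by)) + "\n")

    prop_columns = sorted({k for e in graph.edges for k in e.properties})
    with open(edge_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(EDGE_CORE_COLUMNS + prop_columns) + "\n")
        rows = sorted(graph.edges, key=lambda e: e.full_key())
        for e in rows:
            cells = [e.subject, e.predicate, e.object, e.provided_by]
            cells += [e.properties.get(k, "") for k in prop_columns]
            fh.write("\t".join(check(c) for c in cells) + "\n")
    return node_path, edge_path


def read_kgx_tsv(directory: str | Path) -> KnowledgeGraph:
    """Read a ``nodes.tsv``/``edges.tsv`` pair written by :func:`write_kgx_tsv`.

    Edges referencing a node id absent from the node file fail with a
    :class:`GraphValidationError` listing every offender.
    """
    directory = Path(directory)
    graph = KnowledgeGraph()
    with open(directory / "nodes.tsv", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            graph.add_node(
                KGNode(
                    id=row["id"],
                    category=row["category"],
                    name=row.get("name", ""),
                    provided_by=row.get("provided_by", ""),
                )
            )
    offenders: list[str] = []
    with open(directory / "edges.tsv", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        prop_columns = [c for c in (reader.fieldnames or []) if c not in EDGE_CORE_COLUMNS]
        for row in reader:
            for endpoint in (row["subject"], row["object"]):
                if endpoint not in graph.nodes:
                    offenders.append(endpoint)
            props = {k: row[k] for k in prop_columns if row.get(k, "") != ""}
            graph.add_edge(
                KGEdge(
                    subject=row["subject"],
                    predicate=row["predicate"],
                    object=row["object"],
                    provided_by=row.get("provided_by", ""),
                    properties=props,
                )
            )
    if offenders:
        uniq = sorted(set(offenders))
        raise GraphValidationError(
            f"edges reference {len(uniq)} node id(s) absent from nodes.tsv", offenders=uniq
        )
    return graph
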