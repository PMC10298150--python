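"""End-to-end assembly: input bundle -> merged, validated knowledge graph.

A *bundle* is a directory with a ``manifest.json`` naming per-taxon GAF
and differential-expression files, an ortholog map, and optional id-map /
trait-dictionary / TFBS-hit files. This module wires the readers,
filters, and transforms together; each step lives in its own module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import expression_filter as ef
from . import kg_build
from .formats_io import DiffExprRecord, GafAnnotation, read_expression_table, read_gaf
from .graph import KGEdge, KGNode, KnowledgeGraph

MANIFEST_NAME = "manifest.json"


@dataclass
class BundleInputs:
    """In-memory form of a bundle: typed records ready for assembly."""

    exposure: str
    thresholds: tuple[float, float, float]  # (p_max, lfc_lower, lfc_upper)
    gaf_sets: list[tuple[list[GafAnnotation], str]] = field(default_factory=list)
    expression_sets: list[list[DiffExprRecord]] = field(default_factory=list)
    ortholog_rows: list[tuple[str, str, str]] = field(default_factory=list)  # (a, b, annotation)


def assemble_graph(inputs: BundleInputs) -> tuple[KnowledgeGraph, kg_build.MergeReport]:
    """Transform every source into a subgraph and merge them all."""
    p_max, lfc_lower, lfc_upper = inputs.thresholds
    graphs: list[KnowledgeGraph] = []

    for records, tag in inputs.gaf_sets:
        g, problems = kg_build.transform_annotations(records, provided_by=tag)
        if problems:
            raise ValueError(f"{tag}: {len(problems)} unroutable annotation(s): {problems[:3]}")
        graphs.append(g)

    for records in inputs.expression_sets:
        directional = ef.filter_differential(
            records, p_max=p_max, lfc_lower=lfc_lower, lfc_upper=lfc_upper
        )
        g = KnowledgeGraph()
        g.add_node(KGNode(inputs.exposure, category="environmental exposure", provided_by="gxa"))
        for d in directional:
            rec = d.record
            g.add_node(KGNode(rec.gene_id, category="genomic entity", provided_by="gxa"))
            if rec.taxon:
                g.add_node(KGNode(rec.taxon, category="organism taxon", provided_by="gxa"))
                g.add_edge(KGEdge(rec.gene_id, "in taxon", rec.taxon, provided_by="gxa"))
        for edge in ef.to_exposure_edges(directional, provided_by="gxa"):
            g.add_edge(edge)
        graphs.append(g)

    if inputs.ortholog_rows:
        pairs = []
        for a, b, annotation in inputs.ortholog_rows:
            props = {"annotation": annotation} if annotation else {}
            pairs.append((a, b, props))
        edges = kg_build.transform_orthology(pairs, provided_by="orthology")
        g = KnowledgeGraph()
        kg_build.ensure_nodes_for_edges(
            g,
            edges,
            categories={e: "genomic entity" for edge in edges for e in (edge.subject, edge.object)},
            provided_by="orthology",
        )
        graphs.append(g)

    return kg_build.merge(graphs)


def read_bundle(directory: str | Path) -> BundleInputs:
    """Load a bundle directory (manifest plus referenced files) from disk."""
    directory = Path(directory)
    with open(directory / MANIFEST_NAME, encoding="utf-8") as fh:
        manifest = json.load(fh)
    thresholds = manifest.get("thresholds", {})
    inputs = BundleInputs(
        exposure=manifest["exposure"],
        thresholds=(
            float(thresholds.get("p_max", ef.DEFAULT_P_MAX)),
            float(thresholds.get("lfc_lower", ef.DEFAULT_LFC_LOWER)),
            float(thresholds.get("lfc_upper", ef.DEFAULT_LFC_UPPER)),
        ),
    )
    for source in manifest.get("sources", []):
        taxon = source["taxon"]
        if source.get("gaf"):
            result = read_gaf(directory / source["gaf"])
            inputs.gaf_sets.append((result.records, f"gaf:{taxon}"))
        if source.get("expression"):
            records = read_expression_table(
                directory / source["expression"],
                exposure_term=manifest["exposure"],
                taxon=taxon,
                experiment_id=source.get("experiment_id", ""),
            )
            inputs.expression_sets.append(records)
    ortholog_file = manifest.get("ortholog_map")
    if ortholog_file:
        with open(directory / ortholog_file, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                cols = line.rstrip("\n").split("\t")
                row = dict(zip(header, cols))
                inputs.ortholog_rows.append(
                    (row["gene_a"], row["gene_b"], row.get("annotation", ""))
                )
    return inputs


def build_graph_from_bundle(
    directory: str | Path,
) -> tuple[KnowledgeGraph, kg_build.MergeReport]:
    """Read a bundle directory and assemble the merged knowledge graph."""
    return assemble_graph(read_bundle(directory))


def validate_or_raise(graph: KnowledgeGraph) -> None:
    report = kg_build.validate(graph)
    if not report.ok:
        raise ValueError("graph failed validation:\n" + "\n".join(report.violations))
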