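"""Differential-expression filtering and direction annotation.

A gene is considered responsive to an exposure when its comparison against
baseline is both statistically significant (p below the cutoff) and of
useful magnitude (log2 fold change outside the [lower, upper] band). All
three thresholds are strict inequalities, so boundary rows (p exactly at
the cutoff, |log2FC| exactly at the band edge) are excluded. Retained
records are annotated with a direction — increased for positive log2FC,
decreased for negative — and turned into exposure->gene expression edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .formats_io import DiffExprRecord
from .graph import KGEdge

DIRECTION_INCREASED = "increased"
DIRECTION_DECREASED = "decreased"

DEFAULT_P_MAX = 0.05
DEFAULT_LFC_LOWER = -1.0
DEFAULT_LFC_UPPER = 1.0


@dataclass(frozen=True)
class DirectionalExpression:
    """A retained differential-expression record plus its direction label."""

    record: DiffExprRecord
    direction: str


def filter_differential(
    records: Sequence[DiffExprRecord],
    p_max: float = DEFAULT_P_MAX,
    lfc_lower: float = DEFAULT_LFC_LOWER,
    lfc_upper: float = DEFAULT_LFC_UPPER,
) -> list[DirectionalExpression]:
    """Retain records with ``p < p_max`` and ``log2fc < lfc_lower or > lfc_upper``.

    All comparisons are strict. Retained records are labeled increased when
    log2fc exceeds the upper bound and decreased when it falls below the
    lower bound, so the direction can never contradict the sign of the
    retained fold change.
    """
    if not lfc_lower < lfc_upper:
        raise ValueError(f"lfc_lower ({lfc_lower}) must be < lfc_upper ({lfc_upper})")
    if not 0.0 < p_max <= 1.0:
        raise ValueError(f"p_max must be in (0, 1], got {p_max}")
    if not records:
        return []
    lfc = np.array([r.log2fc for r in records], dtype=float)
    if not np.isfinite(lfc).all():
        bad = [records[i].gene_id for i in np.flatnonzero(~np.isfinite(lfc))]
        raise ValueError(f"non-finite log2fc for gene(s): {bad}")
    pval = np.array([r.p_value for r in records], dtype=float)
    keep = (pval < p_max) & ((lfc < lfc_lower) | (lfc > lfc_upper))
    out: list[DirectionalExpression] = []
    for idx in np.flatnonzero(keep):
        rec = records[idx]
        direction = DIRECTION_INCREASED if rec.log2fc > lfc_upper else DIRECTION_DECREASED
        out.append(DirectionalExpression(record=rec, direction=direction))
    return out


def to_exposure_edges(
    directional: Iterable[DirectionalExpression], provided_by: str = "gxa"
) -> list[KGEdge]:
    """One exposure->gene edge per retained record.

    The predicate encodes the direction (``increases expression of`` vs.
    ``decreases expression of``); the experiment id rides along as an edge
    property so duplicate observations from distinct experiments remain
    distinguishable after merge deduplication.
    """
    edges: list[KGEdge] = []
    for d in directional:
        rec = d.record
        if not rec.exposure_term:
            raise ValueError(f"record for {rec.gene_id!r} has no exposure term")
        predicate = (
            "increases expression of"
            if d.direction == DIRECTION_INCREASED
            else "decreases expression of"
        )
        properties = {}
        if rec.experiment_id:
            properties["experiment_id"] = rec.experiment_id
        edges.append(
            KGEdge(
                subject=rec.exposure_term,
                predicate=predicate,
                object=rec.gene_id,
                provided_by=provided_by,
                properties=properties,
            )
        )
    return edges
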