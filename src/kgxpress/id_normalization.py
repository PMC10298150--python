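"""Normalization of gene and trait identifiers to canonical assembly forms.

Gene catalogs drift between assembly releases (rice MSU vs. RAP ids, maize
B73 assembly versions, poplar v3 suffixes), so every upstream table is
joined through explicit mapping files before graph construction. Mapping
is total and never throws on unknown ids: every input id comes back with a
status (``mapped`` / ``passthrough`` / ``unmapped``) and the run report
conserves counts.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from .errors import AmbiguousMappingError

_VERSION_SUFFIX_RE = re.compile(r"v\d+$")

STATUS_MAPPED = "mapped"
STATUS_PASSTHROUGH = "passthrough"
STATUS_UNMAPPED = "unmapped"


@dataclass
class IdMap:
    """A named one-to-one source->target identifier map."""

    name: str
    mapping: dict[str, str] = field(default_factory=dict)

    def __contains__(self, source_id: str) -> bool:
        return source_id in self.mapping

    def __getitem__(self, source_id: str) -> str:
        return self.mapping[source_id]

    def __len__(self) -> int:
        return len(self.mapping)


class NormalizedId(NamedTuple):
    id: str
    status: str


@dataclass
class NormalizationReport:
    """Per-run counts; mapped + passthrough + unmapped == inputs."""

    mapped: int = 0
    passthrough: int = 0
    unmapped: int = 0

    @property
    def total(self) -> int:
        return self.mapped + self.passthrough + self.unmapped

    def count(self, status: str) -> None:
        if status == STATUS_MAPPED:
            self.mapped += 1
        elif status == STATUS_PASSTHROUGH:
            self.passthrough += 1
        else:
            self.unmapped += 1


def load_id_map(
    path: str | Path,
    name: str | None = None,
    source_col: int = 0,
    target_col: int = 1,
    allow: Iterable[tuple[str, str]] = (),
) -> IdMap:
    """Load a two-column (or configured-column) TSV into an :class:`IdMap`.

    A source id mapping to two distinct targets is an error at load time,
    listing every conflicting source. ``allow`` is the documented escape
    hatch for genuinely one-to-many assembly maps: an explicit
    (source, target) allow-list pins the winning row.
    """
    path = Path(path)
    allow_map = dict(allow)
    mapping: dict[str, str] = {}
    conflicts: set[str] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) <= max(source_col, target_col):
                continue
            src, dst = row[source_col].strip(), row[target_col].strip()
            if not src or not dst:
                continue
            if src in mapping and mapping[src] != dst:
                if src in allow_map:
                    mapping[src] = allow_map[src]
                else:
                    conflicts.add(src)
                continue
            mapping[src] = allow_map.get(src, dst)
    if conflicts:
        listed = sorted(conflicts)
        raise AmbiguousMappingError(
            f"{path}: ambiguous mapping for {len(listed)} source id(s): "
            + ", ".join(listed[:10]) + ("..." if len(listed) > 10 else ""),
            conflicts=listed,
        )
    return IdMap(name=name or path.stem, mapping=mapping)


def strip_version_suffix(raw_id: str) -> str:
    """Drop a trailing ``v<digits>`` assembly suffix (POPTR-style ids)."""
    return _VERSION_SUFFIX_RE.sub("", raw_id)


def _lookup(raw_id: str, maps: Sequence[IdMap]) -> str | None:
    for m in maps:
        if raw_id in m:
            return m[raw_id]
    return None


def normalize_gene_id(
    raw_id: str, maps: Sequence[IdMap], strip_version: bool = False
) -> NormalizedId:
    """Normalize one gene id through the loaded maps.

    Lookup is attempted on the raw id and, when ``strip_version`` is set,
    on the version-stripped form as well. Mapped targets are resolved
    transitively (a target that is itself a source follows the chain) so
    normalization is idempotent; a mapping cycle is an error. Ids absent
    from every map pass through unchanged — with status ``passthrough``
    when version stripping altered them, ``unmapped`` otherwise.
    """
    candidates = [raw_id]
    stripped = strip_version_suffix(raw_id) if strip_version else raw_id
    if stripped != raw_id:
        candidates.append(stripped)
    for candidate in candidates:
        target = _lookup(candidate, maps)
        if target is None:
            continue
        seen = {candidate}
        while True:
            if target in seen:
                raise AmbiguousMappingError(
                    f"cyclic identifier mapping involving {target!r}", conflicts=sorted(seen)
                )
            seen.add(target)
            nxt = _lookup(target, maps)
            if nxt is None or nxt == target:
                return NormalizedId(target, STATUS_MAPPED)
            target = nxt
    if stripped != raw_id:
        return NormalizedId(stripped, STATUS_PASSTHROUGH)
    return NormalizedId(raw_id, STATUS_UNMAPPED)


def normalize_many(
    raw_ids: Iterable[str], maps: Sequence[IdMap], strip_version: bool = False
) -> tuple[list[NormalizedId], NormalizationReport]:
    """Vector form of :func:`normalize_gene_id` with a conserved-count report."""
    report = NormalizationReport()
    out: list[NormalizedId] = []
    for raw in raw_ids:
        result = normalize_gene_id(raw, maps, strip_version=strip_version)
        report.count(result.status)
        out.append(result)
    return out, report


# -- trait labels -----------------------------------------------------------


def _canonical_label(label: str) -> str:
    return re.sub(r"\s+", " ", label.strip()).casefold()


@dataclass
class TraitDictionary:
    """Case- and whitespace-insensitive lookup from trait label to TO CURIE."""

    entries: dict[str, str] = field(default_factory=dict)  # canonical label -> TO id

    @classmethod
    def load(cls, path: str | Path) -> "TraitDictionary":
        entries: dict[str, str] = {}
        conflicts: set[str] = set()
        with open(path, encoding="utf-8", newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#") or len(row) < 2:
                    continue
                label, term = _canonical_label(row[0]), row[1].strip()
                if not label or not term:
                    continue
                if label in entries and entries[label] != term:
                    conflicts.add(label)
                    continue
                entries[label] = term
        if conflicts:
            raise AmbiguousMappingError(
                f"{path}: trait labels map to multiple TO terms: {sorted(conflicts)}",
                conflicts=sorted(conflicts),
            )
        return cls(entries=entries)


def annotate_trait(label: str, dictionary: TraitDictionary) -> str | None:
    """Resolve a free-text trait label to a TO CURIE, or None if unmapped."""
    return dictionary.entries.get(_canonical_label(label))
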