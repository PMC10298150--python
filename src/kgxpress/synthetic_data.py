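"""Synthetic input bundles with planted ground truth.

Emulates every upstream format the pipeline consumes — per-taxon GAF
annotation files, GXA-style differential-expression tables, ortholog
maps, gene-id version maps, trait dictionaries, and PlantPAN-style TFBS
hit tables — with a fully known ground truth so each stage is testable
offline. Responsive ortholog pairs are planted with chosen expression
directions and concordance labels; promoter profiles of pair members are
drawn as correlated binaries (shared-latent Gaussian thresholding) so
similar pairs have high profile correlation and contrasting pairs low.

Defaults mirror the worked drought analysis: two taxa (Arabidopsis-style
and Populus-style gene ids), 8 similar plus 8 contrasting pairs, strong
responsive effects (|log2FC| around 2.5), 60 TF families of which 12 are
ubiquitous and 11 are specifically absent from a divergent subset of
Populus genes.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .formats_io import DiffExprRecord, GafAnnotation
from .kg_query import (
    ARABIDOPSIS_TAXON,
    DROUGHT_EXPOSURE,
    POPLAR_TAXON,
    classify_concordance,
    load_table3_fixture,
)
from .pipeline import MANIFEST_NAME, BundleInputs, assemble_graph
from .promoter_similarity import build_tfbs_matrix, drop_ubiquitous_families, find_absent_families

# -- configuration ----------------------------------------------------------

_TAXA = [ARABIDOPSIS_TAXON, POPLAR_TAXON, "NCBITaxon:4558", "NCBITaxon:4577", "NCBITaxon:4530"]

#: 12 families present in every promoter (removed before clustering) and 11
#: families specifically missing from the divergent subset; the remainder of
#: the catalog carries the correlated pair signal.
UBIQUITOUS_FAMILY_NAMES = [
    "AT-Hook", "bHLH", "C2H2", "Dehydrin", "Dof", "GATA",
    "Homeodomain", "Myb/SANT", "NF-YB", "TBP", "Trihelix", "ZF-HD",
]
ABSENT_FAMILY_NAMES = [
    "RAV", "MIKC", "NAM", "G2-like", "CPP", "ARR-B", "tify", "TALE", "NF-YC", "ERF", "NF-YA",
]
_INFORMATIVE_FAMILY_NAMES = [
    "WRKY", "bZIP", "MYB", "AP2", "B3", "BES1", "BBR-BPC", "C3H", "CAMTA", "DBB",
    "E2F-DP", "EIL", "FAR1", "GRAS", "GRF", "GeBP", "HB-PHD", "HD-ZIP", "HSF", "LBD",
    "LFY", "M-type", "MYB-related", "NF-X1", "Nin-like", "S1Fa-like", "SAP", "SBP",
    "SRS", "STAT", "TCP", "VOZ", "WOX", "Whirly", "YABBY", "ZF-GATA", "bZIP-like",
]


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the worked-analysis conditions."""

    seed: int = 0
    n_taxa: int = 2
    genes_per_taxon: int = 60
    ortholog_fraction: float = 0.5
    n_pairs_similar: int = 8
    n_pairs_contrasting: int = 8
    lfc_effect: float = 2.5
    lfc_effect_sd: float = 0.3
    lfc_null_sd: float = 0.4
    p_signal_max: float = 0.01
    n_tf_families: int = 60
    n_ubiquitous: int = 12
    profile_rho_similar: float = 0.8
    profile_rho_contrasting: float = 0.0
    n_divergent_subset: int = 7
    n_absent_families: int = 11
    n_idmap: int = 200
    n_traits: int = 40
    n_trait_misses: int = 10
    exposure: str = DROUGHT_EXPOSURE
    p_max: float = 0.05
    lfc_lower: float = -1.0
    lfc_upper: float = 1.0

    def validate(self) -> None:
        n_orth = int(self.ortholog_fraction * self.genes_per_taxon)
        if self.n_pairs_similar + self.n_pairs_contrasting > n_orth:
            raise ConfigError(
                f"{self.n_pairs_similar}+{self.n_pairs_contrasting} planted pairs exceed "
                f"the {n_orth} ortholog pairs implied by ortholog_fraction"
            )
        if self.n_ubiquitous + self.n_absent_families > self.n_tf_families:
            raise ConfigError("n_ubiquitous + n_absent_families exceeds n_tf_families")
        if self.n_divergent_subset > self.n_pairs_contrasting:
            raise ConfigError("divergent subset larger than the contrasting-pair gene pool")
        if self.n_taxa < 2 or self.n_taxa > len(_TAXA):
            raise ConfigError(f"n_taxa must be in [2, {len(_TAXA)}]")
        if not (0.0 <= self.ortholog_fraction <= 1.0):
            raise ConfigError("ortholog_fraction must be in [0, 1]")
        for rho in (self.profile_rho_similar, self.profile_rho_contrasting):
            if not (-1.0 <= rho <= 1.0):
                raise ConfigError(f"profile correlation {rho} outside [-1, 1]")


@dataclass
class PlantedPair:
    gene_a: str
    gene_b: str
    direction_a: str
    direction_b: str
    concordance: str


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for recovery tests."""

    pairs: list[PlantedPair]
    responsive: dict[str, str]  # gene -> direction
    ortholog_pairs: list[tuple[str, str]]  # all ortholog pairs incl. non-responsive
    ubiquitous_families: list[str]
    absent_families: list[str]
    divergent_subset: list[str]
    realized_phi: dict[str, float]  # "gene_a|gene_b" -> phi of emitted profiles
    gaf_truth: dict[str, list[tuple[str, str]]]  # taxon -> (gene, term) multiset
    id_map: dict[str, str]
    trait_queries: list[tuple[str, str | None]]

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SyntheticBundle:
    """In-memory bundle; :meth:`write` serializes it deterministically."""

    exposure: str
    thresholds: tuple[float, float, float]
    sources: list[dict] = field(default_factory=list)  # per-taxon metadata
    gaf_records: dict[str, list[GafAnnotation]] = field(default_factory=dict)
    expression_rows: dict[str, list[tuple[str, float, float]]] = field(default_factory=dict)
    ortholog_rows: list[tuple[str, str, str]] = field(default_factory=list)
    id_map_rows: list[tuple[str, str]] = field(default_factory=list)
    trait_rows: list[tuple[str, str]] = field(default_factory=list)
    tfbs_rows: list[tuple[str, str, int]] = field(default_factory=list)

    # -- assembly without touching disk -------------------------------------

    def to_inputs(self) -> BundleInputs:
        inputs = BundleInputs(exposure=self.exposure, thresholds=self.thresholds)
        for source in self.sources:
            taxon = source["taxon"]
            if taxon in self.gaf_records:
                inputs.gaf_sets.append((self.gaf_records[taxon], f"gaf:{taxon}"))
            rows = self.expression_rows.get(taxon, [])
            inputs.expression_sets.append(
                [
                    DiffExprRecord(
                        gene_id=g, taxon=taxon, exposure_term=self.exposure,
                        log2fc=lfc, p_value=p, experiment_id=source["experiment_id"],
                    )
                    for g, lfc, p in rows
                ]
            )
        inputs.ortholog_rows = list(self.ortholog_rows)
        return inputs

    def build_graph(self):
        graph, _report = assemble_graph(self.to_inputs())
        return graph

    # -- serialization -------------------------------------------------------

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        manifest: dict = {
            "exposure": self.exposure,
            "thresholds": {
                "p_max": self.thresholds[0],
                "lfc_lower": self.thresholds[1],
                "lfc_upper": self.thresholds[2],
            },
            "sources": [],
        }
        for source in self.sources:
            taxon = source["taxon"]
            tag = taxon.replace(":", "_")
            entry = {"taxon": taxon, "experiment_id": source["experiment_id"]}
            if taxon in self.gaf_records:
                gaf_path = directory / f"annotations_{tag}.gaf"
                _write_gaf(gaf_path, self.gaf_records[taxon])
                entry["gaf"] = gaf_path.name
                paths[f"gaf:{taxon}"] = gaf_path
            if taxon in self.expression_rows:
                expr_path = directory / f"expression_{tag}.tsv"
                with open(expr_path, "w", encoding="utf-8") as fh:
                    fh.write("gene_id\tlog2foldchange\tp_value\n")
                    for gene, lfc, p in self.expression_rows[taxon]:
                        fh.write(f"{gene}\t{lfc:.6f}\t{p:.10g}\n")
                entry["expression"] = expr_path.name
                paths[f"expression:{taxon}"] = expr_path
            manifest["sources"].append(entry)
        if self.ortholog_rows:
            orth_path = directory / "orthologs.tsv"
            with open(orth_path, "w", encoding="utf-8") as fh:
                fh.write("gene_a\tgene_b\tannotation\n")
                for a, b, annotation in self.ortholog_rows:
                    fh.write(f"{a}\t{b}\t{annotation}\n")
            manifest["ortholog_map"] = orth_path.name
            paths["ortholog_map"] = orth_path
        if self.id_map_rows:
            idmap_path = directory / "id_map.tsv"
            with open(idmap_path, "w", encoding="utf-8") as fh:
                for src, dst in self.id_map_rows:
                    fh.write(f"{src}\t{dst}\n")
            manifest["id_map"] = idmap_path.name
            paths["id_map"] = idmap_path
        if self.trait_rows:
            trait_path = directory / "trait_dictionary.tsv"
            with open(trait_path, "w", encoding="utf-8") as fh:
                for label, term in self.trait_rows:
                    fh.write(f"{label}\t{term}\n")
            manifest["trait_dictionary"] = trait_path.name
            paths["trait_dictionary"] = trait_path
        if self.tfbs_rows:
            tfbs_path = directory / "tfbs_hits.tsv"
            with open(tfbs_path, "w", encoding="utf-8") as fh:
                fh.write("gene_id\ttf_family\thit_count\n")
                for gene, family, count in self.tfbs_rows:
                    fh.write(f"{gene}\t{family}\t{count}\n")
            manifest["tfbs_hits"] = tfbs_path.name
            paths["tfbs_hits"] = tfbs_path
        manifest_path = directory / MANIFEST_NAME
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        paths["manifest"] = manifest_path
        return paths


def _write_gaf(path: Path, records: list[GafAnnotation]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        fh.write("!generated by kgxpress synthetic-data module\n")
        for r in records:
            taxon_cell = "taxon:" + r.taxon.split(":", 1)[1]
            cols = [
                "KGXSYN", r.gene_id, r.gene_symbol, r.qualifier, r.term_id,
                "KGXSYN:0000001", r.evidence_code, "", r.aspect, "", "",
                "gene", taxon_cell, "20230101", "KGXSYN", "", "",
            ]
            fh.write("\t".join(cols) + "\n")


# -- gene id surface conventions --------------------------------------------


def _gene_id(taxon_idx: int, i: int) -> str:
    if taxon_idx == 0:
        return f"AT{1 + i % 5}G{10000 + 10 * i:05d}"
    if taxon_idx == 1:
        return f"POPTR_{1 + i % 19:03d}G{100000 + 100 * i:06d}v3"
    if taxon_idx == 2:
        return f"Sobic.{1 + i % 10:03d}G{100000 + 100 * i:06d}"
    if taxon_idx == 3:
        return f"Zm00001eb{1000 + 10 * i:06d}"
    return f"LOC_Os{1 + i % 12:02d}g{10000 + 10 * i:05d}"


_GO_C = [f"GO:00050{i:02d}" for i in range(12)]
_GO_F = [f"GO:00030{i:02d}" for i in range(12)]
_GO_P = [f"GO:00080{i:02d}" for i in range(12)]
_PO_ANATOMY = [f"PO:00090{i:02d}" for i in range(8)]
_PO_STAGE = [f"PO:00010{i:02d}" for i in range(8)]
_TO_TRAITS = [f"TO:00002{i:02d}" for i in range(8)]

_ASPECT_POOLS = {
    "C": _GO_C, "F": _GO_F, "P": _GO_P, "A": _PO_ANATOMY, "G": _PO_STAGE, "T": _TO_TRAITS,
}


def _family_catalog(config: SyntheticConfig) -> tuple[list[str], list[str], list[str]]:
    ubiquitous = UBIQUITOUS_FAMILY_NAMES[: config.n_ubiquitous]
    absent = ABSENT_FAMILY_NAMES[: config.n_absent_families]
    n_informative = config.n_tf_families - len(ubiquitous) - len(absent)
    informative = list(_INFORMATIVE_FAMILY_NAMES[:n_informative])
    extra = n_informative - len(informative)
    informative += [f"TF-fam-{i:02d}" for i in range(extra)]
    return ubiquitous, absent, informative


# -- the generator -----------------------------------------------------------


def generate(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[SyntheticBundle, SyntheticTruth]:
    """Generate a complete input bundle plus its planted truth.

    With ``out_dir`` set the bundle (and ``truth.json``) is also written
    to disk; the same seed always produces byte-identical files. Config
    invariants are checked before anything is emitted.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = {
        t: [_gene_id(t, i) for i in range(config.genes_per_taxon)] for t in range(config.n_taxa)
    }

    # -- orthology between the first two taxa --------------------------------
    n_orth = int(config.ortholog_fraction * config.genes_per_taxon)
    idx_a = rng.choice(config.genes_per_taxon, size=n_orth, replace=False)
    idx_b = rng.permutation(rng.choice(config.genes_per_taxon, size=n_orth, replace=False))
    ortholog_pairs = sorted(
        (genes[0][int(ia)], genes[1][int(ib)]) for ia, ib in zip(idx_a, idx_b)
    )

    # -- planted responsive pairs --------------------------------------------
    n_planted = config.n_pairs_similar + config.n_pairs_contrasting
    chosen = rng.choice(len(ortholog_pairs), size=n_planted, replace=False)
    planted: list[PlantedPair] = []
    responsive: dict[str, str] = {}
    for rank, pair_idx in enumerate(sorted(int(c) for c in chosen)):
        a, b = ortholog_pairs[pair_idx]
        if rank < config.n_pairs_similar:
            direction = "increased" if rng.random() < 0.5 else "decreased"
            dir_a = dir_b = direction
        else:
            flip = rng.random() < 0.5
            dir_a, dir_b = ("increased", "decreased") if flip else ("decreased", "increased")
        planted.append(PlantedPair(a, b, dir_a, dir_b, classify_concordance(dir_a, dir_b)))
        responsive[a] = dir_a
        responsive[b] = dir_b

    # -- expression tables ----------------------------------------------------
    expression_rows: dict[str, list[tuple[str, float, float]]] = {}
    for t in range(config.n_taxa):
        taxon = _TAXA[t]
        rows: list[tuple[str, float, float]] = []
        for gene in genes[t]:
            direction = responsive.get(gene)
            if direction is not None:
                magnitude = abs(rng.normal(config.lfc_effect, config.lfc_effect_sd))
                lfc = magnitude if direction == "increased" else -magnitude
                p = rng.uniform(0.0, config.p_signal_max)
            else:
                lfc = rng.normal(0.0, config.lfc_null_sd)
                p = rng.uniform(0.0, 1.0)
            rows.append((gene, float(lfc), float(p)))
        expression_rows[taxon] = rows

    # -- GAF annotations ------------------------------------------------------
    aspects = list(_ASPECT_POOLS)
    gaf_records: dict[str, list[GafAnnotation]] = {}
    gaf_truth: dict[str, list[tuple[str, str]]] = {}
    for t in range(config.n_taxa):
        taxon = _TAXA[t]
        records: list[GafAnnotation] = []
        for gene in genes[t]:
            n_annotations = int(rng.integers(2, 6))
            for _ in range(n_annotations):
                aspect = aspects[int(rng.integers(0, len(aspects)))]
                pool = _ASPECT_POOLS[aspect]
                term = pool[int(rng.integers(0, len(pool)))]
                records.append(
                    GafAnnotation(
                        gene_id=gene, gene_symbol=gene.split("_")[-1],
                        qualifier="", term_id=term, taxon=taxon,
                        evidence_code="IEA", aspect=aspect,
                    )
                )
        # a gene annotated twice to one term collapses to one edge; keep the
        # multiset unique per (gene, term, aspect) to keep truth exact
        unique: dict[tuple[str, str, str], GafAnnotation] = {}
        for r in records:
            unique[(r.gene_id, r.term_id, r.aspect)] = r
        records = list(unique.values())
        gaf_records[taxon] = records
        gaf_truth[taxon] = sorted((r.gene_id, r.term_id) for r in records)

    # -- id map and trait dictionary ------------------------------------------
    all_genes = [g for t in range(config.n_taxa) for g in genes[t]]
    id_map: dict[str, str] = {}
    for i in range(config.n_idmap):
        target = all_genes[i % len(all_genes)]
        source = f"{target}.legacy{i // len(all_genes)}"
        id_map[source] = target
    id_map_rows = sorted(id_map.items())

    trait_rows = [(f"synthetic trait {i:02d}", f"TO:{900000 + i:07d}") for i in range(config.n_traits)]
    trait_queries: list[tuple[str, str | None]] = []
    for i in range(config.n_traits):
        label, term = trait_rows[i]
        jittered = label.upper() if i % 2 else f"  {label}  "
        trait_queries.append((jittered, term))
    for i in range(config.n_trait_misses):
        trait_queries.append((f"unknown trait {i:02d}", None))

    # -- TFBS profiles ---------------------------------------------------------
    ubiquitous, absent, informative = _family_catalog(config)
    pair_genes = sorted({g for p in planted for g in (p.gene_a, p.gene_b)})
    poplar_contrasting = sorted(
        p.gene_b for p in planted if p.concordance == "contrasting"
    )
    divergent_subset = poplar_contrasting[: config.n_divergent_subset]

    presence = _sample_profiles(
        rng, config, planted, pair_genes, informative, absent, divergent_subset
    )
    realized_phi: dict[str, float] = {}
    for p in planted:
        va = presence[p.gene_a]
        vb = presence[p.gene_b]
        realized_phi[f"{p.gene_a}|{p.gene_b}"] = _phi(va, vb)

    tfbs_rows: list[tuple[str, str, int]] = []
    informative_and_absent = informative + absent
    for gene in pair_genes:
        for family in ubiquitous:
            tfbs_rows.append((gene, family, int(rng.integers(1, 6))))
        vector = presence[gene]
        for j, family in enumerate(informative_and_absent):
            count = int(rng.integers(1, 6)) if vector[j] else 0
            tfbs_rows.append((gene, family, count))
    tfbs_rows.sort()

    bundle = SyntheticBundle(
        exposure=config.exposure,
        thresholds=(config.p_max, config.lfc_lower, config.lfc_upper),
        sources=[
            {"taxon": _TAXA[t], "experiment_id": f"E-SYNT-{t}"} for t in range(config.n_taxa)
        ],
        gaf_records=gaf_records,
        expression_rows=expression_rows,
        ortholog_rows=[(a, b, "") for a, b in ortholog_pairs],
        id_map_rows=id_map_rows,
        trait_rows=trait_rows,
        tfbs_rows=tfbs_rows,
    )
    truth = SyntheticTruth(
        pairs=planted,
        responsive=responsive,
        ortholog_pairs=ortholog_pairs,
        ubiquitous_families=sorted(ubiquitous),
        absent_families=sorted(absent),
        divergent_subset=divergent_subset,
        realized_phi=realized_phi,
        gaf_truth=gaf_truth,
        id_map=id_map,
        trait_queries=trait_queries,
    )
    verify_truth(bundle, truth)
    if out_dir is not None:
        paths = bundle.write(out_dir)
        truth_path = Path(out_dir) / "truth.json"
        with open(truth_path, "w", encoding="utf-8") as fh:
            fh.write(truth.to_json())
            fh.write("\n")
        paths["truth"] = truth_path
    return bundle, truth


def _phi(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a.astype(float), b.astype(float))[0, 1])


def _sample_profiles(
    rng: np.random.Generator,
    config: SyntheticConfig,
    planted: list[PlantedPair],
    pair_genes: list[str],
    informative: list[str],
    absent: list[str],
    divergent_subset: list[str],
) -> dict[str, np.ndarray]:
    """Binary profiles over informative + absent families for pair genes.

    Pair members share correlated Gaussian latents on the informative
    columns; the latent correlation is ``sin(pi * rho / 2)`` so the binary
    (phi) correlation targets the configured rho under median
    thresholding. Small deterministic repairs afterwards pin the exact
    planted structure: no informative family may be ubiquitous or absent
    from the whole divergent subset, and every subset-absent family must
    occur outside the subset.
    """
    n_inf = len(informative)
    n_abs = len(absent)
    n_cols = n_inf + n_abs
    subset = set(divergent_subset)
    profiles: dict[str, np.ndarray] = {}
    for p in planted:
        rho_target = (
            config.profile_rho_similar
            if p.concordance == "similar"
            else config.profile_rho_contrasting
        )
        # phi of median-thresholded binaries is (2/pi)*arcsin(latent r),
        # so invert to hit the target on the binary scale
        latent_r = math.sin(math.pi * rho_target / 2.0)
        z_a = rng.standard_normal(n_cols)
        shared = rng.standard_normal(n_cols)
        z_b = latent_r * z_a + math.sqrt(max(0.0, 1.0 - latent_r**2)) * shared
        profiles[p.gene_a] = (z_a > 0).astype(np.int8)
        profiles[p.gene_b] = (z_b > 0).astype(np.int8)

    gene_order = list(pair_genes)
    non_subset = [g for g in gene_order if g not in subset]
    subset_order = [g for g in gene_order if g in subset]

    # subset-absent columns: force zero inside the divergent subset
    for g in subset_order:
        profiles[g][n_inf:] = 0

    # repair pass over informative columns: none may be ubiquitous, and the
    # divergent subset must not be void of any (else it is falsely detected
    # as subset-absent)
    for j in range(n_inf):
        if all(profiles[g][j] for g in gene_order):
            profiles[non_subset[j % len(non_subset)]][j] = 0
        if subset_order and not any(profiles[g][j] for g in subset_order):
            profiles[subset_order[j % len(subset_order)]][j] = 1
            if all(profiles[g][j] for g in gene_order):
                profiles[non_subset[j % len(non_subset)]][j] = 0
    # subset-absent columns must occur in at least one non-subset gene
    for j in range(n_inf, n_cols):
        if not any(profiles[g][j] for g in non_subset):
            profiles[non_subset[j % len(non_subset)]][j] = 1
    return profiles


def verify_truth(bundle: SyntheticBundle, truth: SyntheticTruth) -> None:
    """Self-check: re-derive the planted structure from the emitted tables.

    Raises if any emitted value contradicts the truth manifest: responsive
    genes must pass the expression filter with the planted sign, and the
    TFBS table must reproduce the ubiquitous set, the subset-absent set,
    and the recorded per-pair correlations.
    """
    p_max, lfc_lower, lfc_upper = bundle.thresholds
    emitted = {g: (lfc, p) for rows in bundle.expression_rows.values() for g, lfc, p in rows}
    for gene, direction in truth.responsive.items():
        lfc, p = emitted[gene]
        passes = p < p_max and (lfc < lfc_lower or lfc > lfc_upper)
        sign_ok = (lfc > 0) == (direction == "increased")
        if not (passes and sign_ok):
            raise ConfigError(
                f"planted responsive gene {gene} inconsistent with emitted table "
                f"(lfc={lfc}, p={p}, direction={direction})"
            )
    if bundle.tfbs_rows:
        matrix = build_tfbs_matrix(bundle.tfbs_rows)
        reduced, removed = drop_ubiquitous_families(matrix)
        if removed != truth.ubiquitous_families:
            raise ConfigError(f"ubiquitous families drifted: {removed}")
        if truth.divergent_subset:
            found = find_absent_families(reduced, truth.divergent_subset)
            if found != truth.absent_families:
                raise ConfigError(f"subset-absent families drifted: {found}")
        gene_index = {g: i for i, g in enumerate(reduced.genes)}
        for key, expected in truth.realized_phi.items():
            a, b = key.split("|")
            observed = _phi(reduced.values[gene_index[a]], reduced.values[gene_index[b]])
            if abs(observed - expected) > 1e-9:
                raise ConfigError(f"profile correlation for {key} drifted")


def bundle_digest(directory: str | Path) -> dict[str, str]:
    """SHA-256 of every file in a bundle directory (determinism checks)."""
    directory = Path(directory)
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(directory.iterdir())
        if p.is_file()
    }


# -- the printed-table bundle -------------------------------------------------


def table3_bundle(out_dir: str | Path | None = None) -> SyntheticBundle:
    """Minimal bundle encoding the 16 printed drought pair rows.

    Expression directions are realized as synthetic log2 fold changes of
    +/-2 at p=0.001, so the filter retains every gene with the printed
    direction; the duplicated pair appears as two ortholog-map rows with
    distinct annotation text and therefore two property-distinct edges.
    """
    rows = load_table3_fixture()
    directions: dict[str, tuple[str, str]] = {}  # gene -> (taxon, direction)
    ortholog_rows: list[tuple[str, str, str]] = []
    for row in rows:
        directions[row.gene_a] = (row.taxon_a, row.direction_a)
        directions[row.gene_b] = (row.taxon_b, row.direction_b)
        annotation = "; ".join(v for _, v in row.evidence)
        ortholog_rows.append((row.gene_a, row.gene_b, annotation))

    expression_rows: dict[str, list[tuple[str, float, float]]] = {
        ARABIDOPSIS_TAXON: [],
        POPLAR_TAXON: [],
    }
    for gene in sorted(directions):
        taxon, direction = directions[gene]
        lfc = 2.0 if direction == "increased" else -2.0
        expression_rows[taxon].append((gene, lfc, 0.001))

    bundle = SyntheticBundle(
        exposure=DROUGHT_EXPOSURE,
        thresholds=(0.05, -1.0, 1.0),
        sources=[
            {"taxon": ARABIDOPSIS_TAXON, "experiment_id": "E-SYNT-AT-DROUGHT"},
            {"taxon": POPLAR_TAXON, "experiment_id": "E-SYNT-PT-DROUGHT"},
        ],
        expression_rows=expression_rows,
        ortholog_rows=ortholog_rows,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
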