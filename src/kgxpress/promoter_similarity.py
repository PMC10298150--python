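"""Promoter TFBS-profile similarity: matrices, PCA, clustering, group tests.

Each gene's promoter (the 5' upstream cis-regulatory region) is summarized
as a binary presence profile over transcription-factor binding-site (TFBS)
families. Profile similarity between genes is Pearson correlation on the
binary vectors (the phi coefficient). The analyses: remove families present
in every gene (they carry no signal), project genes with a principal
component analysis that tolerates missing entries (SVD with iterative
imputation), cluster genes with one-minus-Pearson distance under complete
linkage, and compare per-pair profile correlations between similarly and
contrastingly expressed homolog pairs with a rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

from .errors import KgXpressError
from .kg_query import HomologExpressionPair


@dataclass
class TFBSMatrix:
    """Genes x TF-family binary presence matrix with optional labels.

    Rows (genes) and columns (families) are sorted lexicographically at
    construction so downstream numerics are deterministic.
    """

    genes: list[str]
    families: list[str]
    values: np.ndarray  # shape (n_genes, n_families), entries in {0, 1}
    taxa: dict[str, str] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.genes), len(self.families)):
            raise ValueError("matrix shape does not match gene/family labels")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0 or 1")
        if len(set(self.genes)) != len(self.genes) or len(set(self.families)) != len(self.families):
            raise ValueError("gene and family labels must be unique")

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]


def build_tfbs_matrix(
    hits: Iterable[tuple[str, str, int]],
    family_map: Mapping[str, str] | None = None,
    taxa: Mapping[str, str] | None = None,
    groups: Mapping[str, str] | None = None,
) -> TFBSMatrix:
    """Aggregate a (gene, motif-or-family, count) hit table into presences.

    ``family_map`` optionally collapses motif names to family names before
    aggregation; counts for one (gene, family) cell sum, and presence is
    count > 0. Hit counts must be nonnegative.
    """
    totals: dict[tuple[str, str], int] = {}
    for gene, raw_family, count in hits:
        count = int(count)
        if count < 0:
            raise ValueError(f"negative hit count for ({gene!r}, {raw_family!r})")
        family = family_map.get(raw_family, raw_family) if family_map else raw_family
        totals[(gene, family)] = totals.get((gene, family), 0) + count
    if not totals:
        raise ValueError("empty TFBS hit table")
    genes = sorted({g for g, _ in totals})
    families = sorted({f for _, f in totals})
    values = np.zeros((len(genes), len(families)), dtype=np.int8)
    gi = {g: i for i, g in enumerate(genes)}
    fi = {f: i for i, f in enumerate(families)}
    for (g, f), total in totals.items():
        values[gi[g], fi[f]] = 1 if total > 0 else 0
    return TFBSMatrix(
        genes=genes,
        families=families,
        values=values,
        taxa={g: taxa[g] for g in genes if g in taxa} if taxa else {},
        groups={g: groups[g] for g in genes if g in groups} if groups else {},
    )


def drop_ubiquitous_families(matrix: TFBSMatrix) -> tuple[TFBSMatrix, list[str]]:
    """Remove families present in every gene; returns (reduced, removed).

    Ubiquitous families are constant columns — they cannot discriminate
    genes and would distort correlation-based analyses. If every family is
    ubiquitous there is nothing left to analyze, which is an error.
    """
    ubiquitous = matrix.values.all(axis=0)
    removed = sorted(np.array(matrix.families)[ubiquitous].tolist())
    if ubiquitous.all():
        raise KgXpressError("no discriminating families: every family is present in every gene")
    keep = ~ubiquitous
    reduced = TFBSMatrix(
        genes=list(matrix.genes),
        families=[f for f, k in zip(matrix.families, keep) if k],
        values=matrix.values[:, keep],
        taxa=dict(matrix.taxa),
        groups=dict(matrix.groups),
    )
    return reduced, removed


# -- PCA (SVD with iterative imputation) ------------------------------------


class PCAResult(NamedTuple):
    coordinates: np.ndarray  # (n_genes, n_components) scores
    variance_fractions: np.ndarray  # per-component sigma_k^2 / sum sigma^2
    n_iterations: int


def pca(
    values: np.ndarray | TFBSMatrix,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> PCAResult:
    """Principal components by SVD on column-centered, unscaled rows.

    Missing entries (NaN) are handled by iterative low-rank imputation:
    fill with column means, decompose, re-impute the missing cells from
    the rank-``n_components`` reconstruction, and repeat until the imputed
    values move less than ``tol``. On complete data the loop is a no-op
    and the result equals a plain SVD. Variance fractions are
    sigma_k^2 / sum_j sigma_j^2 of the final decomposition.
    """
    X = values.values.astype(float) if isinstance(values, TFBSMatrix) else np.array(values, dtype=float)
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValueError(f"need at least 2 genes and 2 families, got {n}x{m}")
    n_components = min(n_components, n, m)
    missing = np.isnan(X)
    if missing.any(axis=0).any():
        col_means = np.nanmean(X, axis=0)
        if np.isnan(col_means).any():
            raise ValueError("a column is entirely missing; cannot impute")
        X = np.where(missing, col_means[None, :], X)

    iterations = 0
    while True:
        centered = X - X.mean(axis=0, keepdims=True)
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        if not missing.any():
            break
        rank = n_components
        reconstruction = (U[:, :rank] * s[:rank]) @ Vt[:rank] + X.mean(axis=0, keepdims=True)
        delta = np.max(np.abs(reconstruction[missing] - X[missing])) if missing.any() else 0.0
        X = np.where(missing, reconstruction, X)
        iterations += 1
        if delta < tol or iterations >= max_iter:
            centered = X - X.mean(axis=0, keepdims=True)
            U, s, Vt = np.linalg.svd(centered, full_matrices=False)
            break

    total = float(np.sum(s**2))
    if total <= 0:
        raise ValueError("zero total variance: all rows identical after centering")
    scores = U[:, :n_components] * s[:n_components]
    fractions = (s[:n_components] ** 2) / total
    # deterministic sign: largest-magnitude loading of each component positive
    for k in range(n_components):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            scores[:, k] = -scores[:, k]
    return PCAResult(coordinates=scores, variance_fractions=fractions, n_iterations=iterations)


# -- correlation and clustering ---------------------------------------------


def _check_variance(values: np.ndarray, genes: Sequence[str]) -> None:
    constant = values.std(axis=1) == 0
    if constant.any():
        names = [g for g, c in zip(genes, constant) if c]
        raise KgXpressError(
            f"zero-variance profile(s); Pearson correlation undefined for gene(s): {names}"
        )


def correlation_matrix(matrix: TFBSMatrix) -> np.ndarray:
    """Gene x gene Pearson correlation of binary profiles (phi coefficient)."""
    values = matrix.values.astype(float)
    _check_variance(values, matrix.genes)
    corr = np.corrcoef(values)
    np.fill_diagonal(corr, 1.0)
    return corr


class LinkageResult(NamedTuple):
    linkage: np.ndarray  # scipy linkage matrix
    genes: list[str]


def hierarchical_cluster(matrix: TFBSMatrix) -> LinkageResult:
    """Complete-linkage agglomeration on one-minus-Pearson distances.

    Genes are in lexicographic order, so equal-distance merges resolve to
    the lexicographically smallest pair (scipy breaks ties by index).
    """
    corr = correlation_matrix(matrix)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    return LinkageResult(linkage=Z, genes=list(matrix.genes))


def cut_clusters(result: LinkageResult, k: int) -> dict[str, int]:
    """Flat cluster labels (1..k) from cutting the tree into k groups."""
    labels = hierarchy.fcluster(result.linkage, t=k, criterion="maxclust")
    return dict(zip(result.genes, labels.tolist()))


def linkage_to_newick(result: LinkageResult) -> str:
    """Serialize the dendrogram as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(result.linkage)

    def walk(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{result.genes[node.id]}:{length:.6f}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return walk(tree, tree.dist) + ";"


# -- homolog-pair group comparison ------------------------------------------


@dataclass
class PairGroupSummary:
    """Per-pair profile correlations and the similar-vs-contrasting contrast."""

    per_pair: list[tuple[str, str, str, float]]  # (gene_a, gene_b, concordance, phi)
    group_means: dict[str, float]
    mannwhitney_u: float | None
    mannwhitney_p: float | None
    group_submatrices: dict[str, tuple[list[str], np.ndarray]]
    skipped_pairs: list[tuple[str, str, str]]  # (gene_a, gene_b, reason)


def pair_group_similarity(
    matrix: TFBSMatrix, pairs: Sequence[HomologExpressionPair]
) -> PairGroupSummary:
    """Compare promoter-profile similarity between concordance groups.

    For each homolog pair, computes the Pearson correlation of the two
    genes' TFBS profiles, then summarizes the similar-pair and
    contrasting-pair correlation sets by their means and a Mann-Whitney
    rank test. Pairs with a gene missing from the matrix are reported and
    skipped; full per-group gene x gene correlation sub-matrices are
    emitted for heatmap rendering.
    """
    per_pair: list[tuple[str, str, str, float]] = []
    skipped: list[tuple[str, str, str]] = []
    group_values: dict[str, list[float]] = {"similar": [], "contrasting": []}
    group_genes: dict[str, set[str]] = {"similar": set(), "contrasting": set()}
    gene_index = {g: i for i, g in enumerate(matrix.genes)}
    values = matrix.values.astype(float)
    for pair in pairs:
        missing = [g for g in pair.genes if g not in gene_index]
        if missing:
            skipped.append((pair.gene_a, pair.gene_b, f"missing from matrix: {missing}"))
            continue
        a, b = values[gene_index[pair.gene_a]], values[gene_index[pair.gene_b]]
        if a.std() == 0 or b.std() == 0:
            skipped.append((pair.gene_a, pair.gene_b, "zero-variance profile"))
            continue
        phi = float(np.corrcoef(a, b)[0, 1])
        per_pair.append((pair.gene_a, pair.gene_b, pair.concordance, phi))
        group_values[pair.concordance].append(phi)
        group_genes[pair.concordance].update(pair.genes)
    group_means = {
        name: float(np.mean(vals)) for name, vals in group_values.items() if vals
    }
    u_stat = p_val = None
    if group_values["similar"] and group_values["contrasting"]:
        u_stat_, p_val_ = mannwhitneyu(
            group_values["similar"], group_values["contrasting"], alternative="two-sided"
        )
        u_stat, p_val = float(u_stat_), float(p_val_)
    submatrices: dict[str, tuple[list[str], np.ndarray]] = {}
    for name, members in group_genes.items():
        if len(members) < 2:
            continue
        ordered = sorted(members)
        idx = [gene_index[g] for g in ordered]
        sub = values[idx]
        _check_variance(sub, ordered)
        submatrices[name] = (ordered, np.corrcoef(sub))
    return PairGroupSummary(
        per_pair=per_pair,
        group_means=group_means,
        mannwhitney_u=u_stat,
        mannwhitney_p=p_val,
        group_submatrices=submatrices,
        skipped_pairs=skipped,
    )


def find_absent_families(matrix: TFBSMatrix, subset: Sequence[str]) -> list[str]:
    """Families absent from every subset gene but present somewhere outside.

    Used to explain why a gene subset separates in ordination space: the
    returned families are exactly those whose loss is specific to the
    subset (families absent everywhere are uninformative and excluded).
    """
    subset_set = set(subset)
    if not subset_set:
        raise ValueError("subset must be nonempty")
    unknown = subset_set - set(matrix.genes)
    if unknown:
        raise ValueError(f"subset gene(s) not in matrix: {sorted(unknown)}")
    if subset_set == set(matrix.genes):
        raise ValueError("subset must be strictly smaller than the gene set")
    in_subset = np.array([g in subset_set for g in matrix.genes])
    absent_inside = ~matrix.values[in_subset].any(axis=0)
    present_outside = matrix.values[~in_subset].any(axis=0)
    mask = absent_inside & present_outside
    return sorted(np.array(matrix.families)[mask].tolist())
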