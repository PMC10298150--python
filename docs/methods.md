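# Methods

This note documents the models and procedures `kgxpress` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Semantic model

The graph uses a closed vocabulary: ten node categories (anatomical entity,
life stage, phenotypic feature, genomic entity, environmental exposure,
organismal entity, organism taxon, cellular component, molecular function,
biological process) and nine predicates (`in taxon`, `active in`,
`regulates`, `enables`, `expressed in`, `has phenotype`, `orthologous to`,
`increases expression of`, `decreases expression of`), each predicate
restricted to specific (subject category, object category) combinations.
`validate()` reports every violation rather than raising on the first; the
vocabularies are deliberately closed — an unknown predicate is a modeling
error, not an extension point.

GAF aspect codes route annotation edges: the GO aspects `C`/`F`/`P` map to
`active in`/`enables`/`regulates`, and the extension aspects `A` (plant
anatomy), `G` (growth stage), and `T` (trait) map to `expressed in`
(anatomical entity), `expressed in` (life stage), and `has phenotype`.
The extension codes are this package's GAF dialect; annotation sources
using other codes are surfaced as record-level errors with counts.

Orthology is symmetric but stored once, with the lexicographically smaller
gene id as subject. The query layer matches the edge in either direction,
so results are invariant to the stored orientation. Two assertions of the
same pair with different edge properties (e.g. two annotation records)
remain distinct edges: merge deduplication keys on
(subject, predicate, object, canonicalized properties), where
canonicalization sorts keys and normalizes numeric strings ("2.50" ≡
"2.5") but leaves stored values verbatim. Provenance (`provided_by`) is
excluded from the key; duplicate assertions from different sources collapse
to one edge with pipe-joined provenance tags.

## Expression filter

A record is retained when `p < p_max` and
`log2FC < lfc_lower or log2FC > lfc_upper`, with defaults
`p_max = 0.05`, `lfc_lower = −1`, `lfc_upper = 1` (log2 fold change
against the experiment's baseline). All three comparisons are strict, so
boundary rows are excluded. The p-value column is used as supplied — no
multiple-testing correction is added; whether upstream tables report raw or
adjusted p-values is the data provider's contract, and the reader leaves
the column's interpretation to the caller. Direction is the sign of the
retained fold change (necessarily nonzero given the band).

## Homolog-pair query

The query finds every unordered gene pair (g, h) such that the exposure has
an expression edge to both and g is orthologous to h. Directions are read
from the matched edge predicates. A gene carrying both an increase and a
decrease edge under one exposure (different experiments) contributes one
result row per direction combination, each tagged with its supporting
experiment ids — an information-preserving choice over collapsing or
erroring. With `dedup=False`, each orthology edge (i.e. each distinct
assertion of the pair) yields its own row; with `dedup=True`, rows collapse
on (exposure, canonical pair, direction combination). `cross_taxon_only`
restricts results to pairs whose genes carry `in taxon` edges to different
taxa; it defaults off in the raw query (the graph pattern itself does not
constrain taxa) and is switched on for the cross-species analyses.

`brute_force_pairs` re-derives the same result by exhaustively scanning
edge triples with no shared indexing code; tests assert set equality
between the two routes across seeded synthetic graphs.

### The printed drought pair table

The packaged fixture reproduces the 16 printed A. thaliana × P. trichocarpa
drought pair rows, including one pair printed twice with different
functional annotations. In the corresponding input bundle
(`table3_bundle()`) that duplicate is encoded as two ortholog-map rows with
distinct annotation properties, which survive merge deduplication as two
edges; the non-deduplicated query therefore returns 16 rows and
deduplication returns 15 unique pairs. By the printed direction arrows the
rows split 7 similar / 9 contrasting (6/9 after dedup), and every similar
row is decreased/decreased. Expression directions are realized as synthetic
log2 fold changes of ±2 at p = 0.001 — values chosen only to clear the
filter thresholds decisively; the printed table records directions, not
magnitudes.

## Promoter TFBS similarity

Promoters are summarized as binary presence vectors over TFBS families
(hit count > 0), aggregated from motif-level hits through an optional
motif→family map. Presence rather than counts is the primary
representation; counts are retained in the hit table for sensitivity
analyses.

- **Ubiquitous-family removal** drops exactly the families present in every
  gene (constant columns carry no signal and inflate binary correlations);
  the operation is idempotent and errors when nothing would remain.
- **PCA** centers columns, applies no row scaling, and decomposes by SVD.
  Missing entries are imputed iteratively: fill with column means,
  decompose, replace missing cells from the rank-k reconstruction, repeat
  until the imputed values move < `tol` (default 1e-6, max 100 iterations).
  On complete data the loop is a no-op and the result equals plain SVD
  (cross-checked against scikit-learn in tests). Variance fractions are
  σ_k²/Σσ². Component signs are fixed by making each component's
  largest-magnitude loading positive. Column centering before SVD is
  assumed (the convention of the ordination tools this emulates).
- **Hierarchical clustering** uses distance 1 − Pearson(row_i, row_j) and
  complete linkage. Genes are sorted lexicographically, and scipy's linkage
  breaks equal-distance ties by index, so merges are deterministic with the
  lexicographically smallest pair first. A zero-variance profile makes the
  correlation undefined and is an error naming the gene, never a silent
  drop. The dendrogram exports as Newick text.
- **Pair-group comparison** computes each homolog pair's profile
  correlation (phi), the group means for similar vs. contrasting pairs, a
  two-sided Mann–Whitney rank test between the two correlation sets, and
  per-group gene×gene correlation sub-matrices for heatmap rendering.
- **Subset-absent family detection** returns families absent from every
  gene of a given subset but present in at least one gene outside it —
  the families whose specific loss explains a subset separating in
  ordination space.

## Synthetic-data generator

The generator emits a complete offline input bundle — per-taxon GAF files,
per-taxon differential-expression TSVs under a configured exposure CURIE,
an ortholog map, a gene-id legacy map, a trait dictionary, and a TFBS hit
table — plus a truth manifest, with byte-identical output under a fixed
seed. Gene ids follow real surface conventions (AT#G#####,
POPTR_###G######v3, Sobic., Zm00001eb, LOC_Os) so id-normalization paths
are exercised realistically.

Default conditions mirror the worked drought analysis: 2 taxa × 60 genes,
half with cross-taxon orthologs; 8 similar + 8 contrasting responsive
pairs; responsive |log2FC| ~ Normal(2.5, 0.3) with p ~ Uniform(0, 0.01);
null log2FC ~ Normal(0, 0.4) with p ~ Uniform(0, 1); 60 TF families of
which 12 are ubiquitous and 11 are specifically absent from a divergent
subset of 7 Populus genes drawn from contrasting pairs. Under these
settings essentially all planted responsive genes pass the filter and
roughly 0.1% of null genes do (the band at |log2FC| > 1 is the binding
constraint for Normal(0, 0.4) nulls).

Pair-correlated binary profiles are drawn by thresholding correlated
Gaussian latents at the median with latent correlation
r = sin(π·ρ/2), so the expected binary (phi) correlation equals the target
ρ (0.8 similar, 0.0 contrasting) by the arcsine identity. The realized
per-pair phi of the emitted profiles is recorded in the truth manifest
rather than assumed equal to the target, keeping recovery tests honest.
Small deterministic repair passes pin the exact planted combinatorics —
no informative family may be ubiquitous by chance, none may be absent from
the entire divergent subset, and every subset-absent family must occur
outside the subset; without them, chance events (~0.5⁷ per family) would
blur the exact 12- and 11-family recoveries. A self-check pass re-derives
the planted structure from the emitted tables on every generate call.

What the generator does **not** emulate: read-level data, real promoter
sequences or motif content, linkage between annotation terms and
expression, realistic p-value/effect-size joint distributions, one-to-many
orthology, or assembly-version chaos beyond a simple legacy-id map. Passing
recovery tests therefore demonstrate the pipeline's correctness on data
with the assumed statistical structure, not robustness to the full
messiness of real annotation releases.

## Problem sizes

Tests and the acceptance script run on bundles of ~120 genes and graphs of
~600 edges (well under the scale the semantics require), with 50–100 seeded
replicates for oracle-equivalence and recovery checks; these sizes give
stable estimates for every quantity reported while keeping the whole suite
fast. The full-scale graph the semantic model supports (10⁵–10⁶ edges)
exercises no additional code paths.

## Known limitations

- The in-memory query supports exactly one motif (exposure → homolog pair);
  it is not a graph-query language. The Cypher export exists for users who
  need richer queries in a graph database.
- `merge` holds all graphs in memory; no streaming/out-of-core path.
- Trait-label lookup is exact after case/whitespace normalization — no
  fuzzy matching or synonym expansion.
- The binary-profile representation discards hit-count magnitude; the phi
  coefficient saturates for very sparse or very dense profiles.
- KGX edge properties with legitimately empty string values do not survive
  a write/read round-trip (empty cells read as absent).
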