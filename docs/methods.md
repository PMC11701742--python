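# Methods

## Scope and data model

`idranno` operates on four kinds of objects: an ontology (a DAG of GO/IDPO
terms connected by `is_a` edges, partitioned into the namespaces
molecular_function, biological_process, cellular_component and
disorder_function); sequence regions (1-based inclusive intervals on a
protein, the UniProt/DisProt convention, at every interface); region
embeddings (the arithmetic mean of the per-residue vectors of a protein
language model over the region, dimension D — 1024 for ProtT5-class
models, 16 in the default test fixtures); and per-residue ternary tracks
(annotated / not annotated / no coverage). Language-model inference and the
ν predictor are deliberately outside the package: embedding matrices and ν
values are read from files, and a pluggable embedder interface (with a
deterministic mock implementation for tests) marks where a real model would
plug in.

## Ontology handling

Only `is_a` edges define the hierarchy; `part_of` and other relations are
ignored, matching the usual convention for Molecular Function evaluation.
Obsolete terms are dropped (with a logged warning) and `alt_id`s resolve to
their primary term. The true-path rule closes an annotation set over all
ancestors; namespace root terms are removed from propagated sets because
membership in the namespace carries no information — note that GO:0005488
"binding" is *not* a root and is retained. `enforce_hierarchy` replaces each
term's score by the maximum over itself and its scored descendants, which
makes score maps monotone along parent edges and is idempotent. Cycles and
dangling parents are hard errors naming an offending edge or term.

## Weighted-KNN term transfer

For a query region embedding q and reference entries r_i:

1. d_i = cosine distance(q, r_i), computed in double precision;
2. entries with d_i > c (cutoff, default 0.8) are discarded — the
   comparison is an exact `<=` on the computed double, no epsilon;
3. the K nearest survivors are kept, ties at the K-th distance broken by
   the index's stable (accession, start, end) ordering;
4. raw weights w_i = 1 − d_i/c; normalised weights ŵ_i = w_i / Σ w_j;
5. score(term) = Σ ŵ_i · 1[term ∈ terms_i] — a convex combination, so all
   scores lie in [0, 1];
6. scores are hierarchy-enforced, then thresholded per namespace, and the
   broad binding terms face their stricter per-term threshold *after*
   hierarchy enforcement (so their specific descendants keep the namespace
   threshold).

Design choices where the published description leaves room: the mapping
from cutoff-bounded distances to weights is the linear form w = 1 − d/c
(any monotone-decreasing alternative can be swapped behind one function);
reference term sets are true-path propagated at index build by default
(CAFA-style gold sets are propagated; exposed as a flag); fewer than K
survivors simply all vote; if every survivor sits exactly at the cutoff all
raw weights are zero and the query gets an empty prediction with a logged
warning rather than a division by zero. Biological Process and Cellular
Component terms are refused by `transfer` unless an explicit override is
passed — those namespaces are imported from curation, not predicted.
Search is exact (reference sets are small); no approximate indexing.

Defaults follow the optimised operating point: K=10, τ=0.44 for Molecular
Function; K=5, τ=0.59 for Disorder Function; cutoff 0.8; strict threshold
0.9 on GO:0005488 and GO:0005515.

## f-max evaluation

Evaluation is at the region level. For each threshold t in a grid (default
0.00–1.00, step 0.01): precision(t) is the mean, over regions with at least
one prediction scoring ≥ t, of |predicted ∩ gold| / |predicted|; recall(t)
is the mean over *all* gold regions of |predicted ∩ gold| / |gold|, so a
region with no surviving prediction contributes zero recall; f-max is the
maximum harmonic mean over the grid, and the reported optimal threshold is
the smallest t attaining it. Namespaces are evaluated separately. Region
matching between predictions and gold uses exact (accession, start, end)
keys; a prediction on a region absent from the gold set is a hard error. A
separate utility maps predicted regions onto gold regions by interval
Jaccard (default threshold 0.5) for workflows whose region boundaries do
not match exactly — this mapping rule is a toolkit choice, not a published
one. Grid search runs one transfer pass per candidate K with the score
threshold disabled and sweeps τ on the resulting scores; ties break toward
smaller K then smaller τ (simpler models preferred). The template's strict
binding-term filter stays active during the sweep, since it is a separate
mechanism from τ.

## Consensus tracks

Per residue, with a = number of sources calling it annotated and v = number
of sources covering it: `merge` annotates when a ≥ 1; `majority` when v > 0
and a/v ≥ 0.5; `strict` the same with 0.9. Residues covered by no source
stay no-coverage. The denominator counts covering sources by default —
predictors and structure-derived tracks have very different coverage, and
counting absence as a negative vote would conflate missingness with
disagreement — with `denominator="all"` available to divide by the track
count instead. An optional minimum region length (default 1, i.e. no
erasure) removes short annotated runs after thresholding; no morphological
smoothing is applied. These rules guarantee strict ⊆ majority ⊆ merge as
residue sets. Content statistics report, per feature, the annotated-residue
fraction over the total length of proteins carrying at least one annotated
residue for that feature (proteins with none are excluded from the
denominator, and reported separately as a count).

## Compaction labels

A region of at least 30 residues is `compact` when ν ≤ 0.475 and `expanded`
when ν > 0.55; the band between is unlabeled, as is any shorter region.
Boundary semantics are read literally from the inequalities: ν = 0.475 is
compact, ν = 0.55 is unlabeled. The length gate is measured on the input
region as given. ν values outside (0, 1) are errors; values outside
[0.3, 0.8] are accepted with a warning. The per-protein summary reports the
fraction of distinct proteins with at least one compact and at least one
expanded region.

## Synthetic fixtures

The generators emulate the statistical shape of the real inputs, not their
content. Ontologies are complete trees (default depth 4, branching 3 → 40
terms per namespace) plus random cross-links to strictly shallower levels,
so acyclicity holds by construction. Embedding fixtures plant one leaf term
per cluster (paired across the two transfer namespaces so one geometry
serves both): cluster centres are random directions scaled to
`cluster_separation × noise_sd` from the origin (default separation 10,
noise 1), members add isotropic Gaussian noise, and ground truth is the
planted leaf plus its true-path closure. Defaults — 20 clusters, 600
reference regions, 200 queries, dimension 16 — keep the suite fast while
matching the scale of a curated disorder-function reference set; a smoke
test exercises D=1024. Vote tracks copy a hidden binary truth per residue
with probability `agreement` (default 0.9) and mask coverage at rate 0.1,
so majority-vote recovery has a closed binomial form to check against. ν
values come from a three-component Gaussian mixture at means 0.42 / 0.50 /
0.60 with weights 0.02 / 0.53 / 0.45 — the component weights mirror the
proteome-scale compact and expanded protein fractions — and component sd
0.01, chosen so that each component's mass stays essentially within its
label band (the middle component leaks < 1% across the 0.475 threshold);
region lengths are drawn from 30–150 by default, and the sub-30 length gate
is exercised by passing a shorter range.

What the fixtures do **not** emulate: real ProtT5 embedding geometry
(anisotropy, norm structure, sequence-length effects), the heavy-tailed
term-frequency imbalance of curated databases, correlated errors between
disorder predictors, or curation noise. Passing the recovery tests
therefore shows the machinery is correct and well-calibrated on separable
data — not that the published accuracy transfers to real proteins.

## Numerical and formatting conventions

All distances and scores are float64. TSV outputs use fixed 6-decimal score
formatting and LF line endings; embedding TSVs write `repr` doubles and are
read back with round-trip float parsing, so file round-trips are bit-exact.
All randomness in the generators flows from a single seed through named
`SeedSequence` substreams, making the full pipeline bit-identical across
reruns and platforms; the pipeline writes a manifest with SHA-256 checksums
of its inputs and a config snapshot that reproduces the run.

## Problem sizes used in the checks

The oracle comparisons run on 200 random KNN instances (≤ 50 references,
D ≤ 8) and 100 random evaluation instances (≤ 10 regions, ≤ 8 terms, grid
step 0.1); consensus rules are verified exhaustively per residue for all
ternary columns of up to 4 tracks (the rule is per-residue, so this is
exact); recovery and determinism checks use the default fixture sizes
above. These sizes were chosen to make the whole suite run in seconds on a
single CPU while leaving the checked properties exact.

## Known limitations

- The transfer quality on real data depends entirely on the supplied
  embeddings; the package validates shapes and finiteness but cannot detect
  a semantically wrong embedding file.
- Exact nearest-neighbour search scales linearly in the reference-set size;
  it is intended for curated reference sets (10²–10⁴ regions).
- The evaluator requires exact region keys; the Jaccard mapper is a
  convenience, and its threshold materially affects results on boundary-
  mismatched data.
- Consensus modes treat sources as exchangeable; no per-source reliability
  weighting is implemented.
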