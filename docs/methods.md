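# Methods

This note documents the models and procedures implemented in `harmonet`,
the parameters that matter, the numerical choices made where the design
was open, and what the synthetic fixtures do and do not demonstrate.

## The association-matrix abstraction

Every dataset is reduced to a genes × attributes grid whose entries
quantify evidence that a gene is associated with a biological entity
(tissue, disease, pathway, phenotype, chemical, …). The abstraction
deliberately discards source-specific detail — binding-site positions,
phosphosite residues, SNP coordinates — because comparability across
dozens of sources requires a common schema. Unobserved pairs are `NaN`
internally and materialize as 0 ("no observed association") on export; a
matrix's `value_kind` tracks where it stands in the pipeline
(raw → standardized → thresholded).

## ECDF standardization

Observed values are replaced by right-continuous empirical cumulative
probabilities, p(v) = #{x ≤ v}/n. This definition was chosen over the
alternative #{x < v}/n because it guarantees that the maximum observed
score is exactly 1 and is the standard ECDF; under ties every tied value
receives the shared upper count (pool [1,1,2] → [2/3, 2/3, 1]).

*Pooling.* The counting pool is the whole matrix unless the per-gene
medians differ, in which case each gene's row is its own pool. "Differ" is
operationalized as a relative spread above `median_tolerance`
(default 1e−9, configurable): exact float equality would be brittle, and
nothing stronger is implied by the rule. Rows with no observed values are
excluded from the comparison and reported. Note that per-gene pooling on
short rows is coarse — with 10 observed values per row the scores are
multiples of 0.1 and each row's maximum is exactly 1 — which is the main
reason the mode can be forced to `global` for small matrices.

*Sign.* For datasets where negative association is meaningful the
probabilities are doubled and shifted (s = 2p − 1). Unobserved entries are
never pulled into a pool and stay 0 after materialization; when a source
stores "no data" as literal zeros, `zero_is_unobserved` excludes them too.

## Thresholding

The strongest fraction (`retain_fraction`, default 0.10) of *observed*
entries is retained; applying the fraction to the full grid would let
structural zeros crowd out real signal in sparse datasets. Ranking is by
|s| so strong negative associations survive alongside positive ones
(ranking by signed value is available; a fixed 5%/5% split per tail is
not, because "strongest" reads as magnitude). Retained entries become 1 or
sign(s); boundary ties are broken by stable row-major index so the
retained count is exactly ⌊f·N⌋ and byte-identical across runs;
`keep_all_tied` instead keeps the whole tie group for sensitivity
analyses.

## Preprocessing

The step vocabulary (row/column filtering, row/column averaging,
imputation, log transform, z-scaling, quantile normalization) mirrors what
per-dataset cleaning scripts typically need before standardization. Steps
apply in the caller's order and each records itself in the matrix's
provenance log, which serializes to a sidecar text file. Quantile
normalization requires fully observed columns (impute first) and is
idempotent. Imputing a fully unobserved row is an error rather than a
silent zero-fill.

## Identifier mapping

Symbol tables are built from synonym lists (synonym, gene id, official
symbol) with two filters applied at finalization: synonyms reaching more
than one gene id are dropped as ambiguous, and synonyms identical to an
official symbol are dropped, after which official symbols are added as
identity entries so current nomenclature still resolves. Matching is
exact-case first with a case-insensitive fallback for symbol tables (the
fallback is logged through the table's lookup API); sources disagree on
case conventions and a silent case-sensitive miss would inflate the
unmapped fraction.

Chained id spaces (probeset → Ensembl → gene id, coordinates → Ensembl →
gene id) compose by relational join with the ambiguity filter re-applied
post-join; a probeset whose annotation lists several intermediates is kept
only if all its surviving paths converge on one gene id. Homolog tables
(gene id → gene id across species) relabel rows, dropping genes without a
homolog and averaging many-to-one collapses. Every application of a table
to a matrix emits a report with n_input = n_mapped + n_unmapped, the
unmapped fraction, and up to 20 verbatim unmapped identifiers.
Coordinate-interval resolution at query time is out of scope: coordinates
are assumed pre-joined into a mapping table.

## Similarity and clustering

Cosine similarity is computed on materialized vectors (unobserved = 0).
Zero-norm vectors get similarity 0 with every partner — not NaN — so
matrices stay exportable; they are flagged in a side list. On ternary
vectors the cosine reduces to (same-sign overlap − opposite-sign
overlap)/(√n₁√n₂), which the tests verify against set arithmetic.
Cross-dataset comparisons restrict both attribute vectors to the shared
gene universe (default minimum 10 genes) rather than zero-filling the
union, which would inflate the similarity of sparse attributes.

Heat-map orderings use agglomerative clustering with average linkage on
distance 1 − similarity. Linkage choice is a convention (exposed in the
API); average linkage is the common default for association heat maps.
Determinism matters more than optimality here: rows are pre-sorted by
label before linkage so identical data yield identical leaf orders
regardless of input permutation, and repeated runs are bit-identical.

## Guilt-by-association pipeline

*Features.* Each dataset is projected onto the smallest set of leading
principal components capturing `variance_fraction` (default 0.99) of its
variance; component signs are fixed (largest-magnitude loading positive)
for determinism. Per-dataset scores are concatenated; a gene missing from
a dataset is zero-filled on that block rather than dropped, so coverage
differences across sources shrink neither the task nor the gene universe
— coverage is reported instead.

*Feature selection.* Features are ranked by univariate ROC
discriminativeness |AUC − 0.5|, so a feature whose *low* values mark
positives ranks as high as its mirror image; the top `n_features`
(default 70) are kept. Dataset-level ranking (mean |AUC − 0.5| of a
dataset's top components) is provided as an explicitly labelled heuristic.
Because selection uses the training labels, out-of-bag estimates carry a
mild optimistic bias when many pure-noise features compete; the
permutation-null tests therefore use either many examples relative to the
feature pool or the full feature set.

*Training and evaluation.* The classifier is a bagged decision-tree
ensemble (random forest, default 300 trees) with a fixed seed. Each
training example is scored by the trees whose bootstrap sample excluded
it; the forest's out-of-bag decision function averages those trees'
predicted probabilities, which for fully grown trees is effectively the
vote fraction. Examples included in every bootstrap (rare at 300 trees)
score 0.5 with a warning. ROC/F1/MCC curves sweep the unique scores as
thresholds; AUC is the trapezoid under the tie-aware ROC, which equals the
Mann–Whitney statistic normalized by n⁺n⁻; MCC is defined as 0 when a
confusion marginal is 0.

*FDR.* The estimated FDR at a threshold is 1 − out-of-bag precision,
made nondecreasing in descending-score order by a running maximum so that
loosening the cutoff can never claim a lower error rate. An unknown gene
inherits the FDR of the tightest out-of-bag threshold at or below its
score. The presets 0.67 and 0.33 correspond to "two-thirds" and
"one-third expected false discoveries" operating points.

*Multi-label and pair tasks.* Multi-label problems train one ensemble per
label (labels with fewer than 3 positives are skipped and reported) and
pool micro-style — concatenating all labels' out-of-bag scores — with
macro averaging as an option. Pair prediction (receptor–ligand,
enzyme–substrate) featurizes a pair by concatenating the two genes'
assembled feature vectors; the negative class in such tasks is typically
"not known to interact", so label noise is expected and quantified only
through the out-of-bag curves.

## Networks

Figure-style networks insert candidate edges in descending |weight|
order, skipping any edge that would push either endpoint past
`max_edges_per_node` (default 3, counting total degree; counting only
edges contributed per candidate node is available). Greedy insertion is
the natural reading of "no more than three edges per node" and is
reproducible; it does not maximize total retained weight, which is not
the goal of a readability cap. Components whose edges are all flagged
known can be trimmed, leaving only components containing a novel
prediction; the operation is idempotent. Tripartite joins (e.g.
drug–enzyme–disease) drop middle nodes lacking a partner on either side
and apply the cap per layer pairing.

## Synthetic fixtures

`make_planted_matrix` emulates the block structure of clustered
association heat maps: genes and attributes partition into modules,
in-module cells get mean `within_module_signal` (default 3) with Gaussian
noise (sd 1), and a `sparsity` fraction of cells is unobserved. Gaussian
additive structure is the simplest generator exhibiting the phenomenology;
real datasets have heavier tails, correlated noise and non-random
missingness, so passing tests demonstrate correctness of the machinery,
not performance on real data.

`make_mapping_fixture` injects an exact number of ambiguous synonyms and
official-symbol collisions and returns the finalized table the filters
must produce, so the filter tests are self-validating.

`make_gba_fixture` gives positives — and a hidden 20% of the "unknown"
class — a mean shift of `effect_size` (default 3) noise-sd units on 5
informative attributes in each of 3 datasets, for 100 positives, 100
negatives and 100 unknowns. Effect size 3 makes the task cleanly
separable, which is intended: it verifies the pipeline recovers plantable
signal and that permuting labels destroys it, not that the method attains
any particular accuracy on real biology. All generators are pure functions
of their parameters and seed.

## Problem sizes and determinism

The test suite and the acceptance script run on small planted instances —
matrices up to 100×100, supervised tasks of 300 genes × ~90 features,
forests of up to 300 trees — chosen so the full pipeline, including
repeated training runs, completes in seconds while still exercising every
code path at the published parameter defaults. All randomness flows
through explicit integer seeds (`numpy.random.default_rng`,
scikit-learn's `random_state`), and reruns are bit-identical.

## Known limitations

- Per-gene ECDF on rows with few observations quantizes scores coarsely
  (every row maximum becomes exactly 1).
- The FDR estimator inherits the out-of-bag curves' granularity; with few
  training examples the estimate is a step function.
- Univariate feature ranking cannot credit features informative only in
  combination; this is by design (the pipeline reproduces a univariate
  ROC selection step), not a recommendation.
- The negative class in real guilt-by-association tasks is "not known
  positive"; measured error rates conflate model error with label
  incompleteness.
- Genomic-coordinate identifiers must arrive pre-resolved to a mapping
  table; no interval arithmetic is performed.
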