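# Methods

This note documents the models, numerical conventions and design choices
behind `methtree` — what each stage assumes, which parameters matter, and
what the synthetic cohorts do and do not emulate.

## Data model and preprocessing

A cohort is a beta matrix (CpG probes × samples, β ∈ [0, 1)), a sample
manifest (sample id, cancer type, clinical subtype, cohort/batch tag,
train/test split) and a probe annotation (probe id, chromosome).  Beta
values computed from intensity pairs use β = M/(M + U + 100); the
pseudo-count keeps β strictly below 1 and damps low-intensity noise.

Probe filtering keeps the intersection of the per-cohort probe sets, drops
sex-chromosome probes (the annotation names `X/Y/chrX/chrY/23/24` are all
recognised) and drops any probe with a missing or non-finite cell — no
imputation is attempted at preprocessing, because a probe missing in any
cohort cannot anchor a cross-cohort classifier.  Probes absent from the
annotation are kept as presumed autosomal, with a logged warning, rather
than silently discarded.  Subtype filtering removes subtypes with fewer
than 5 samples or contributing < 10% of their cancer type; an explicit
exclusion list handles ambiguous subtypes instead of heuristics.

The train/test split is stratified by cancer type: per type,
⌊0.8·n⌋ samples train and the remainder test.  Flooring (rather than
rounding) guarantees at least one test sample whenever n ≥ 2.  The split
is a pure function of the seed.  Stratification is by type only, not by
subtype — subtypes are a clustering device here, not a prediction target.

## Taxonomy construction

Subtype mean profiles are computed on the top 1% most variable probes
(variance across *all* samples, sample variance with ddof = 1, ties and
ranking resolved by probe id so the selection is deterministic).  The
profiles are clustered by UPGMA on d = 1 − Pearson r.  The UPGMA
implementation is in-package so two conventions are explicit:

* node height = merge distance / 2 (children of a node sit at equal depth
  — the output is ultrametric by construction, and on an input that is
  already ultrametric the cophenetic distances reproduce the input
  exactly);
* ties at the minimal linkage distance merge the pair whose smallest
  member labels are lexicographically first, so rebuilding the tree on the
  same input is byte-stable.

The linkage matrix is scipy-compatible; scipy's own average-linkage
cophenetic matrix is used as an independent cross-check in the tests, not
as the implementation.

The number of groups k is chosen by cutting the tree into k clades for
each candidate k (default 2 … min(20, n − 1)) and maximising the mean
silhouette (ties go to the smaller k).  Silhouette uses the standard
convention s = 0 for singleton clusters.  Because a silhouette argmax
cannot encode domain judgment (e.g. keeping a biologically distinct
entity separate from its nearest neighbour), forced assignments are
exposed as explicit configuration (`overrides`) applied after the cut —
never as hidden heuristics.  A cancer type whose subtypes land in
different groups is split into per-subtype class labels, so every class
routes to exactly one group.

## Marker screening

Each classification problem (the group problem, and one per multi-type
group, using only that group's training samples) runs the same cascade on
training data only:

1. **ANOVA screen.**  One-way fixed-effects ANOVA per probe, vectorized
   as between/within sums of squares; default α = 0.05.  Degenerate
   probes: zero within-class variance with equal means → p = 1 (excluded);
   with unequal means → p = 0 (retained).
2. **Tukey–Kramer one-vs-all-others.**  For classes (i, j),
   SE = √((MSE/2)(1/nᵢ + 1/nⱼ)), q = |mᵢ − mⱼ|/SE, and the adjusted p is
   the upper tail of the studentized range distribution with k classes and
   N − k degrees of freedom (valid for unequal class sizes).  A probe
   marks class g at level Δ iff *every* other class h has adjusted
   p < 0.01 and |m_g − m_h| > Δ.  Each class uses the first level of the
   schedule (0.2, 0.15, 0.1) that yields ≥ `min_markers` (default 20)
   markers; classes that never reach the quota keep the last level's
   markers and are recorded as failures, not exceptions.  Internally the
   p-comparison is done against the critical studentized-range quantile
   (one `isf` call) instead of per-pair `sf` calls — the same decisions,
   orders of magnitude faster across thousands of probes.
3. **Boruta confirmation.**  Implemented in-package: each iteration
   appends a permuted shadow copy of every active feature, fits a
   random-forest importance estimator, and scores an undecided feature a
   hit when its impurity importance exceeds the maximum shadow importance.
   Hit counts are tested against Binomial(iterations, ½), two-sided with
   Bonferroni correction across the currently undecided features
   (α = 0.05): significantly more hits confirms, significantly fewer
   rejects; rejected features leave the active pool.  Features still
   undecided at `max_iter` are dropped by default; an optional "rough fix"
   confirms those whose median importance exceeds the median max-shadow
   importance.  The internal estimator is a 300-tree, depth-10 forest:
   with hundreds of mutually correlated candidate markers, a small forest
   leaves many informative features unused in a given iteration (impurity
   importance 0 → spurious miss), so the estimator needs enough splits to
   touch every candidate each round.  The pipeline default of 30
   iterations decides strong candidates (a perfect hitter reaches
   Bonferroni significance around iteration 15) while keeping a full
   cascade run within minutes.

## Two-layer classifier and prediction

Both layers are scikit-learn random forests with 200 trees and balanced
class weighting by default (class imbalance across tumor types is the
rule, so down-weighting the majority classes is the sensible default; a
switch disables it).  Tree depth and features-per-split stay at estimator
defaults but are exposed.  Each fitted layer stores its feature panel and
the training-set mean of every panel probe: at prediction time, panel
probes absent from the input (e.g. another array platform) are imputed
with those means and logged per sample; a sample missing more than 50% of
the panel is rejected rather than silently imputed.

Top-k² routing with k = 2: take the two highest-probability groups from
layer 1 (ties broken by group label for determinism); a singleton group
contributes its type directly, a multi-type group contributes the
top-min(k, group size) types from its layer-2 model.  The candidate set is
the deduplicated union — between 2 and 4 labels — and the top-1 call
routes through the argmax group only.  Per-class precision and recall are
computed on top-1 calls (candidate sets have no unique per-class
assignment).  k-fold cross-validation is stratified; classes smaller than
the fold count trigger a documented fallback to unstratified folds with a
warning rather than an error.  One-vs-rest AUC is reported per class and
macro-averaged; classes absent from the test set are excluded with a
warning.

A flat baseline (`train_flat_baseline`) runs the same cascade once with
every type as its own class (the flat panel is the union of per-type
one-vs-all selections) and fits a single forest, for head-to-head
comparisons between hierarchical and flat classification.

## Synthetic cohorts

The generator plants every structure the pipeline is supposed to recover.
Defaults mirror the pan-cancer regime at desk scale: 12 groups over 30
cancer types (group sizes 1–4, three singleton groups), 2 clinical
subtypes per type, 20 samples per subtype (1 200 samples), 5 000
background probes, 40 group-marker and 30 type-marker CpGs per class with
planted Δβ = 0.3, beta noise of concentration κ = 50 (per-probe s.d.
≈ 0.06 at intermediate means), two cohort tags, no batch shift and no
missingness unless requested, plus 100 sex-chromosome probes that the
preprocessing must remove.

* **Baselines** are bimodal (mixture of Beta(2, 8) and Beta(8, 2)),
  mimicking the hypo/hyper-methylated peaks of array data.
* **Group structure** lives on a "lineage" subset of the background
  probes (≈ 1% of all probes, intermediate baselines drawn from
  U(0.45, 0.55)).  Group signatures evolve along a random ultrametric
  binary tree (successive random joins, the m-th merge at height
  m/(n − 1)): each edge adds a drift increment of fixed per-probe
  magnitude `drift_scale`·√(edge duration) with Rademacher signs,
  orthogonalised against a constant vector, the centred baseline and all
  previously drawn edges.  With exact orthogonality the planted
  between-group correlation distance is an exact monotone function of the
  pair's merge height — i.e. the planted structure is ultrametric not
  just in expectation but realisation-by-realisation, which is the
  precondition for UPGMA recovery to be a well-posed test.  What a
  recovery test then measures is robustness of the full pipeline
  (sampling noise, subtype jitter, variance-based probe selection) rather
  than luck in the drift draw.  The default `drift_scale` = 0.22 places
  lineage-probe variance safely above marker-probe variance, so the top-1%
  variance selection is dominated by lineage probes.
* **Markers** keep a flat baseline in every class except the marked one,
  which is shifted by ±Δβ (direction chosen to stay inside (0, 1); the
  generator errors before sampling if neither direction fits).  Keeping
  marker baselines free of group drift means the realised minimum gap to
  all other classes stays at the planted Δβ.
* **Noise**: per-sample values are Beta(mκ, (1 − m)κ) draws; only means
  are ever clipped (to [0.02, 0.98]), never draws.  Per-subtype N(0, 0.01)
  jitter, per-cohort additive batch offsets, uniform missingness and
  alternating chrX/chrY probes complete the picture.

What the generator does **not** emulate: Type I/II probe chemistry bias,
copy-number contamination, tumor purity, correlated missingness, or the
local correlation of neighbouring CpGs.  Passing tests therefore show the
pipeline recovers structure of this planted kind under realistic noise —
not that real pan-cancer cohorts will be classified with the same
accuracy.

## Problem sizes used by the checks

The behavioural checks run on the default cohort above (≈ 6 500 probes ×
1 200 samples): planted-tree recovery over five seeds, marker-cascade
recall/contamination and held-out accuracy on one seed, and the routing
worked examples on a four-group cohort (two multi-type, two singleton
groups; 90 samples).  These sizes were chosen so a full run completes in
minutes on a single core while leaving wide statistical margins on every
asserted threshold.

## Known limitations

* The silhouette-guided cut occasionally prefers k one below the planted
  group count when two sibling groups are very close; group membership is
  still recovered up to that merge (this is why forced overrides exist).
* Boruta decisions on features that are informative only in-sample (small
  n, many features) follow the association structure of the data, not the
  generative truth; with ≥ 4 samples per feature the false-confirmation
  rate is negligible.
* Tukey–Kramer assumes a shared within-class variance per probe; beta
  noise is heteroscedastic in the mean, which is mild at the planted
  effect sizes but untested at Δβ close to 0.
* Cross-platform prediction relies on mean imputation of missing panel
  probes; beyond 50% missing the model refuses rather than extrapolates.
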