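# methtree

Hierarchical classification of primary tumor type from DNA-methylation
beta values.

## The problem

Genome-wide DNA methylation is strongly tissue- and tumor-type-specific,
which makes 450K-array beta values (β = M/(M + U + 100), the fraction of
methylated signal at a CpG) a powerful substrate for predicting the tissue
of origin of a tumor sample.  Flat multi-class classifiers treat every
cancer type as an unrelated label and must find features that separate all
types at once; they degrade as the label set grows and give no useful
signal for types they were never trained on.  `methtree` instead exploits
the natural hierarchy of tumor methylomes: closely related entities
(e.g. squamous carcinomas of different organs, or the kidney-derived
carcinomas) share methylation signatures, so classification can proceed
top-down — first the *group* of related types, then the *type* within the
group.

`methtree` is aimed at computational epigenomics researchers who want a
transparent, fully scriptable pipeline from a beta matrix to a ranked
differential diagnosis, including the taxonomy construction and marker
screening stages.

## Method

1. **Preprocessing** (`methtree.data_io`) — probes restricted to those
   shared by all cohorts, sex-chromosome probes and probes with missing
   values removed; clinical subtypes with fewer than 5 samples or < 10% of
   their cancer type removed; stratified 4:1 train/test split per type.
2. **Taxonomy** (`methtree.taxonomy`) — per-subtype mean methylomes on the
   top 1% most variable CpGs are clustered by UPGMA on the Pearson
   correlation distance d = 1 − r; the dendrogram is cut into k groups
   where k maximises the mean silhouette coefficient
   s(i) = (b(i) − a(i)) / max(a(i), b(i)), with explicit overrides for
   judgment calls.  A cancer type whose subtypes land in different groups
   is split into per-subtype class labels.
3. **Marker screening** (`methtree.feature_select`) — a three-stage
   cascade per classification problem: (i) one-way ANOVA screen
   (p < 0.05); (ii) Tukey–Kramer one-vs-all-others selection — a CpG marks
   class g iff for *every* other class h the studentized-range adjusted
   p < 0.01 **and** |Δβ| > 0.2, with the Δβ threshold relaxed stepwise to
   0.15 and 0.1 when a class cannot muster enough markers; (iii) Boruta
   confirmation against permuted shadow features with a binomial hit test.
4. **Two-layer model** (`methtree.classifier`) — a 200-tree random forest
   over groups (layer 1) and one per multi-type group over its types
   (layer 2); singleton groups are predicted directly by layer 1.
5. **Top-k² prediction** (`methtree.evaluate`) — the top-2 groups are
   taken from layer 1; each contributes its single type or its top-2
   layer-2 types, yielding a candidate set of 2–4 diagnoses plus a routed
   top-1 call, with per-class precision/recall, k-fold CV and one-vs-rest
   AUC for evaluation.

A synthetic-cohort generator (`methtree.synthetic`) plants a known group
hierarchy, marker CpGs, batch structure, missing values and sex-chromosome
probes so that every stage is testable end-to-end without external data.

## Worked example

```python
from methtree import SyntheticSpec, generate_cohort, ForestConfig
from methtree.pipeline import train_from_cohort
from methtree.evaluate import predict_batch, classification_report

spec = SyntheticSpec(n_groups=4, types_per_group=(1, 2, 2, 1),
                     subtypes_per_type=2, samples_per_subtype=10,
                     n_background_probes=300, n_markers_per_group=12,
                     n_markers_per_type=8, n_sex_probes=10, seed=5)
matrix, manifest, annotation, truth = generate_cohort(spec)
result = train_from_cohort(matrix, manifest, annotation,
                           config=ForestConfig(n_trees=100, seed=5),
                           min_markers=5, boruta=False)
test = result.manifest[result.manifest.split == "test"]
preds = predict_batch(result.model, result.matrix[test.sample_id.to_numpy()], k=2)
truths = result.assignment.class_labels_for(test)
report = classification_report(preds, [truths[p.sample_id] for p in preds])
```

Output:

```
taxonomy: 4 groups over 12 subtypes
layer-1 panel: 69 CpGs; second-layer models: ['grp02', 'grp03']
held-out n=24: top-1 accuracy 1.000, top-2^2 accuracy 1.000
sample S00001: groups [('grp01', 0.97), ('grp03', 0.02)] -> candidates ['T01', 'T04', 'T05'], top-1 T01
```

The taxonomy recovered the four planted groups from the subtype-mean
dendrogram; two of them (grp02, grp03) contain more than one cancer type
and therefore get second-layer classifiers.  The first test sample routes
through grp01 (probability 0.97) and grp03: grp01 is a singleton group
contributing its type directly (T01), while grp03 is multi-type and
contributes its top-2 types (T04, T05) — a 3-label candidate set whose
top-1 call (T01) is correct.

The same flow is available from the shell:

```bash
methtree simulate --spec spec.json --out-dir cohort/ --seed 5
methtree preprocess --matrix cohort/beta_matrix.tsv --manifest cohort/manifest.tsv \
    --annotation cohort/annotation.tsv --seed 5 --out-dir prep/
methtree train --matrix prep/beta_matrix.tsv --manifest prep/manifest.tsv \
    --n-trees 200 --seed 5 --out model/
methtree predict --model model/ --matrix prep/beta_matrix.tsv --out predictions.tsv
```

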