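# anchorseq

Global, human-readable *if-then* rules from any black-box sequence
classifier — built for T-cell-receptor (TCR) binding predictors, usable
for any fixed-frame categorical sequence model.

Machine-learning models that predict whether a TCR β-chain binds an
epitope are typically black boxes: accurate, but silent about the
biochemical rules behind their predictions. `anchorseq` extracts those
rules post hoc. It needs nothing from the model but a batch
`predict(samples) -> {binding, non-binding}` contract, which makes it
applicable to models with proprietary or unreleased code. The intended
users are computational immunologists auditing a trained predictor, and
method developers who need a quantitative way to compare explanation
quality.

## Method

1. **Split.** The dataset is partitioned into *binding* and *non-binding*
   splits according to the model's own predictions.
2. **Cluster.** Each split is clustered separately under the Levenshtein
   edit distance (k-medoids, agglomerative or OPTICS on the precomputed
   distance matrix; BIRCH for vector features). Each cluster is
   represented by its **medoid** — the member minimising total distance to
   the rest. Silhouette / Davies–Bouldin sweeps, consensus clustering over
   a co-association matrix, and t-SNE/LLE projections support algorithm
   choice.
3. **Explain.** For each medoid x with predicted class y, the search finds
   an **anchor**: a conjunction A of `(position = amino acid)` predicates
   drawn from x's own frame such that

       prec(A) = P[ f(z) = y | z ~ D(x | A) ]  ≥  τ*  (with confidence 1 − δ)

   where `D(x | A)` perturbs x by position-wise resampling from the
   split's empirical per-position composition (keep probability ½) while
   holding A's positions fixed. Candidate extensions are compared by
   KL-LUCB best-arm identification (tolerance τ) on batched model calls,
   and an accepted rule is minimised so that every remaining predicate is
   necessary. Defaults: precision target τ* = 0.9, δ = 0.3, τ = 0.3.
4. **Audit.** The rule set is scored by accuracy/precision/recall at three
   levels — per cluster (CL: a true positive fulfils *only* its own
   cluster's rule), per split (CS: fulfils the rule and shares its split),
   and for the whole split's rule set (SP) — plus a predicate-overlap
   matrix, a co-fulfilment matrix and a completeness histogram (how many
   anchors apply per sample).
5. **Regions.** Predicates are mapped onto framework (FR1–4) and
   complementarity-determining regions (CDR1–3), densities normalised by
   region length, and rules rendered as motifs above the split's sequence
   logo.

A synthetic module generates TCR-like repertoires (mutated clones in a
padded frame with FR/CDR annotations) together with a **planted-rule
model** whose ground truth makes rule recovery measurable.

## Worked example

`python examples/01_extract_rules.py` builds the default benchmark
(1000 sequences, frame 20, two planted 3-predicate binding rules),
clusters the binding split and extracts one anchor per medoid:

```
model predicts 427 binding / 573 non-binding sequences
binding split clustered into 4 clusters, medoids ['s00000', 's00001', 's00465', 's00533']

planted ground-truth rules:
  (G@3) AND (E@8) AND (P@13)
  (W@3) AND (I@8) AND (R@13)

anchors recovered from the black box:
  cluster 0: IF (G@3) AND (E@8) AND (P@13) THEN binding  [precision 1.000 >= 0.981, coverage 0.51]
  cluster 1: IF (W@3) AND (I@8) AND (R@13) THEN binding  [precision 1.000 >= 0.981, coverage 0.49]
  ...
```

Each anchor reproduces one planted conjunction exactly: every perturbed
sequence satisfying the rule keeps the model's binding prediction
(precision estimate 1.0, KL lower bound 0.98), and each rule covers the
half of the binding split descended from its carrier clone. The other
examples audit a full rule set (`02`), compare clusterings and build a
consensus (`03`), and map rules onto CDR regions with a motif figure
(`04`).

The same pipeline runs from a JSON configuration:

```sh
anchorseq run --config cfg.json --seed 0        # or per stage:
anchorseq split|cluster|explain|evaluate|visualize --config cfg.json
```

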