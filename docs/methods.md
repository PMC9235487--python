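# Methods

## Problem setting

`anchorseq` explains a black-box classifier `f` over fixed-frame
amino-acid sequences. The only contract is a deterministic, order-
preserving batch `predict` returning labels in {binding, non-binding};
any model-specific encoding (BLOSUM, SMILES, physicochemical factors) is
an adapter's responsibility behind that contract. Probabilistic adapters
should threshold at 0.5 and document any other decision rule; the
pipeline never sees scores, only labels. All sequences of a run share one
frame length; shorter sequences are PAD-filled (`-`), optionally wrapped
in START/STOP tokens (`^`, `$`). Rule predicates, perturbations and
region annotations all address frame positions, which is what makes rules
comparable across clusters.

## Clustering and medoids

Each prediction split is clustered separately — binding and non-binding
rules are expected to differ, and mixing the splits would blur both.
The built-in distance is Levenshtein on residues (reserved tokens
stripped first: edit distance on padding is meaningless), computed by
edlib. k-medoids (seeded initialisation, alternating assignment and
exhaustive medoid update), agglomerative and OPTICS accept the
precomputed matrix; BIRCH is registered for vector features only, since
it cannot consume arbitrary distances. Medoids minimise the summed
intra-cluster distance, ties broken by lexicographically smallest id;
OPTICS noise points (label −1) get no medoid and no anchor — a noise
"cluster" has no meaningful representative.

Model selection: a sweep over a user grid (k, or ε for OPTICS) scored by
silhouette (precomputed distances; samples alone in their cluster
contribute 0) or Davies–Bouldin (features, minimised). Consensus over
several clusterings is built from the co-association matrix (fraction of
inputs placing a pair together), grouped by average-linkage agglomeration
on 1 − co-association and cut at the floor of the median input cluster
count; the construction is invariant to relabeling of input clusters.
t-SNE (precomputed distances, random init) and LLE (features) provide
qualitative 2-D views; for n ≤ 3, where no t-SNE perplexity exists, a
classical-scaling fallback keeps the contract total. Every stochastic
step takes an explicit seed (default 0).

## Anchor search

An anchor for medoid x with predicted class y is a conjunction A of
(position, symbol) predicates, all equal to x's own frame symbols, with

  prec(A) = P[f(z) = y],  z drawn by perturbing x with A's positions held
  fixed.

Positions holding PAD/START/STOP are eligible: a rule may require padding
and thereby encode sequence length.

**Perturbation distribution.** Every position outside A independently
keeps x's symbol with probability ½, otherwise resamples from the
perturbation pool's empirical distribution at that position (the pool is
the medoid's own split by default). The marginal probability that a
perturbed sequence carries symbol s at a free position j is therefore
`0.5·[x_j = s] + 0.5·freq_pool(j, s)` — a closed form the tests check at
n = 10 000. The keep probability ½ balances locality around the medoid
against exploration of the split's composition.

**Estimation.** prec(A) is a Bernoulli mean estimated from batched model
calls (batch 100 per bandit pull). Confidence bounds are
Kullback–Leibler (Chernoff) bounds: the upper/lower bound is the
largest/smallest q with `n·KL(p̂, q) ≤ β`, solved by 40 bisection steps
(resolution < 1e-12); reported two-sided bounds use β = log(2/δ).

**Search.** Bottom-up beam search from the empty rule (so that a
constant-enough model yields the vacuous rule immediately). Each round
extends every beam rule by one unused position; the best extension is
identified by KL-LUCB: after one initial pull per arm, the empirically
best arm and the highest-upper-bound contender are pulled alternately
with exploration rate β(t) = log(K·t^1.1/δ) until the contender's upper
bound is within τ of the best arm's lower bound. Ties between equal
candidates break toward higher pool coverage, then lower position index
(prefer general rules; stay deterministic). A selected rule is accepted
when its lower bound reaches the precision threshold, pulled further
while the threshold lies between its bounds, and abandoned as a candidate
anchor (but kept extendable) when its upper bound falls below the
threshold — precision grows along the search path, so a weak prefix can
still lead to a strong conjunction.

**Minimisation.** An accepted rule is pruned: each predicate is removed
in turn if the reduced rule's lower bound still clears the threshold,
repeating until no predicate is removable. Anchors are meant to be
minimal sufficient conjunctions — at the loose default operating point
(δ = τ = 0.3) the bandit occasionally commits to a superfluous predicate
before completing a sufficient one, and pruning removes exactly those.
The pass can be disabled (`minimize_rule=False`).

**Budget.** A per-anchor cap on total bandit pulls (default 2000 pulls =
200 000 model calls) bounds runtime; on exhaustion the best rule found is
returned flagged `below_threshold`, and evaluation keeps such rules but
marks them.

Defaults — precision threshold 0.9, δ = 0.3, τ = 0.3, beam width 1
(greedy), batch 100 — are the operating point the package is calibrated
and tested at.

## Rule-set audit

The evaluation universe at every level is the full test set (both
splits), so false positives can come from the opposite split. Per rule r
from cluster c of split s:

* **CL** — TP: samples of c fulfilling *only* r (exclusive over the whole
  rule set; an inclusive variant and a per-split quantification are
  available behind flags, default exclusive-over-all). FN: other samples
  of c. FP: samples outside c fulfilling r.
* **CS** — TP: samples fulfilling r predicted as s; FP: fulfilling r,
  predicted otherwise; FN: predicted s, not fulfilling r.
* **SP** (per split) — TP: samples predicted s fulfilling ≥ 1 of s's
  rules; FP/FN analogous.

Accuracy, precision and recall follow the usual ratios; zero-denominator
ratios are reported as NaN with a logged warning, never coerced to 0
(small clusters make them common). The predicate-overlap matrix counts
sub-rules identical in position *and* symbol; the co-fulfilment matrix
counts samples satisfying both rules (rules ordered non-binding first);
the completeness histogram counts applicable anchors per sample,
including bin 0. All of these are verified against a brute-force
enumerator on random fixtures (integer equality).

## Region analysis

Region annotations (FR1–4, CDR1–3, Other, PAD, Start, Stop intervals per
sequence, 0-based half-open) are inputs; germline numbering/alignment is
out of scope. Each predicate of a split's rules is assigned to the region
covering its position in the rule's own medoid annotation (uncovered
positions fall to Other with a warning); counts are divided by the region
length summed over the split's medoids. The counting unit is the
predicate — whole-rule counting (each rule contributes 1 split across its
predicates' regions) is available behind a flag, since a multi-region
rule makes "rules per region" ambiguous. Sequence logos use per-position
frequencies over non-PAD symbols (all-PAD columns flagged empty); motif
figures draw the rule's required residues above the split logo with
matplotlib glyph rendering and are byte-stable for fixed input.

## Synthetic benchmark

The generator emulates the cluster structure of an antigen-expanded
repertoire at desk scale: `n_seed_sequences` random clones copied
round-robin to `n_samples` sequences, each residue position independently
replaced with probability `mutation_rate` by a uniformly random alphabet
symbol (possibly identical, so the expected Hamming distance to the seed
is exactly `L·rate·(1 − 1/|alphabet|)`). Defaults: n = 1000, frame 20
(16 residues across FR1–FR4 with CDR1/2/3, then PAD), alphabet of the 20
amino acids, 4 clones, mutation rate 0.05 — large enough for stable
bandit estimation, small enough for minutes-scale test runs; 0.05 gives
tight clusters (≈ 0.8 edits within a clone, ≈ 15 between clones).

The black box is a planted-rule oracle: binding iff any planted
conjunction holds, with optional per-sample label flips (deterministic
via a salted content hash, so batch predictions stay reproducible). The
default benchmark plants two 3-predicate rules, one per CDR position
(3, 8, 13), carried by clones 0 and 1; the repertoire is redrawn
(deterministically) if the carrier clones coincide at a planted position,
since a predicate shared by the whole binding pool is unidentifiable by
any perturbation scheme and the planted rules are meant to be two
distinct, recoverable conjunctions.

What the generator does *not* emulate: VDJ-recombination statistics,
length variation within a repertoire (all clones share the template
layout), position interdependence, and real negative-pool heterogeneity.
Passing the recovery tests therefore demonstrates correctness of the
machinery under clean, identifiable conditions — not that anchors on a
real predictor will be as crisp; on real data precision bounds and
completeness histograms are the instruments for judging that.

## Determinism and problem sizes

All randomness flows from one configured seed through
`numpy.random.SeedSequence` children (per stage, per anchor); two runs
with the same configuration are byte-identical, which the tests assert on
the full pipeline. The test suite and the acceptance script run the
benchmark at n = 1000 with 20 recovery runs and 50 precision-guarantee
runs (10 000 fresh perturbations each), the evaluation oracle on 100
random ≤ 50-sample fixtures, and distance/medoid oracles on 1000 random
pairs/triples — sizes chosen so the whole suite completes in a few
minutes on one CPU.

## Known limitations

* Anchors only ever contain the medoid's own symbols; they cannot express
  disjunctions or "anything but X" constraints.
* The perturbation distribution treats positions independently; strongly
  covarying positions (e.g. paired structural contacts) are perturbed as
  if independent, which can overstate precision for rules that rely on
  such covariation.
* CS/SP metrics inherit the model's own split — they audit faithfulness
  to the model, not biological truth.
* The non-binding split of a typical repertoire is unspecific; its
  anchors are often vacuous or very loose (the empty rule can already
  exceed the precision target). This mirrors the underlying biology but
  limits the interpretive value of non-binding rules.
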