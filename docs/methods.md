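# Methods

This note records the models and procedures `spiderens` implements, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic benchmarks do and do not establish.

## Problem setting

Binary classification of samples × features tables in which one class
(the positive class, label 1 — by convention the minority/patient class)
is underrepresented, feature counts can far exceed sample counts, and
values may be missing. The minority-is-positive convention is applied
uniformly: KEEL-format readers map the rarer class token to 1, so TP,
recall, F1 and the ROC score always refer to the class of interest.

## Preprocessing

Missing cells are imputed by the feature mean within the sample's class;
a feature entirely missing within a class falls back to the overall
feature mean, and one missing everywhere is filled with 0 (logged).
Features are then min–max scaled to [0, 1]; constant features map to
all-zeros, which both avoids division by zero and leaves their χ² scores
at 0. Imputation precedes normalization. In the pipeline harnesses both
statistics are learned on the training split only; test values outside
the training range are clipped to [0, 1].

## Selective over-sampling

Distances are Euclidean. Neighbor order is deterministic: ties in
distance break by lower sample index, and a sample is never its own
neighbor.

* **Noise flagging.** A sample is *safe* iff the plurality label of its
  k nearest neighbors equals its own label; vote ties (possible at even
  k) count as safe. Default k = 3 — the selective-preprocessing
  literature uses small odd neighborhoods; k is exposed everywhere.
* **Weak/strong partition.** Non-noisy minority samples are re-examined
  in the pool of *safe* samples only. A minority sample whose k nearest
  pooled neighbors contain more majority than minority samples is
  *weak*; otherwise *strong*. Noisy minority samples are *excluded*.
  Restricting the pool to safe samples (rather than only dropping noisy
  majority samples) is deliberate: a sample that passed the safety vote
  keeps at least ⌈k/2⌉ own-class unrestricted neighbors, so with noisy
  minority samples still in the pool the weak tag would be unattainable
  at odd k.
* **Generation.** Weak seeds generate one synthetic sample per majority
  sample among their k nearest pooled neighbors; strong seeds generate
  one. Each synthetic sample is a uniform random interpolation between
  the seed and one of its k nearest non-noisy neighbors, so every
  coordinate lies on the parent–neighbor segment. Generation sweeps the
  weak set repeatedly (at most 10 passes, and stops when a pass makes no
  progress) until the minority count reaches the balance target
  (default 1.0 × majority count). Original majority rows are always
  retained — under-sampling loses information; `drop_noisy_majority`
  enables literal removal of noisy majority rows for ablation.

Amplification counts and the pass cap are conventions of the cited
selective-preprocessing scheme; neither is dictated by the data, and both
are configurable. With few or no weak seeds the stop rule can leave the
output short of exact balance; the output imbalance ratio is still
guaranteed ≤ the input's, and the balanced-subset boosting downstream
does not rely on exact balance.

## The ensemble

Two arms, one per base-learner family:

* random forest: 100 trees, `max_features = min(10, n_features)`;
* SVM: RBF kernel, C = 1, `gamma = 'scale'`. Class probabilities come
  from a sigmoid fitted on the decision values of a 20% internal holdout
  of each training subset (falling back to training decisions when the
  holdout cannot be stratified).

Each arm is an AdaBoost-style committee over class-balanced subsets.
Weights start at 1/n. Per round: draw `per_class_size` samples per class
(without replacement when the class is large enough, probability
proportional to weight; rows kept in original order), fit one learner,
compute its weighted error ε on the entire population. Members with
ε ≥ 0.5 are discarded and the draw retried (3 retries, then early stop);
accepted members get α = ½·ln((1−ε)/ε) with ε clipped to
[1e−6, 1−1e−6], so α is always finite; a member with raw ε ≤ 1e−6 ends
the loop. Defaults: 10 rounds; `per_class_size` = minority count of the
(resampled) training pool, i.e. subsets are as large as the minority
class allows.

Committees average member class probabilities with α-normalized weights
(uniform if Σα = 0). The ensemble averages the arms' probabilities
unweighted; argmax decides, and an exact 0.5/0.5 tie goes to the
minority class (configurable). With one round, a full-size subset and no
resampling, the RF arm reduces exactly to a directly trained random
forest — a tested identity.

An optional third arm of gradient-boosted trees (100 rounds, depth 3,
learning rate 0.1) can be enabled; the default is the two-arm
configuration. Hyperparameter search is deliberately minimal: an opt-in
deterministic grid over C ∈ {0.1, 1, 10} by 3-fold CV, instead of any
stochastic optimizer, to keep full-run determinism.

## Feature selection

* **χ²**: the standard nonnegative-feature selection statistic
  (class-conditional feature sums vs label-frequency-proportional
  expectations) on min–max-normalized values. Whether to discretize
  first is an open choice; continuous normalized values are used.
* **RFE-SVC**: linear SVC (C = 1), dropping `step` smallest-|w|²
  features per round; score = elimination round.
* **BoostFS**: gain importance of a gradient-boosted tree classifier
  (100 rounds, depth 3, learning rate 0.1, fixed seed); unused features
  score 0.
* **DEG selection**: per contrast, Welch two-sample *t* on (optionally
  log2) values with Benjamini–Hochberg adjustment across genes; a gene
  is differentially expressed at adjusted p < α (default 0.005).
  Direction is the sign of (condition mean − reference mean). The three
  contrasts follow the control-vs-patient / baseline-vs-year-1 /
  year-1-vs-year-2 design, each written (reference, condition); the
  selected set is the intersection of consistently up- (resp. down-)
  regulated genes across all three. This selector is a deliberate,
  documented stand-in for a moderated-*t* microarray pipeline: it
  operates on preprocessed expression matrices and makes no attempt at
  background correction, probe summarization or probe→gene mapping, so
  DEG *counts* from raw-array studies are not comparable.

All rankings break score ties by ascending feature index and are
deterministic given (data, seed). The cut-off sweep evaluates the
default ensemble at cut-offs 5, 10, …, 1000 (clipped and deduplicated).

## Evaluation

Accuracy, MCC, RMSE and F1 are computed from the confusion counts by
their definitions; conventions for degenerate cases: MCC = 0 when any
denominator factor is 0; F1 = 0 when TP = 0. RMSE defaults to hard 0/1
predictions (for which RMSE = √(1 − accuracy)); a flag switches to
positive-class probabilities. ROC thresholds every distinct score; AUC
is trapezoidal and equals the Mann–Whitney pair-counting statistic — the
test suite asserts this equivalence against an independent enumeration
oracle.

## Synthetic data

The generator draws Gaussian class-conditional features: majority
samples N(0, σ²) everywhere; minority samples shifted by +effect·σ in a
planted informative subset. Missingness is completely at random.
Three-contrast stage data plant genes shifted up or down in the
condition group of all three contrasts (plus optional single-contrast
extras), with disjoint truth sets. This is the simplest structure under
which every downstream claim — flagging, weak/strong partition, ranking
recovery, DEG intersection, ordering of methods — is analyzable.

What it does **not** emulate: heavy-tailed or discrete expression
distributions, feature–feature correlation, batch effects, probe-level
artifacts, or informative missingness. Passing the recovery and
ordering tests therefore demonstrates correctness of the algorithms
under their stated model, not performance on any particular real
dataset.

Benchmark problem sizes are desk-scale by design: the ordering checks
use 600-sample datasets with 50 features (10 informative) at imbalance
ratio 9 over 20 seeds; recovery checks use 1000 features with 10 planted
(effect 3 σ) and 30-per-group contrasts with 30 planted genes
(effect 4 σ).

## Known limitations

* The resampler's kNN flagging degrades in very high dimensions (noise
  features dilute Euclidean neighborhoods); with few weak seeds the
  balance target may not be reached (see above).
* Balanced-subset committees trade precision for minority recall. On
  nearly separable data this can cost a small amount of MCC relative to
  a single well-regularized classifier trained on the unbalanced data,
  while still improving minority recall substantially — the trade-off
  the method is designed to make.
* Binary problems only; multi-class imbalance is out of scope.
* The DEG selector assumes approximately normal within-group values at
  the tested scale (Welch *t*); counts are not comparable to
  moderated-*t* pipelines on raw arrays.
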