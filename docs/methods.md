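# Methods

## Models

**Single trees.** `train_cart` grows a binary classification tree by exact
greedy Gini reduction. Candidate thresholds are midpoints between
consecutive distinct sorted values of each feature; routing is "`x ≤
threshold` goes left"; ties in split quality resolve to the lowest feature
index, then the lowest threshold, so training is a deterministic function of
the data. Every node records its cover (training rows routed through it),
its Gini impurity, and its *value* — the class-1 fraction of the rows it
sees. The value is what the decomposition differences, so it must exist at
internal nodes, which is why the trainers are implemented here rather than
delegated: standard libraries expose leaf statistics in various forms but
not a decomposable internal-node expectation with controlled tie-breaking.

**Boosted ensembles.** `train_boosted` is Newton (second-order) gradient
boosting with a logistic loss: per round, gradients `g = p − y` and hessians
`h = p(1−p)` at the current margin; split gain is the standard regularised
second-order improvement with an L2 leaf penalty λ (default 1.0); leaf
weights are `−lr·G/(H+λ)`. Internal node values — again required by the
decomposition — are cover-weighted means of descendant leaf weights, with
cover the training row count. Node impurity records the label Gini so
impurity-decrease importances remain defined for ensembles. Defaults
(`n_trees=100`, `learning_rate=0.3`, `max_depth=6`, `base_score=0` in logit
space) mirror common boosted-tree practice.

The logistic function is evaluated as `(1 + tanh(m/2))/2`. Because `tanh`
is odd, complementing the labels negates every gradient bitwise and leaves
every hessian unchanged, so the flipped model's margins are the exact
negation of the original's. This makes the pipeline's class-symmetry
property (below) exact rather than approximate.

**Imported boosters.** `import_model_dump` reads the common JSON dump
dialect (`nodeid`/`split`/`split_condition`/`yes`/`no`/`leaf`/`cover`).
Internal values are reconstructed as cover-weighted descendant-leaf means;
for such dumps cover is a hessian sum and therefore fractional, which the
reconstruction uses as-is. The dialect routes "`x < t` to yes"; on import
thresholds become `nextafter(t, −inf)` so the predicate is identical to the
internal "`x ≤ t`" convention bit for bit, and export applies the inverse
map, making round trips exact. Dumps without cover statistics are rejected
with a pointer to re-export with statistics, since the decomposition is
undefined without internal expectations.

## Decomposition

For one sample the root-to-leaf path is walked once per tree; each internal
node contributes `value(child taken) − value(parent)` to the split feature.
Per-feature contributions sum over repeated splits on the same feature, and
`bias + Σ contributions` telescopes exactly to the raw output (leaf
probability, or total margin), a conservation identity tested to 1e-9 but
exact in float arithmetic up to associativity. Negative contributions
toward the predicted class are legitimate and are not clipped; direction
handling happens downstream.

`orient_to_predicted_class` re-expresses log-odds contributions as log odds
of the predicted class (negation for class-0 predictions). It is a
stateless map keyed on the predicted class, so applying it twice to a
class-0 decomposition restores the original values.

## The aggregation pipeline

Defaults: confidence threshold 0.7 (kept at equality — only predictions
*below* 70% are dropped), 5 stratified folds, seeded shuffling.

Choices where the procedure is genuinely open, and why:

* **Normalisation** divides by the number of retained predictions in the
  class partition, not the total sample count: the quantity reported is an
  average weight per (confident, correct) prediction.
* **Sign inference** uses the fold's *test* split class means. The
  alternative (training split) is equally defensible; the test split keeps
  the direction estimate out-of-sample and defined per fold. Exactly equal
  class means yield sign 0; the weight is zeroed and a warning logged
  rather than guessing a direction.
* **Cross-fold averaging** includes folds where a feature is absent (as 0),
  keeping magnitudes comparable across features; `fold_average="present"`
  switches to present-folds-only means.
* **Fold assignment** shuffles indices once with the seeded generator and
  deals them round-robin within each class. Unlike library stratified
  splitters, this partition is invariant under complementing the labels,
  which makes the pipeline's antisymmetry exactly testable: flipping
  `y → 1−y` exchanges the positive and negative signed weight vectors
  *bitwise*. (Oriented per-prediction weights are invariant under the flip —
  contributions negate, the predicted class flips, orientation negates
  again — partitions swap, and the sign rule's `s` negates while the
  negative class uses `−s`.) Note the exchange does not negate the vectors;
  with the orientation step the swap is sign-preserving.
* **Appearance** of a feature in a fold means the larger of its two signed
  class-weight magnitudes exceeds `appearance_epsilon` (default 1e-12);
  "was used by any split" is a different, looser notion not used here.
* The literal sign rule can disagree with intuition on particular datasets
  when aggregate orientation and class-mean direction interact; it is
  applied exactly as defined, and only weight magnitudes and fold counts
  should be compared across studies.

## Baselines

Gini importance is the normalised total impurity decrease per feature
(summed across trees for ensembles); non-negative, sums to 1, exactly zero
for unused features. Permutation importance shuffles one column at a time
(default 10 seeded repeats) and reports the mean and sd of the accuracy
drop; a log-loss variant is available. Partial dependence sweeps one or two
features over a grid — unique observed values up to the grid resolution
(default 50), otherwise equispaced quantiles, since "every possible value"
is impractical for continuous features — and averages the model prediction
with the swept features overwritten. More than two features are rejected;
that limitation is the point of comparison with the pipeline above.

## Synthetic data

`make_synthetic` emulates the target setting: a numeric table with a binary
label, a few informative features and many noise features. Labels are
Bernoulli(`class_balance`); all features are Gaussian with sd `noise_sd`;
each informative feature's class-1 rows are shifted by `mean_shift ·
noise_sd`, so the planted direction is the sign of `mean_shift`. Defaults
(n=500, 10 features, one informative feature with a +3 sd shift, balanced
classes) give a cleanly learnable problem whose ground truth a recovery
test can check. What it does *not* emulate: feature correlation,
non-Gaussian tails, label noise, interactions, or class imbalance beyond
the Bernoulli rate — so passing recovery tests demonstrate correctness of
the machinery, not robustness on messy real data. The reduced-scale
high-dimensional check uses 60 samples × 379 features, the size of a
parcellation-level connectivity study, rather than a full pairwise
connectome; scaling beyond that is linear in features per split search.

The iris table is the canonical 100-row versicolor/virginica subset
(versicolor = 0, virginica = 1), loaded from scikit-learn's bundled copy.

## Numerical conventions and degenerate inputs

* Missing/non-finite cells are rejected everywhere; no surrogate routing.
* Single-class labels raise "degenerate labels" at training and fold
  construction.
* Split search requires a strict quality improvement (> 1e-12); otherwise
  the node becomes a leaf.
* Midpoint thresholds are clamped back to the left value when floating
  rounding would land them on the right value.
* Empty class partitions after filtering yield zero weights with a logged
  warning; F1 returns 0 with a warning when its denominator is empty.
* ROC AUC is the midrank Mann–Whitney statistic, so ties are handled
  exactly and constant scores give 0.5.

## Limitations

* Binary classification only; no multiclass softmax attribution, no
  regression objectives.
* The linearised view assumes contributions are comparable across paths;
  strongly interacting features distribute credit along whichever split
  order the trees happened to choose.
* Attributions are not SHAP values: credit follows the realised decision
  path, not an average over feature coalitions.
* Imported models must carry cover statistics; missing-value ("default
  direction") routing in dumps is not honoured since missing inputs are
  rejected anyway.
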