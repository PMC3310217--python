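# Methods

## Model and inference

A classification tree routes a record down binary splits
`x[feature] <= rule` (a record exactly at the rule goes left) to one of k
leaves. Each leaf j holds the class counts n_j1..n_jC of the training
records reaching it and a Dirichlet(1,…,1) prior over its class
probabilities, so its marginal likelihood is the Dirichlet-multinomial

    Γ(C) · ∏_c Γ(n_jc + 1) / Γ(n_j + C),

the tree's marginal likelihood is the product over leaves, and the leaf's
predictive class probabilities are the posterior means (n_jc+1)/(n_j+C).
The tree prior is uniform over *valid* trees: every leaf holds at least
p_min training records (the pruning factor), the tree has at most s_max
splits (default n−1), the splitting feature is any attribute with at
least two observed values, and the rule is any observed value of that
feature. No explicit depth penalty is imposed; the leaf-size floor and
the marginal likelihood's built-in complexity penalty control tree size.

Sampling uses a reversible-jump chain with four moves, chosen with
probabilities (0.15, 0.15, 0.10, 0.60):

- **birth** — pick a leaf uniformly, split it with a feature and rule
  drawn from the priors;
- **death** — pick uniformly among splits whose both children are leaves
  and merge them;
- **change-split** — pick a split uniformly, redraw feature and rule from
  the priors (a "large" jump);
- **change-rule** — pick a split uniformly and move its rule a discrete
  number of steps along the sorted observed values of its feature, the
  step drawn as a rounded zero-mean Gaussian with sd = proposal_scale ×
  L/100 (L = number of observed values), magnitude clamped to [1, L]
  (a "local" jump). The quoted proposal variance of 1.0 is interpreted as
  this rank-space scale; the interpretation is a design choice, since a
  variance on raw feature units would depend on each feature's scale.

Acceptance is Metropolis-Hastings-Green:
min{1, exp(Δ log marginal likelihood + log prior ratio + log proposal
ratio)}. With the uniform tree prior the prior ratio is 1; the proposal
ratios account for the number of leaves, prunable splits, splittable
features and per-feature rule counts. Proposals that would produce an
empty child or violate p_min auto-reject but still count in the
acceptance-rate denominator. A rank step falling off either end of the
value list also auto-rejects — clamping instead would break the
symmetry of the change-rule kernel. Because these ratios are easy to get
subtly wrong, the sampler has a validation mode (`likelihood="flat"`)
that replaces the likelihood with a constant; the chain must then sample
the uniform tree prior, and the test suite compares its leaf-count
distribution against exhaustive enumeration of all valid parameter
tuples on a small dataset (total-variation distance below 0.05).

Chains start from a single randomly drawn valid split, discard a burn-in
phase, then collect every `thin`-th state of the post-burn-in phase.
Full-scale defaults are 200,000 / 10,000 / 7 (≈1,428 trees); the
experiment harness defaults to a desk-scale 5,000 / 2,000 / 7 (285
trees), which on the synthetic tables reaches the same qualitative
behaviour in about a second per chain. "10,000 collected" is read as
10,000 post-burn-in iterations with every-7th retention, the reading
consistent with per-iteration thinning; burn-in likewise counts
iterations, not accepted moves.

## Prediction, importance, refinement

The predictive distribution is the unweighted mean of the per-tree leaf
probabilities (Bayesian model averaging); the predicted class is the
argmax, ties broken to the lowest class index for determinism.
Posterior feature importance is counted at the split-node level: the
frequency of feature j is the number of split nodes testing j across the
whole ensemble divided by the total number of split nodes, so the
frequencies sum to one. Node-level counting is the only convention
consistent with reported per-feature frequencies in the 0.0–0.07 range
for ~30-node trees over 72 features; tree-level counting would
concentrate far more mass per feature. Features with frequency strictly
below a threshold T are *weak* (strict inequality makes T = 0 the
identity), and refinement discards every tree containing a split on any
weak feature. Weak sets are nested increasing in T and refined ensembles
nested decreasing; refinement that would empty the ensemble raises an
error reporting zero survivors rather than returning an invalid object.

Uncertainty is summarised as the total Shannon entropy (base 2) of the
averaged predictive distributions over a test set, bounded by
n_test · log2 C. Base 2 matches the magnitude of the reference
uncertainty values this statistic is modelled on (a maximum of ≈592 bits
for 229 six-class records); natural log would cap below the values seen.

## Evaluation harness

Stratified 3-fold cross-validation; reported intervals are ±2 sample
standard deviations across folds (ddof = 1). The threshold sweep runs
one chain per fold and, for each T in {0, 0.001, …, 0.005}, scores
(a) the refined ensemble (no re-sampling), (b) a fresh chain on data
with the weak features deleted, and (c) a greedy single tree on the same
reduced data. Weak features at each (fold, T) come from that fold's
unrefined ensemble, so the weak count k is common to the three
techniques. Fold chains reuse the same derived seeds as plain
cross-validation, making the T = 0 refine row exactly reproduce it.

The greedy baseline grows a tree top-down, choosing the split that
maximises the same Dirichlet-multinomial marginal-likelihood gain the
sampler uses (Gini impurity is available behind `criterion="gini"`),
stopping when no split satisfies p_min or improves the criterion. Using
one scoring function keeps a single likelihood under test; it also makes
the baseline deterministic (ties break to the lowest feature, then the
lowest rule).

## Spectral features

Band powers come from a single rectangular-window FFT per analysis
window: one-sided periodogram mass |X(f)|²/N summed per band, with the
half-open convention [lo, hi) — a bin exactly at a band edge belongs to
the upper band — and the last band closing at 25 Hz. Because the six
bands tile 0–25 Hz, their powers sum exactly to the total power in that
range (Parseval), which the tests assert to 1e−6 relative. Epoch-level
features use ten one-second sub-windows of a 10 s epoch: power features
are means across sub-windows, variance features population variances of
the same quantities. Recording-level features apply the same
mean/variance construction across whole epochs; this is the default mode
for classification, and both modes are exposed because the source
protocol is ambiguous about whether one feature vector summarises an
epoch or a recording. Relative powers are normalised within one location
over the six bands and sum to one whenever the total power is positive.

## Synthetic data

The signal generator emits two channels of band-centre sinusoids
(Subdelta 0.75 Hz, Delta 2.5, Theta 5.5, Alpha 10.5, Beta1 16.5, Beta2
22.25) plus independent white Gaussian noise per channel, at 100 Hz for
10 s by default. Sinusoids at band centres — rather than band-limited
noise — make the expected band powers analytic, so the feature extractor
can be checked in closed form.

The table generator emulates the study corpus shape: C = 6 classes,
100 records per class, m = 72 features, of which an index set (default
the first ten) is informative with class means spaced effect_size ×
noise_sd apart, increasing monotonically with the class index (spectral
maturity changes monotonically with postconceptional age); all other
features are i.i.d. Gaussian noise, identically distributed across
classes. Defaults: effect size 1.5, unit noise SD. These choices are a
declared stand-in, not an inference about real EEG: real feature
distributions are correlated, heavier-tailed, and nonstationary across
sleep states, and none of that is modelled. Passing tests on these
tables therefore demonstrates the correctness of the machinery and the
direction of the refinement effect under planted structure — not
clinical-grade accuracy on real recordings. One consequence of the
axis-aligned, monotone planted structure is that the greedy single tree
is an unusually strong baseline on synthetic tables, unlike on real EEG
data where single-model selection is noise-sensitive.

## Numerical choices and degenerate inputs

- Leaf marginals use log-gamma throughout; an empty leaf has marginal 1
  (log 0), and an empty ensemble, an all-leaf ensemble (undefined usage
  denominator), a single-epoch recording (undefined variance) and a
  mismatched prediction/label length all raise informative errors.
- A dataset admitting no valid split under p_min yields a single-leaf
  chain with a warning rather than an exception.
- Chains, generators and fold assignments are all driven by explicit
  seeds; identical seeds give byte-identical serialized outputs.
- Ensembles serialize to JSON (nested nodes with feature, rule, children
  and leaf counts), tables and reports to CSV.

## Known limitations

- Single chain per fit; no cross-chain convergence diagnostics (R-hat),
  adaptive proposals or tempering.
- The acceptance rate is data-dependent: on the easy synthetic tables it
  sits near 0.5, higher than on hard real-world data where it is
  reported around 0.13, because proposals that improve the likelihood
  are found more often.
- No artifact handling, filtering, re-referencing or sleep staging; the
  spectral module assumes clean fixed-length two-channel segments.
- Weighted (non-uniform) model averaging and diversity-based ensemble
  cutting are out of scope.
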