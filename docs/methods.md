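# Methods

## Model and procedure

`permsig` treats biomarker discovery as a feature-importance problem for an
ensemble of classifiers rather than a collection of univariate tests.  The
data model is a dense two-class expression matrix (samples × features,
positive = case/tumor).  The pipeline has five stages — balanced division,
iterated resample/train/score rounds, mixture thresholding, vote-ensemble
classification, and a repeated-division stability layer — described in the
README; this note records the assumptions, parameter choices and numerical
behaviour behind them.

### Balanced error and permutation scores

All model selection inside the pipeline uses the balanced error rate,
`(FN/(TP+FN) + FP/(TN+FP))/2` — the mean of the two class-conditional error
rates.  It is invariant to class imbalance given fixed per-class error rates,
which matters because the intended cohorts are heavily imbalanced (the
default synthetic conditions mirror a 539-case / 72-control cohort).

The per-round score of feature *i* is `Err~ − Err`: the winner of the round
is **not retrained**; only its evaluation-partition column *i* is permuted.
Retraining per feature per round would multiply the cost by the feature count
and answer a different question (importance to the model *class*, not to the
*fitted* model).  One fresh permutation is drawn per feature per round;
averaging happens across rounds.  Permutations are drawn in feature-index
order from a per-round generator, so the vectorised batch path, the
per-feature API, serial execution and any `--jobs` setting all produce
bit-identical scores.

### The classifier pool

Seven members in a fixed order — DTC, MNB, KNN, LDA, LR, MLP, SVM — which is
also the tie-breaking order when two members reach the same evaluation error.
Hyperparameters (config-overridable) are deliberately modest, since each
member is refitted in every round: KNN uses 5 neighbours; the MLP has a
single 16-unit hidden layer trained by L-BFGS (capped at 150 iterations); the
SVM uses a linear kernel; logistic regression runs L-BFGS capped at 200
iterations.  Members that raise during fitting are skipped with a logged
warning; multinomial naive Bayes is skipped automatically when the matrix
contains negative values, since it is defined for non-negative data.
Expression values pass through unchanged by default (no normalisation); a
`log2(x+1)` load-time flag exists for count-like data.

### Winner-selection optimism: why null scores are not centred on zero

A property worth knowing when interpreting score scatter plots: under a
global null (no feature associated with the labels), accumulated scores are
**not** centred on zero but carry a small common positive offset.  The
winner is chosen as the error *minimum* over seven members on the very
evaluation partition the permutation is scored on, so `Err` is optimistically
biased; permuting any feature partially re-randomises the winner's
predictions and regresses its error toward chance, making `Err~ − Err`
positive in expectation for every feature.  Measured on null data (40+20
samples, 30 features, 300 rounds) the offset is ≈ +0.014 with a
seven-member pool and vanishes (≈ +0.0002) when the pool has a single member
and no selection step.  A second, smaller effect is dataset-level spurious
feature–label correlation, which repeated rounds on the same split cannot
average away.

Consequently the per-feature Monte-Carlo standard error is *not* a valid
null band around zero, and the package does not advertise one.  The
selection stage is insensitive to this: the mixture boundary lies between
the low (bulk) and high (marker) score clusters, and selection is equivariant
under a common translation of all scores.  The stability layer's
intersection-across-divisions removes features whose apparent importance was
split-specific.

### Mixture thresholding

The two-component 1-D Gaussian mixture is fitted by a transparent,
hand-written EM: initialisation from a seeded 2-means partition (neither
side allowed to be a singleton), convergence when the relative
log-likelihood change drops below 1e−8 (cap 500 iterations), and a recorded
log-likelihood trace that is non-decreasing by construction — asserted in
tests, with `sklearn.mixture.GaussianMixture` as an independent cross-check
of the fitted means.  The threshold is the root of the weighted
log-density equality (a quadratic) that lies strictly between the component
means; if no crossing lies there (extreme weight/variance combinations) the
midpoint of the means is used and a warning logged.  Selection uses a strict
`>` at the threshold.

Degeneracy handling: a component variance falling below 1e−12 aborts the fit
with advice to run more rounds or pass `--threshold` manually.  This arises
genuinely at low round counts, where many features accumulate *exactly* zero
(no round's winner ever responded to their permutation) and the score
distribution contains a point mass no Gaussian component can describe.  At
the intended operating scale (thousands of rounds) the point mass dissolves.
The boundary between two well-separated narrow components is sensitive to
the estimated component SDs — the equal-density point between clusters many
SDs apart moves with the SD ratio — so boundary accuracy is only meaningful
at realistic score-sample sizes (hundreds to thousands of features).

### Ensembles and voting

An ensemble on a feature subset keeps the best-of-pool member of each
resampling round, with no filtering of weak rounds.  Classification is an
unweighted majority vote; the vote fraction doubles as the ROC score (the
combination rule is config-exposed in the sense that the threshold can be
swept).  A 50/50 vote tie at the default threshold goes to the positive
class.  Incremental-dimension ensembles reuse the same root seed per prefix,
so the size-K model is identical to building on the full ranking directly.

### Metrics and tables

Per-class metrics follow the standard one-vs-rest layout: each class is
designated positive in turn, and a support-weighted row summarises the two.
Full precision is kept internally; the published-style table renderer rounds
half-up to three decimals and computes the weighted row from the *rounded*
per-class cells, so the printed summary is self-consistent with the printed
per-class rows.  Precision with an empty predicted-positive set is reported
as 0 with a flag.  ROC curves collapse tied scores into single threshold
steps; AUC is the trapezoidal area and equals the Mann–Whitney pair
statistic with ties counted 1/2 (asserted to 1e−12 against exhaustive pair
counting).

### Stability layer

R divisions run with independently derived seeds (`SeedSequence` mixing of a
root seed and the division index).  The core set is the intersection of the
per-division selections, ordered by mean accumulated score.  Ranks are
positions within each division's *full* selection, and the signature keeps
features whose **median** rank across divisions is ≤ k (ties broken by mean
rank, then feature id; truncated at k).  Median rather than minimum or mean
is used because a single lucky division should not promote a feature.  The
subset screen enumerates all non-empty combinations of a small panel
(capped at 12 features) with a shared root seed so subsets differ only in
their features.

## Synthetic data

The generator emulates what the method assumes about real cohorts: heavy
class imbalance (defaults 539/72), a small planted marker set with a
location shift of `effect_size` noise-SDs on the log scale, exchangeable
noise features, and optionally exactly-constant decoy features (mirroring
zero-variance features that upstream pipelines leave behind).  Log-normal
noise is the default — non-negative and right-skewed like expression
quantifications, with `effect_size` reading as a log-fold-change in SD
units; a Gaussian variant (the log-scale values themselves) exists for
classifier-theory checks.  The platform-pair generator draws two cohorts
from the same structure and multiplies designated features of the second by
a scale factor, emulating cross-platform scale mismatch.

What the generator does **not** model: count discreteness and
zero-inflation, correlated feature blocks, batch effects beyond a scale
factor, and label noise.  Passing tests therefore demonstrate that the
implementation recovers planted structure under the method's own
assumptions, not that the method is robust to everything real data does.

## Problem sizes and defaults

Desk-scale defaults are 2,000 scoring rounds and 200 ensemble rounds; the
full-scale settings used for the original application are 1×10⁵ and 1×10⁴ —
the estimator is a mean, so more rounds narrow the Monte-Carlo error without
changing its target.  Test and acceptance runs use 150–1,000 scoring rounds
on matrices of 30–200 features, sizes at which every qualitative property
(marker ranking, mixture separation, signature recovery) is already stable
for the planted effect sizes used.  Defaults: split fraction 0.5, resample
fraction 0.7, R = 10 divisions, k = 5, EM tolerance 1e−8, variance floor
1e−12.

## Known limitations

- Correlated markers share credit: permuting one of several redundant
  features may not raise the error, deflating all of their scores.
- The null offset described above means raw accumulated scores should not
  be read as calibrated test statistics; only their relative ordering and
  the mixture split are interpreted.
- The EM threshold assumes the score distribution is well described by two
  Gaussian components; heavy bimodality inside the null bulk (e.g. the
  exact-zero point mass at low round counts) is rejected as degenerate
  rather than modelled.
- Cross-platform transfer is only addressed diagnostically (the subset
  screen); no calibration or batch correction is attempted.
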