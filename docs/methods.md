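# Methods

## Model and procedure

`drcomb` develops binary classifiers for expression data in the p ≫ N
regime as a three-level hierarchy over a labeled development cohort.
Class 1 is, by convention, the clinically positive group (e.g. alive at
the survival horizon); every score in the package is oriented so larger
means more class-1-like.

**Split realizations.** The development set is partitioned many times
into a training and a test portion, stratified by class: each realization
draws ⌊f·N/2⌋ samples per class into training (f = 2/3 by default),
capped at (smallest class size − 1) so unbalanced cohorts undersample the
majority class; everything else is the test portion. Equal training
class counts avoid an intercept bias in the logistic combination below.

**Atomic classifiers.** Within one realization, a kNN classifier with
fixed odd k is fitted on every candidate feature subset (all singles and
pairs by default; singles/pairs/triplets are supported). Distances are
Euclidean on raw values or on per-feature ranks. The rank variant maps
each feature to the rank of its value within the atomic classifier's own
training set; a query value maps to #below + (#ties + 1)/2 when it ties
training values (so a training point keeps its own average-tie rank) and
to #below + 1 otherwise. This makes the classifier invariant under any
strictly monotone per-feature transform — the property that matters when
raw features and synthetic noise features live on different scales.
Distance ties at the neighborhood boundary are resolved deterministically
in favor of the lower training-row index.

**Filtering.** An atomic classifier is admitted to the combination only
if its training accuracy a satisfies ℓ < a ≤ u. Because a is measured on
the classifier's own training set (with the sample participating in its
own neighborhood), it is over-optimistic by construction and is used
purely as an admission gate, never as a performance estimate. The bounds
can be given directly or derived from a target pass fraction (default
25%): ℓ is then the (1 − target)-quantile of the candidate accuracy
distribution, lowered to the next distinct accuracy when ties would empty
the pass set. In hierarchical enumeration (singles, then pairs over
filter-passing singles) the quantile is computed per candidate family:
pairs fit their training set systematically better than singles, so a
singles-derived bound would admit nearly all pairs and defeat the
25% heuristic.

An optional **external filtering set** — unlabeled samples that cannot
be used for training, either a held-out slice or a separate cohort — adds
a second gate: the fraction of external samples a classifier assigns to
the class of interest must lie in [pℓ, pu]. A classifier that has learned
a confounder rather than the endpoint classifies a single-confounder-
stratum external set lopsidedly and is rejected; sweeping pℓ upward
progressively removes confounder-leaning classifiers. The external set
never enters logistic fitting or performance estimation.

**Dropout-regularized combination.** The survivors' binary outputs (0/1
classifications, not vote fractions) are combined by logistic regression
under dropout: for each of I iterations, d distinct atomic classifiers
are drawn uniformly without replacement, a logistic regression of the
training labels on those d columns is fitted, and the fitted coefficients
accumulate into the drawn classifiers' slots. The final weight of
classifier j is its accumulated sum divided by I (iterations where j was
not drawn contribute zero), and the intercept is the mean over
iterations; dividing by the selection count instead is available as an
option (`average_over="draws"`). Averaging over all iterations is the
default because it keeps the total weight mass bounded as the pool grows
and matches the expectation-scaling reading of dropout; classifiers never
drawn have weight exactly zero, which at very large pool sizes acts as an
additional within-bag feature selection.

**Bagging and out-of-bag estimation.** One base classifier per
realization yields the master classifier, whose continuous output is the
mean of the base outputs (the ensemble averages continuous logistic
outputs, not thresholded votes). A development sample's out-of-bag (OOB)
score averages only bases from realizations that held it in the test
portion; at 325 realizations and f = 2/3 each sample is in test over 100
times on average. AUC is the exact Mann–Whitney probability with ties
credited 0.5 — identical to the trapezoidal area under the empirical ROC
curve, which is stored alongside for plotting. A binary test is obtained
by thresholding the master score; `select_threshold` offers Youden-J
maximization (midpoint between consecutive distinct scores, lowest
maximizer on ties) or a fixed threshold.

## Parameters

| parameter | default | notes |
| --- | --- | --- |
| n_realizations | 325 | each sample lands in test >100 times at f = 2/3 |
| train_fraction f | 2/3 | trade-off between training representativeness and split diversity |
| k | 7 (9 for single-feature problems) | odd only — even k invites vote ties; deliberately not tuned |
| max_order | 2 | singles + pairs; hierarchical mode restricts pairs to passing singles |
| pass fraction | 0.25 | "wide" filtering; admission, not selection |
| d | 10 | per-iteration draw; must stay below the training size, use smaller d for small pools |
| I (dropout iterations) | 100,000 | enough that each classifier is drawn ~10–100 times for pools up to ~10⁵ |
| ridge ε | 1e−6 | separation safeguard on non-intercept weights; perfect separation is routine at d = 10 on small balanced training sets |

Tests, examples, and the acceptance script scale n_realizations (25–60),
I (300–2,000), and cohort sizes down so that a full study runs in
minutes; the production defaults above are never silently altered.

## Numerical choices

* The many-subset kNN sweeps run through a single vote kernel (a numba
  routine with a pure-numpy equivalent fallback) that computes the k-th
  smallest distance exactly and admits boundary ties in training-row
  order; it agrees with a brute-force stable sort by (distance, index)
  to the last bit, which the test suite verifies on thousands of random
  instances.
* Logistic fits use a damped Newton solver (batched across dropout
  iterations) on the ridge-penalized deviance, with backtracking line
  search, a 1e−10 Hessian jitter for solvability, convergence declared
  at max|gradient| ≤ 1e−9, and a hard error past 200 iterations. The
  solver matches statsmodels (unpenalized) and scikit-learn (ridge) to
  ≤ 1e−6 on reference problems; with d = |pool| and one iteration the
  dropout combination reproduces a direct logistic fit to 1e−8.
* All randomness flows from a single seed through
  `numpy.random.SeedSequence` spawning (splits, per-realization dropout
  streams, per-tree seeds), so serial reruns are bit-identical and
  per-realization work is order-independent.
* Missing values are a load-time error; no imputation exists in the
  package. Exactly-at-horizon survivors dichotomize to class 1. Feature
  intersection orders features lexicographically.

## Baselines

Random Forest is assembled from the same stratified realizations: one
CART tree (Gini, grown to purity, scikit-learn's implementation) per
realization, trained on that realization's bag without resampling —
stratified bags keep the forest's OOB estimate reliable at small N. The
per-node feature draw is round(√N_train), or round(N_train/3) when the
development set has ≤ 30 samples per class (≤ 20 per class in training);
the rule is interpreted on the training-bag sample count, since its
trigger is phrased in training counts. The forest's continuous output
averages hard 0/1 tree votes, full-ensemble or OOB. Single kNN scores a
sample by its class-1 neighbor count among k (resubstitution on the
development set, deliberately optimistic); single logistic regression
uses the same ridge-safeguarded solver. Bagged kNN/logistic average
per-realization continuous outputs with OOB bookkeeping. Welch's
unequal-variance t-test (pooled-variance by flag) ranks features for
selection; for bagged learners selection is recomputed inside each bag
to avoid leakage, for single learners it uses the whole development
subset, matching their resubstitution evaluation.

## Synthetic fixtures: what they do and do not show

The generators produce two-class Gaussian data: informative features
shift their class means by a standardized effect size δ (single-feature
population AUC Φ(δ/√2)), noise features are N(0,1), and validation
cohorts are drawn i.i.d. from the same population, larger than
development to stabilize AUC estimates. The confounded design adds a
hidden binary confounder c associated with the class in development
(P(c = 1|y) = 0.5 ± a/2) but not in validation, a feature block shifted
by c, a mixed block shifted by both y and c at half strength (real
transcriptomes contain genes associated with both the endpoint and, say,
histology — these partially confounded features are what progressively
tighter external filtering keeps pruning), and an external set drawn
from the c = 0 stratum only with a balanced, alive-leaning true-class
mix. The acceptance fixture uses a = 0.7, echoing the squamous-histology
skew of the motivating clinical problem, with 600 features so that harsh
external filtering never empties the candidate pool.

Features are independent Gaussians: the fixtures exercise
dimensionality, sparse signal, and confounding structure, not microarray
noise, gene–gene correlation, or batch effects. Passing tests therefore
demonstrate the estimator's honesty and the filter mechanics under the
stated statistical structure; they do not certify performance on any
real cohort, and batch correction (e.g. empirical-Bayes adjustment) is
expected to happen upstream of the loader.

One statistical limit is worth stating explicitly: with 40 samples per
class, a development-set AUC — OOB or otherwise — carries a standard
deviation near 0.1 under the null, because it is computed on 80 samples
whose ensemble scores are correlated through shared training subsets.
The OOB estimate is unbiased (its mean over seeds sits at 0.5 on pure
noise, and at very small cohort sizes it tends, if anything, to
underestimate), but any single-seed OOB AUC at this size should be read
with that spread in mind.

## Known limitations

* Filtering metrics other than binary training accuracy (hazard ratios,
  continuous outcomes) are not implemented; the filter bound structure
  is the extension point.
* Subset enumeration is exhaustive up to triplets; no sampled or
  approximate exploration of larger subsets.
* The loader accepts delimited text only; converting repository formats
  (e.g. GEO series matrices) to the matrix + annotation CSV layout is a
  documented external step: export the expression table with samples as
  rows (or pass `orientation="features_as_rows"`), and a
  `sample_id,label[,time,event]` annotation file.
* Training is serial; per-realization RNG substreams make a parallel
  implementation safe, but none ships.
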