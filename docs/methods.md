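# Methods

This note documents the model, the simulator, the numerical choices, and
the limitations of `ketodetect`. It describes what the code computes;
every empirical statement here is one the test suite or
`scripts/acceptance.py` recomputes.

## The dissimilarity and its learned weights

The core object is a dissimilarity between equal-length series
a, b ∈ Rⁿ,

    D(a, b; W, p) = ( Σᵢ Σⱼ |aᵢ − bⱼ|ᵖ Wᵢⱼ )^(1/p),

i.e. *every* index pair contributes, weighted by W. Unlike elastic
measures (DTW), it needs no alignment and is a single einsum; unlike the
plain Manhattan distance, off-diagonal weights can reward or punish
cross-hour structure. The package fixes the pointwise term to the
absolute difference and p = 1 in the pipeline; general p is kept in the
library but requires non-negative weights (signed p-th roots are
undefined). For diagonal positive weights and p ≥ 1 the function is a
weighted Minkowski metric; with a general sign matrix it is a learned
*dissimilarity*, not a metric, which is fine for nearest-centroid use.

The weights are learned from the two class-mean series h (healthy) and s
(sick):

    Gᵢⱼ = sign( min(|hᵢ−sⱼ|, |sᵢ−hⱼ|) − max(|hᵢ−hⱼ|, |sᵢ−sⱼ|) ),

+1 where the smallest between-class gap at an index pair exceeds the
largest within-class gap, −1 where it is dominated, 0 on ties
(sign(0) = 0, which matters when the class means coincide). G is
symmetric by construction, so D is symmetric in its arguments.

**Blend orientation.** G is blended with the identity as
W(λ) = (1−λ)G + λI, λ ∈ [0,1]: λ = 0 uses the raw sign structure and
λ = 1 recovers the Manhattan distance exactly. The search grid is the
sorted union {2⁻ⁱ} ∪ {1−2⁻ⁱ}, i = 0..15 — 31 values crowding both
endpoints, so the search can land arbitrarily close to "pure Manhattan"
or "pure sign structure" while also probing the middle.

## Per-stream classifiers and the ensemble

Each of the five behaviour streams gets its own nearest-centroid
classifier (NCC): an animal takes the label of the nearer class-mean
series under D with W(λ). NCC was chosen for the same reasons one would
choose it in any imbalanced screening problem: it has no per-example
memory, so duplicating majority-class examples does not move its
decision boundary (a property the tests check directly).

λ is selected per stream by leave-one-out (LOO) balanced error
1 − (Sens+Spec)/2; ties are broken toward the **largest** λ, i.e. toward
the Manhattan regime, the less structured hypothesis. Inside the LOO
loop the held-out example's own-class centroid is recomputed by the
exact downdate (mean·n − x)/(n−1); the sign matrix is built **once**
from the full training fold — it is a one-time construction from the
training set, and rebuilding it per split (available via
`rebuild_sign_matrix=True`) changes little but costs a factor ~n. The
hot path exploits that W(λ) is affine in λ: per example/centroid pair
only two scalars are needed (the double sum against G and the Manhattan
term), after which all 31 grid values are linear combinations; the
scalar pass is a numba kernel whose exact agreement with a naive
double-loop implementation is pinned by tests.

A test animal is labelled at this stage only when at least 4 of 5
stream classifiers agree (`votes_required=5` gives the strict,
unanimous variant). Distance ties resolve toward *sick*: in a screening
context a missed sick animal costs more than a false alarm. Animals
missing one or more stream weeks simply contribute fewer votes and
therefore tend to fall through to the feature stage; with two or more
streams missing a 4-of-5 quorum is unreachable by construction.

## Feature stage

Features are ranked by the original deterministic two-class Relief: one
full pass over all complete-case training examples, nearest hit and
nearest miss by Manhattan distance on min-max-normalised features,
weight accumulation |x−miss| − |x−hit| averaged over examples. The
deterministic full pass (rather than the sampled m < n variant) was
chosen for reproducibility; ranking ties keep schema order.

The number of top-ranked features is picked by an inner stratified
10-fold CV on the complete cases, scoring a Gaussian naive Bayes on mean
balanced accuracy over prefixes k = 1..K; ties go to the smallest k
(parsimony). When the minority class has fewer than 10 complete cases
the fold count shrinks to that count (at least 2 per class required).

The naive Bayes itself is deliberately simple: per class and feature a
Gaussian fitted on whatever values are *available* (so partially missing
training rows still contribute), empirical class priors (a uniform-prior
flag exists), and at prediction time missing features simply drop their
likelihood terms — the posterior equals that of a model that never
included the feature, an exact identity the tests assert. All features
are treated as Gaussian, including the ±1-coded parity: the schema
metricises ordinal/nominal measurements, and a single uniform treatment
keeps the omission identity exact. Variances are floored at 1e−9 times
the largest fitted variance so constant features stay usable. The
decision rule is sick iff posterior ≥ threshold (default 0.5); the ≥
convention makes the tuned threshold — the ⌈target·n_sick⌉-th largest
sick training posterior — an attained maximum achieving the requested
training sensitivity. Animals with *no* observed feature at all receive
the configured fallback label (default healthy, the majority class) and
are counted separately in the report.

## Cross-validation and reporting

The outer loop is a stratified 10-fold CV (per-class shuffle +
round-robin deal from a random starting fold, so per-fold class counts
differ by at most one); λ, G, Relief, the feature count and the naive
Bayes are all fitted strictly inside the training fold. Out-of-fold
predictions are pooled into a single confusion matrix — results are
added up, not averaged per fold — and scored with the usual battery.
Lift is precision over prevalence. Per-fold selected λ (per stream) and
chosen features are logged and retained in the report;
`selection_frequencies` aggregates how often each feature entered the
final naive Bayes across folds and experiments.

Mann–Whitney U (two-sided, mid-rank ties) uses the exact null
distribution of U (standard rank-sum recursion) for samples of ≤ 20 per
group without ties, and the tie-corrected normal approximation with
continuity correction otherwise; full permutation enumeration under ties
is infeasible, so tied small samples also use the approximation. The
implementation is cross-checked against `scipy.stats.mannwhitneyu` in
tests but does not call it.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes,
with defaults fixed at the documented study conditions: 15.8% prevalence
(106/671), 168 hourly bins per week, per-class feature means/SDs at
their published values, and published per-feature missingness rates
(31.45/11.03/1.19% for the three BCS–BFT visits, 1.79% NEFA, 0.15% milk
yield and parity, 26.23% for the location block, 0 elsewhere).

* **Streams.** Lying and rumination are a diurnal sinusoid + class
  offset + i.i.d. Gaussian noise (SD 6 min/h), clipped to [0, 60]. The
  activity trio is drawn as a Dirichlet composition (concentration 60)
  centred on class-specific proportions and scaled by 60, so
  inactive + active + highly-active = 60 holds *exactly* by
  construction, never by clipping.
* **Class offsets** (sick − healthy, min/h): lying +2, ruminating −4,
  inactive +3, active −2.4, highly active −0.6 (the trio offsets sum to
  zero to preserve the budget). The published per-stream magnitudes are
  shown only graphically in the source material, so these were fixed
  once at magnitudes a herd-health researcher would call realistic —
  sick cows ruminate less, lie more, and shift activity toward
  inactivity.
* **Between-animal heterogeneity.** Each animal carries a random
  intercept (SD 3 min/h) per stream family, applied along the
  budget-preserving direction for the trio. This is the feature of real
  sensor data that keeps stream classification non-trivial: hourly noise
  averages out over a 168-hour week, but an individual cow's habitual
  level does not.
* **Features** are class-conditional Gaussians truncated to their
  schema ranges by re-drawing tails; the underlying location is solved
  (Brent root-finding on the truncated-normal mean) so the *realised*
  class means sit on the published values even for heavily truncated
  features such as heat-stress hours. Realised SDs of strongly
  truncated features are somewhat below nominal; means are exact.
  Parity is a ±1 Bernoulli whose class means match the published ones.
* **Missingness** is MCAR: one draw per BCS–BFT visit pair (the two are
  measured at the same farm visit), one block draw for the nine
  location features (a single positioning source), independent draws
  elsewhere. Informative missingness is out of scope — the source
  material documents rates, not a mechanism.
* A `correlation` knob (default 0) couples a per-animal severity latent
  into both stream and feature effect sizes; the true within-animal
  coupling on farm is unknown, so the default asserts none.
* BHB emission is off by default; when on, day-3/5/8 values are drawn
  consistently with the >1.2 mmol/L case definition and labels are
  derived through `label_from_bhb`, keeping the labelling rule
  exercised end to end.

**What passing tests show — and don't.** Because the cohorts are
synthetic, pipeline-level results demonstrate *correct mechanics and
sane statistical behaviour* (chance level under label permutation,
recovery of planted signal, nominal type-I error), not field
performance. The generator omits oestrus and calving-related behaviour
bursts, weather-driven non-stationarity, autocorrelated sensor dropout,
and real covariance between streams; published headline numbers from
the original proprietary cohort are therefore not reproduction targets,
except for the identities recomputable from printed inputs.

## Problem sizes and numerics

Test and acceptance runs use cohorts of 400–671 animals (20 replicates
for permutation nulls), 1000 random pairs for the Manhattan-limit check
(tolerance 1e−10), 10⁴ random triples for the metric axioms, and 2000
replicates for the Mann–Whitney type-I rate — sizes chosen so the whole
battery runs in a few minutes on one CPU while keeping Monte-Carlo
error well inside the asserted bands. Distance computations are exact
einsums; the only approximations anywhere are the normal approximation
of the U test outside the exact regime and the variance floor in the
naive Bayes.

## Known limitations

* The sign matrix is learned from class means only; heavy-tailed or
  multi-modal stream distributions would blur it.
* Relief and the feature-count CV use complete cases only (by design);
  under the default ~44% complete-case rate the effective ranking
  sample is small in the minority class.
* The ensemble's undecided set is handled entirely by the feature
  stage; there is no abstention output at the animal level unless every
  feature is missing.
* MCAR is the only missingness mechanism; informative gaps (e.g.
  sicker cows measured more often) would bias the naive Bayes moments.
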