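# ketodetect

Early detection of **subclinical ketosis (SCK)** in dairy cows — elevated
blood ß-hydroxybutyrate (BHB > 1.2 mmol/L) in early lactation without
clinical signs — from two complementary data sources per animal:

1. **behaviour sensor streams**: minutes per hour spent lying, ruminating,
   inactive, active, and highly active (the activity trio sums to 60 min
   each hour), over one week before or after calving;
2. **health features**: 20 named health/location/climate measurements
   (body condition score, back-fat thickness, NEFA, milk yield, parity,
   barn-location summaries, heat-stress hours), with realistic missingness.

It is written for researchers in precision livestock farming and
veterinary epidemiology who want a transparent, fully reproducible
re-implementation of this hybrid time-series + feature classifier, and a
synthetic cohort generator to exercise it, since the original farm data
are proprietary.

## The method

**Weighted time-series dissimilarity.** Two series a, b ∈ Rⁿ are compared
with a double sum over all index pairs,

    D(a, b) = ( Σᵢ Σⱼ |aᵢ − bⱼ|ᵖ · wᵢⱼ )^(1/p),   p = 1 in deployment,

where the n×n weight matrix is learned from class-mean series: a sign
matrix G with Gᵢⱼ = sign(min between-class gap − max within-class gap) at
the index pair (i, j), blended with the identity as W = (1−λ)G + λI.
At λ = 1 the dissimilarity is the Manhattan distance; with diagonal
positive weights and p ≥ 1 it is a weighted Minkowski metric (the package
verifies the metric axioms by simulation).

**Classification pipeline** (stratified outer 10-fold cross-validation,
everything fitted on the training ~90%):

1. per stream, λ is chosen from the 31-value dyadic grid
   {2⁻ⁱ} ∪ {1 − 2⁻ⁱ}, i = 0..15, minimising the leave-one-out balanced
   error of a nearest-centroid classifier (ties → largest λ);
2. a test animal is labelled when ≥ 4 of the 5 stream classifiers agree;
3. the rest go to a feature stage: Relief ranks the features on the
   training complete cases, an inner stratified 10-fold CV picks the
   number of top features by balanced accuracy, and a Gaussian naive
   Bayes — which simply omits likelihood terms for missing features —
   decides.

Out-of-fold predictions are pooled into one confusion matrix and scored
with Acc, Sens, Spec, Youden's J, Cohen's κ, F, Prec, MCC, NPV and Lift.
A screening module compares each feature between classes with a two-sided
Mann–Whitney U test at a Bonferroni-corrected level (0.05/20 = 0.0025).

## Worked example

```sh
ketodetect simulate --n 671 --seed 1 --out data/
ketodetect run --data data/ --time-frame post_partum --seed 3 --out report.json
```

which prints (numbers from this exact invocation):

```
wrote cohort of 671 animals to data/
n=671  Acc=0.8241  Sens=0.7959  Spec=0.8290  J=0.6249  F=0.5693
```

Read: on a synthetic cohort of 671 cows at 15.8% SCK prevalence with
published-scale feature separations and missingness, the cross-validated
pipeline recovers 79.6% of sick and 82.9% of healthy animals (Youden's
J = 0.62). `ketodetect stats` writes the per-feature screening table and
`ketodetect report` aggregates several runs into a measure table plus
per-feature selection frequencies.

The same run from Python:

```python
from ketodetect import (CohortSpec, ExperimentConfig, apply_missingness,
                        bundle_from_cohort, generate_cohort, run_experiment)

cohort = apply_missingness(generate_cohort(CohortSpec(n_animals=671, seed=1)), seed=2)
report = run_experiment(bundle_from_cohort(cohort), ExperimentConfig(seed=3))
print(report.confusion, report.measures.as_dict())
```

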