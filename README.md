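# typicality

One-class classification of biomedical data by a distance-based
typicality test, with reference baselines and a benchmark harness.

## The problem

In many biomedical settings — diagnosis, tumor recognition from images,
ECG screening — labelled examples exist for only one class: the *target*
class C. Given n units y₁,…,yₙ from C measured on p features (not
necessarily continuous), a one-class classifier (OCC) must decide whether
a new unit y₀ belongs to C or comes from some other, unknown class.

## The statistic

Let δ²(y, y′) be a squared distance between units that is Euclidean-
embeddable (there is a map Ψ into some ℝ^q with
δ²(y, y′) = ‖Ψ(y) − Ψ(y′)‖²). The package estimates

- the **geometric variability** of the class (a distance-based dispersion,
  a variant of Rao's diversity coefficient):

      V̂_δ(C) = (1 / 2n²) Σᵢⱼ δ²(yᵢ, yⱼ)

- the **proximity** of a unit y₀ to the class:

      φ̂²(y₀, C) = (1/n) Σᵢ δ²(y₀, yᵢ) − V̂_δ(C)

For the plain squared Euclidean distance these are the biased total
variance and the squared distance to the class mean ‖y₀ − ȳ‖²; for a
general embeddable distance, φ² is the squared distance to the δ-mean of
the class in the embedding space — no embedding is ever computed.

The decision is a hypothesis test: H₀ "y₀ comes from C" against H₁ "y₀
comes from another unknown class". Since the sampling distribution of φ²
is intractable for mixed data, it is calibrated by a bootstrap: units are
drawn from C itself (by default each draw is scored against the class
*without* itself, which removes the zero self-distance bias), their φ²
values form the null sample, and y₀ is rejected when its φ² falls in the
upper α tail (α = the nominal false alarm rate, default 0.1).

Because only δ² is needed, the same test runs on continuous data
(Euclidean, standardized-Euclidean, Mahalanobis, correlation distances),
on p ≫ n expression-style tables, and on mixed continuous / ordinal /
binary / nominal tables with missing values via **Gower's distance**
(δ² = 1 − Gower similarity) — a regime where density-based OCC methods do
not apply.

Five reference baselines are included under the same fit/score/threshold
contract: Gaussian, mixture of Gaussians (EM), Parzen, naive Parzen and
support vector data description (SVDD, dual QP). The evaluation module
implements the standard protocol: repeated 50/50 target splits, mid-rank
(Mann–Whitney) AUC mean ± sd in percent, and confusion tables at a fixed
false alarm rate.

## Worked example

```python
import numpy as np
import typicality as tp

# two well-separated Gaussian classes, 100 units each, p = 5
table, labels = tp.make_continuous(
    tp.SynthSpec(n_target=100, n_nontarget=100, p=5, shift=5.0, seed=7))
train, test, test_labels = tp.split_target(table, labels, "target", seed=1)

res = tp.OneClassTypicality(train, distance="euclidean").fit(
    alpha=0.1, n_boot=1000, seed=1)
print(res.summary())

scores = res.score(test)                      # phi2, p-value, decision
phi2 = np.array([s.phi2 for s in scores])
is_target = test_labels == "target"
print("AUC:", tp.auc(phi2[is_target], phi2[~is_target]))
```

prints

```
One-class typicality test
===========================================
n training units                         50
n features                                5
distance                          euclidean
geometric variability               4.01904
bootstrap replicates                   1000
bootstrap mode                leave-one-out
nominal FAR (alpha)                     0.1
decision threshold                  7.39944
-------------------------------------------
bootstrap null quantiles of the proximity
50%              3.86343
90%              7.39944
95%              8.01647
99%              11.0078
AUC: 0.9998
```

The geometric variability ≈ 4 estimates the total variance of the
training class (5 unit-variance features, small-sample noise); the
threshold 7.40 is the 90th percentile of the bootstrap null of φ², so
about 10% of genuine target units are rejected on average while, at this
separation, essentially every nontarget unit scores far above it
(AUC ≈ 1.00). In this run 10 of the 50 held-out targets and all 100
nontargets were flagged — the realized false alarm rate of a single
n = 50 training half fluctuates noticeably around the nominal 0.1.

The same flow works from the shell:

```sh
typicality simulate --regime mixed --missing-rate 0.096 --out data.csv
typicality benchmark data.csv data.csv.schema.yaml \
    --methods typicality --distance gower --far 0.1 --out results.csv
```

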