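# Methods

## Model

The core procedure is a nonparametric typicality test used as a one-class
classifier. A target class C = {y₁,…,yₙ} is observed on p features; a
squared distance δ² between units is chosen; and two plug-in estimators
are computed:

    V̂_δ(C)      = (1 / 2n²) Σᵢⱼ δ²(yᵢ, yⱼ)          (geometric variability)
    φ̂²(y₀, C)   = (1/n) Σᵢ δ²(y₀, yᵢ) − V̂_δ(C)      (proximity function)

The only assumption on δ is Euclidean embeddability: δ²(y, y′) =
‖Ψ(y) − Ψ(y′)‖² for some map Ψ into a Euclidean space. Under it, V̂ is
nonnegative and φ̂²(y₀) estimates the squared distance from Ψ(y₀) to the
class mean in the embedding, so "large φ²" coherently means "atypical".
The embedding itself is never computed; only its distance-level
consequences are used. All five built-in distances are embeddable,
including Gower (with δ = √(1 − s), Gower 1971) and the correlation form
δ² = 2(1 − r), which equals the squared Euclidean distance between
z-scored unit profiles divided by p.

New units are tested as H₀ "y₀ comes from C" vs H₁ "y₀ comes from another
unknown class": φ̂²(y₀) is referred to a bootstrap sample of its null
distribution, giving an upper-tail p-value with add-one smoothing,
p = (1 + #{b : φ²_b ≥ φ²_obs}) / (B + 1) ∈ (0, 1]. The decision rule
rejects (declares nontarget) when p ≤ α.

## Bootstrap null

The null sample is built by drawing units from the class itself.
Two modes:

- **leave-one-out** (default). Each of the B replicates draws one index i
  uniformly (with replacement across replicates) and computes
  φ̂²(yᵢ, C∖{yᵢ}): both the reference distances and the geometric
  variability use the remaining n−1 units. Scoring a unit against a
  reference set containing itself contributes a zero self-distance, which
  deflates φ², shifts the null left and inflates the realized false alarm
  rate — holding the unit out removes this bias. All n leave-one-out
  proximities are obtained in one O(n²) pass from the pairwise matrix.
- **resample-class**. Each replicate draws a probe index i and a full
  bootstrap class of size n−1 from C∖{yᵢ}, then scores yᵢ against it.
  Closer to a textbook bootstrap, O(B·n²), behind a flag.

Defaults: B = 1000; threshold = empirical (1−α) quantile of the null with
*higher* interpolation and strict-exceedance rejection, both conservative
toward H₀ (realized FAR ≤ α in expectation under ties). One root seed
drives everything; child seeds are derived with `numpy.random.SeedSequence`
so repeated runs are byte-identical.

Calibration accuracy at the default settings: with n = 200 training units
the realized false alarm rate of a single fitted model is unbiased
(mean ≈ 0.10 over independent training draws) but fluctuates with
standard deviation ≈ 0.02–0.025, dominated by the sampling noise of the
training class's upper quantile — not by B. The calibration test therefore
averages the rejection rate over several independent training classes;
a check conditioned on one training draw measures that quantile noise,
not the method's calibration.

## Distances

All fitted parameters are frozen on the training half of the target class
and never updated when new units are scored.

- `euclidean` — no parameters.
- `euclidean_std` — per-column training mean and sd (population sd,
  ddof 0). A zero-variance training column is assigned standardized
  coordinate 0 for every unit (it carries no information); a warning is
  logged.
- `mahalanobis` — training covariance (ddof 1) regularized as
  Σ + λ·mean(diag Σ)·I with λ = 1e−6; if the regularized matrix is still
  numerically singular (the p ≥ n regime), the Moore–Penrose
  pseudo-inverse is used. The same inverse backs the Gaussian baseline.
- `correlation` — δ² = 2(1 − r) with r the Pearson correlation across
  the p features of the two unit profiles; chosen over 1 − r or 1 − |r|
  because it is the Euclidean-embeddable convention. A constant profile
  has no defined correlation and raises.
- `gower` — similarity s averages per-column scores with missing-value
  weights: range-scaled absolute difference for continuous columns
  (training range; differences beyond it are clamped), exact match for
  binary/nominal columns; a comparison gets weight 0 when either cell is
  missing or a numeric column has zero training range. δ² = 1 − s, so
  distances live in [0, 1] and V̂ ∈ [0, 1]. Ordinal columns are
  rank-transformed (Podani): training values map to mid-ranks, unseen
  values are linearly interpolated into the training rank scale, and the
  range is taken on ranks. A pair of units sharing no observed column is
  an error (`IncomparablePairError`), not a silent NaN; with few columns
  and heavy missingness such pairs occur by construction, so mixed-data
  analyses should keep enough columns that the incomparability
  probability (≈ Π_k P(missing in either unit)) is negligible.

## Baselines

Common contract: scores oriented "larger = more atypical"; the decision
threshold is the (1−α) higher-interpolation quantile of the training
scores, so ⌊αn⌋–⌈αn⌉ training units are rejected. All require
all-continuous, fully observed data.

- **Gaussian** — ML mean, ridge-regularized covariance; score = squared
  Mahalanobis distance to the mean.
- **Mixture of Gaussians** — EM, diagonal covariances by default (full
  covariance behind a flag; it is refused for p ≥ n, where it is
  unidentifiable and mirrors the NaN failures density methods show on
  such tables). Five random restarts, best log-likelihood kept; a
  variance floor of 1e−8 × mean feature variance prevents component
  collapse; the per-iteration log-likelihood trace of the winning restart
  is stored and is nondecreasing. Convergence: relative tolerance 1e−8,
  max 300 iterations.
- **Parzen / naive Parzen** — Gaussian-kernel density estimates (joint
  isotropic / per-feature product); score = −log density, computed in log
  space so p ≫ n underflow yields large finite scores rather than NaN.
  Bandwidths default to the leave-one-out log-likelihood maximizer over a
  25-point log-spaced grid spanning [median/30, median×10] of the
  pairwise distances.
- **SVDD** — the minimum-volume hypersphere in kernel feature space,
  via the dual QP max Σαᵢ Kᵢᵢ − ΣᵢⱼαᵢαⱼKᵢⱼ subject to 0 ≤ αᵢ ≤ C,
  Σαᵢ = 1, solved with SLSQP (analytic gradient, ftol 1e−14); C < 1/n is
  an infeasible box and raises. RBF kernel with the median heuristic
  width by default; a linear kernel is available, under which the sphere
  center is Σαᵢxᵢ (for an acute triangle inscribed in a circle this is
  the circumcenter, the geometric test case). Score = squared kernel
  distance to the center.

A failed fit raises `FitFailed`; the benchmark protocol records the
repeat as missing (NaN) and excludes it from the AUC mean/sd with a
logged count, rather than crashing the run.

## Evaluation protocol

The target class is split uniformly at random into equal halves (training
gets the extra unit for odd counts, favoring the fitted model); training
uses target units only; the test set is the held-out target half plus all
nontarget units. R = 10 repeats by default, per-repeat seeds derived from
the root seed. AUC is the mid-rank Mann–Whitney statistic,
P(s_nontarget > s_target) + ½P(equal) — exact, tie-aware and equal to the
trapezoidal area under the empirical ROC — reported ×100 with mean and
sd (ddof 1) over repeats. Confusion tables at a fixed false alarm rate
recalibrate the threshold on the target-class calibration scores (the
bootstrap null for the typicality test, the training scores for
baselines); `far = 0` maps to a +∞ threshold (nothing rejected).

## Synthetic data

Three generators define the test conditions; all are pure functions of
their spec (seed included).

- `make_continuous` — target N(0, I_p), nontarget N(shift·1/√p, I_p):
  the Euclidean separation of the class means is `shift` sd regardless
  of p. Defaults n = 100 per class, p = 5, shift 3 (5 for the separation
  benchmark).
- `make_highdim` — p ≫ n (default p = 500, n = 40/22, the shape of
  two-class expression compendia). Each class carries its own disjoint
  sparse signature: a random 5% of features up-shifted by `shift` sd per
  feature in that class only. Shared within-class signatures make
  same-class profiles positively correlated, which is the structure the
  correlation distance exploits; a design that shifts only the nontarget
  mean leaves target profiles mutually uncorrelated and gives the
  correlation distance no power at any shift.
- `make_mixed` — clinical questionnaire shape (defaults 6 continuous,
  1 ordinal, 3 binary, 3 nominal; 150/120 units). The nontarget class
  differs by a mean shift on the continuous block, a one-step shift on
  the ordinal column and `nominal_shift` total-variation mass moved
  between categorical levels. Missingness is MCAR at a configurable rate
  (0.096 in the mixed-data benchmark, matching heavily incomplete
  clinical registries); every unit keeps at least one observed cell.

What these emulate — and what they do not: real clinical/expression data
have correlated features, non-Gaussian marginals, informative
missingness and label noise; the generators have none of these. Passing
tests therefore demonstrate correctness of the estimators, calibration
under the stated sampling models and the expected ordering of methods,
not field performance on any particular dataset.

## Numerical choices and edge cases

- Distance matrices are symmetrized ((D + Dᵀ)/2), clipped at 0, and
  checked symmetric to 1e−10 with an exactly zero diagonal.
- p-values are never 0 (add-one smoothing); decisions at an exact
  threshold tie go to "target" (reject only strictly above).
- n = 1 classes: V̂ = 0 by convention; fitting a typicality model or a
  bootstrap null requires n ≥ 2.
- Problem sizes in the test-suite benchmarks (n ≈ 100–200 per class,
  p ≤ 500, B ≤ 1000, R ≤ 10) are desk-scale choices that keep every
  statistical check well-powered while the full suite runs in seconds.

## Known limitations

- Single-class testing only: the multi-class typicality assignment
  setting is out of scope, as are analytic (non-bootstrap) nulls.
- Gower treats all comparable columns with equal weight; no user
  weighting is exposed.
- The SVDD solver targets the small-n regime of one-class benchmarks
  (n ≲ a few hundred); it is a dense SLSQP, not an SMO-style solver.
- Bootstrap calibration inherits the training sample's quantile noise:
  at n = 200 the realized FAR of one fitted model varies by ±0.02–0.03
  around the nominal level (see above), and more for smaller classes.
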