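# Methods

This note documents the statistical procedures implemented in `esdbench`,
their assumptions, the numerical conventions chosen where the literature
leaves the choice open, and what the simulation-based tests do and do not
establish.

## The effect-size distribution and its benchmarks

The unit of analysis is a study-level standardized effect y_i with
standard error s_i, one row per effect. Benchmarks are quantiles of the
empirical distribution of the y_i: the 25th/50th/75th percentiles
("quads") or the 16.65th/50th/83.35th percentiles ("thirds"; these
printed levels, not 1/6 and 5/6, are the convention the package keeps).
Benchmarks may be computed per group, on |y_i|, and weighted by the
inverse variance w_i = 1/s_i².

**Unweighted quantiles** use linear interpolation between order
statistics at position h = p·(n−1) — the default of most statistical
software, so results match what practitioners get from a plain quantile
call on the same data.

**Weighted quantiles.** There is no unique weighted generalization of
that estimator. `esdbench` sorts the values, assigns the k-th sorted
value the interpolation position

    c_k = S_{k−1} / (S_n − w_k),      S_k = w_1 + … + w_k (sorted order),

and linearly interpolates the sorted values at the point where the c_k
cross p (clamping beyond the extremes). This grid was chosen for three
properties, each enforced by tests:

1. *Equal-weight reduction.* With all weights equal, c_k = (k−1)/(n−1),
   exactly the unweighted positions; equally weighted data therefore
   reproduce the unweighted estimator (the implementation short-circuits
   identical weights so the equivalence is exact, not merely up to
   cumulative-sum rounding).
2. *Symmetry.* c_k(w) + c_{n+1−k}(w reversed) = 1, so
   Q_p(−x, w) = −Q_{1−p}(x, w).
3. *Frequency consistency.* For positive integer weights, each c_k lies
   inside the span of positions that the w_k replicates of value k occupy
   in the expanded sample, so at every grid point the estimator agrees
   exactly with the replicate-expansion brute force. Between grid points
   the two differ by interpolation convention only.

A midpoint-cumulative convention (positions (S_k − w_k/2)/S_n) was
considered and rejected: with equal weights it yields Hazen positions
(k−½)/n, which do **not** reduce to the unweighted estimator.

**Bootstrap CIs.** Benchmark precision is assessed with the percentile
bootstrap: resample n effects with replacement (probability proportional
to weight in the weighted case) n_boot = 2000 times by default, take the
quantile of each replicate, and report the 2.5th and 97.5th percentiles
of the replicate distribution. Resampling is per group and driven by a
single seeded generator, so tables are reproducible bit-for-bit. A
Monte-Carlo experiment in the test suite (standard-normal samples,
n = 200, 1000 simulations) checks that the nominal 95% interval for the
median covers the truth between 93% and 97% of the time — the percentile
bootstrap for quantiles is approximate, not exact, and slightly
conservative or liberal depending on n and p.

**Skewness.** Bowley's quartile coefficient (Q₁ + Q₃ − 2Q₂)/(Q₃ − Q₁)
is reported on request. It is bounded in [−1, 1], uses only the middle
50% of the distribution (robust to tails), and is undefined when the
interquartile range is zero, which the code treats as an error (NaN in
table context).

**Group threshold.** Groups with fewer than `min_group_n` effects are
omitted. Three is the minimum needed to estimate three benchmarks and is
the default; published tables sometimes use four, so the threshold is a
parameter. Rendered tables round to 2 decimals; underlying values keep
full precision.

## Random-effects and limit meta-analysis

Between-study heterogeneity is estimated by **DerSimonian–Laird**: with
fixed-effect weights w_i = 1/s_i², Q = Σw_i(y_i − ŷ_FE)² and
τ̂² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)). DL was chosen for its closed
form — every fit is independently checkable by hand, and the test suite
does exactly that against a brute-force evaluation (and the fixture
values were verified against an independent meta-analysis package). A
likelihood-based τ² could be added behind the same interface; adjusted
benchmarks can shift at the second decimal depending on this choice.

**Limit meta-analysis** adds a small-study parameter on the generalized
radial plot: z_i = y_i·x_i regressed on x_i = 1/√(s_i² + τ̂²) by OLS with
residual variance fixed at 1 (the radial construction standardizes the
residuals). The intercept α̂ measures the small-study effect, the slope
β̂ is the effect of a hypothetical infinitely precise study. Per-study
adjusted effects shrink toward the limit,

    ỹ_i = β̂ + τ̂·(y_i − β̂)/√(s_i² + τ̂²),

and the adjusted summary is β̂ + τ̂·α̂ with a 95% CI from the
delta-method variance τ̂²·var(α̂) + var(β̂) + 2τ̂·cov(α̂, β̂), treating τ̂
as fixed. Other published summary variants (β̂ alone, or the limit-model
mean at average precision) exist; the expectation variant is reported
because it is the quantity the shrunken distribution is centered on.

Numerical notes: the OLS is computed in centered form
(β̂ = S_xy/S_xx), which stays stable when the precisions are nearly
equal; identifiability is judged on the raw SEs (all equal ⇒ constant
regressor ⇒ explicit error) rather than on s_i² + τ̂², which flattens as
τ̂ grows. When τ̂² = 0 every ỹ_i equals β̂ — complete shrinkage is the
correct degenerate behavior, not a bug. Shrinkage is a contraction
toward β̂ and preserves the side of β̂ each study sits on, and preserves
ranks among equally precise studies; because the shrinkage factor
depends on s_i, the *global* ranking can change, and as τ̂ → ∞ the
shrunken effects recover the raw ones only when the effects are
uncorrelated with the sampling variances (otherwise the radial slope
itself diverges). The adjusted benchmark table computes shrinkage on
signed effects first and applies any absolute-value conversion
afterwards, so the adjustment operates on the directional distribution
the model describes.

## Power and sensitivity

Power for t tests is evaluated with the noncentral-t distribution:
paired/one-sample designs use df = n−1 and noncentrality λ = d√n;
two-sample equal-n designs use df = 2n−2 and λ = d√(n/2). One-tailed
power is P(T_{df,λ} > t_{1−α,df}); two-tailed power adds the lower
rejection region (negligible for the usual positive-effect scenarios but
included for correctness). Where the library noncentral-t underflows at
extreme noncentrality the normal limit N(λ, 1) is substituted; this only
affects powers indistinguishable from 1. The smallest sufficient n is
found by doubling-then-bisection over integers (power is nondecreasing
in n); the minimal detectable effect by Brent root finding on
d ∈ (10⁻⁶, 10] at tolerance 10⁻⁶. `detectable_proportion` combines the
sensitivity solve with the ESD: for each power level it reports the
minimal detectable d and the share of |effects| at or above it — near 0%
means the planned design cannot inform the field.

## The synthetic literature generator

The generator emulates the process that produces a published ESD, with
defaults meant to represent a typical psychology/biomedicine
intervention literature:

- true study effects θ_i ~ Normal(μ, τ²); defaults μ = 0.2, τ = 0.1
  (a modest average effect with moderate heterogeneity);
- per-group sample sizes uniform on 10–100 — small-study-dominated, so
  selection has teeth;
- sampling SE from the large-sample approximation for a two-sample
  standardized mean difference with n per group,
  s_i = √(2/n)·(1 + θ_i²/8); observed y_i ~ Normal(θ_i, s_i²);
- one-sided selection: results with one-sided p < 0.05 (z = y/s against
  the normal) are always "published", others with probability
  1 − `selection`. The two-point step is deliberately simple; graded
  selection curves are out of scope.

All randomness flows from one seeded generator; candidate studies are
drawn in vectorized batches with a hard cap of 10⁶ draws (an error past
that indicates an unreachable selection regime). The recovery experiment
replays this per replicate, comparing |raw median − μ| with
|median(ỹ) − μ|; under strong selection (severity 0.9, k = 50) the
adjusted median is closer to the truth in ≈90% of replicates.

What the generator does *not* emulate: correlated multiple effects per
study, metric mixtures requiring conversion, rounding/reporting error,
time trends, or selection on direction-free two-sided significance.
Passing recovery tests therefore show that the adjustment works when the
bias mechanism is one-sided significance selection with independent
studies — not that it corrects every real publication-bias mechanism.

## Data hygiene and conversions

Raw extractions often carry several effects per study. The filtering
rule keeps, within each `study_id`, the record with the smallest SE,
breaking ties by the effect closest to zero (either sign) and then by
input order; rows without a study id are kept as singleton studies with
a warning rather than silently merged. Cohen's d is converted to
Hedges' g with the standard small-sample factor J = 1 − 3/(4·df − 1)
(df = n₁+n₂−2 two-sample, n−1 paired); the exact gamma-function J is
intentionally omitted (differences are < 0.1% for df ≥ 10). Pearson r
conversion (d = 2r/√(1−r²)) is an explicit opt-in utility, never
applied implicitly.

## Plots

Histograms use half-open bins [a, a + w) anchored at zero with default
width 0.1 effect-size units; values landing exactly on an edge are
snapped into the bin they open despite floating-point division noise.
Every plotting function returns (and writes alongside the figure) a JSON
manifest of bin edges, counts, benchmark-line positions and diamond
coordinates; the test suite asserts manifests, never pixels, so results
are backend- and format-independent.

## Problem sizes used in the checks

The simulation-backed checks run at deliberately moderate sizes chosen
as the package's own verification conditions: 1000 Monte-Carlo
replications for bootstrap coverage (n = 200 per sample, 1000 bootstrap
resamples), 1000 random instances for quantile properties, 200
replicates for the bias-recovery experiment (k = 50 studies, selection
0.9), and 10⁴ effects for law-of-large-numbers checks on the generator.
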