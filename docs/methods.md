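# Methods

This note records the models implemented in `qscan`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the methodology was
genuinely open.

## Curve model and fitting

Each subject's inverted-U dose-response curve is parameterized as a
Gaussian in log10-log10 coordinates:
`log10 R = A·exp(−0.5·((log10 d − x0)/b)²)` with three free parameters —
peak log response `A`, peak log dose `x0`, width `b` (log10-dose units).
Reported variables are the antilogged amplitude and mean dose, the width,
and the analytic area `AUC = amplitude·b·√(2π)` (the closed-form integral
of the fitted curve over the log-dose axis; it reproduces the reference
table's AUC column to four significant figures, which a literal
`ln(width)` reading of the area formula cannot, since `ln b < 0` for
every observed width).

Fitting is unweighted nonlinear least squares on log10 responses
(`scipy.optimize.least_squares`), initialized at the data-driven start
(max log response; log dose at the max; half the log-dose span) plus five
jittered restarts, lowest SSE wins.  Width is bounded to (1e−3, 10) to
exclude the degenerate spike solution on sparse grids.  Zero doses are
excluded (log undefined; their data still feed the per-dose median splits
and the ANOVA's raw option), as are zero responses (with a warning).
R² is 1 − SSE/SST on the fitted log10 responses.  Six-point curves fit in
about a millisecond; the multistart makes the fit insensitive to the
inverted-U's shallow second mode (wide-and-low vs narrow-and-high).

A note on invariances: because fitting happens on log responses, the
model is exactly equivariant under *power* scaling of responses
(`R → R^c` scales `A` by c), not under multiplicative scaling — a
multiplied response is an additive shift in log space that a
baseline-free Gaussian cannot absorb exactly.  The test-suite checks the
former and only the direction of the latter.

## Demand model, and where k comes from

Demand curves re-express the same data economically: price `C = FR/dose`,
consumption `Q = mean infusions × dose`.  The exponential model
`log10 Q = log10 Q0 + k(e^(−αQ0C) − 1)` is fitted per curve over
(log10 Q0, log10 α) at fixed k, with a coarse log-spaced α scan for
initialization.  Essential value is `1/(100·α·k^1.5)`.

`k` (the consumption-range scaling constant) is shared across curves that
are compared, and is not identifiable per subject from six points.  The
default policy calibrates one cohort-wide k by minimizing the pooled SSE
with per-subject (Q0, α) free — a bounded scalar minimization over
k ∈ [0.5, 8].  On the reference cohort this gives k ≈ 2.40 and reproduces
the published per-subject Q0 and essential-value columns within ~5%
(mostly <1%), and the published pre-exclusion mean Q0 (3.47) within 1%.
The Hursh range convention `k = log10(Qmax/Qmin) + 0.5` and fixed user
values are available alternatives.

The published group-level demand-curve F statistics are a separate
matter: they are reproduced (2.9, 3.9, 4.8 for the three partitions,
within rounding) only at k = 4, a constant consistent with the demand
template the original analysis used, not with the calibrated cohort k
(which yields 4.4, 5.9, 6.1 — same ordering, larger values).
`compare_demand_curves` therefore takes k explicitly; the pipeline passes
its calibrated cohort value, and the ordering of the three partitions is
k-robust.

## Group comparison statistics

* **Grubbs screen** — two-sided single-outlier test per derived variable,
  one pass, critical value from the closed-form t-quantile expression;
  a subject flagged on any variable is excluded cohort-wide.  On the
  reference cohort exactly one subject (K) is flagged, on demand
  intensity only.
* **Extra-sum-of-squares F** — Gaussian-curve comparisons pool each
  subject's six log10 responses (one shared 3-parameter curve vs
  per-group curves; df 3 and n_points − 6).  Demand comparisons use
  group-mean consumption (two 6-point curves; k fixed; df 2 or 1, and
  n_points − 4).  The two data conventions follow from the degrees of
  freedom each design implies (66-point pooled fits vs 12-point
  group-mean fits).
* **Mixed ANOVA** — two-way (group × dose) repeated-measures ANOVA via
  `pingouin.mixed_anova` on log10 responses at the nonzero doses (a raw
  scale flag exists), with Greenhouse–Geisser correction of the
  within-subject effects.  Exact published F values for this ANOVA are
  not reproducible bit-for-bit: commercial packages compute the GG
  epsilon from per-group covariance in ways that differ from the pooled
  estimate used here, and the published group effects are consistent
  with different response scales for different partitions.  The group
  main effect for the amplitude split lands within 10% of the published
  value on the log scale; all qualitative verdicts agree.
* Significance is two-sided at α = 0.05 throughout and **no
  multiple-testing correction is applied anywhere** — the per-variable
  "fraction distinct" summaries are descriptive comparisons between
  partitions, mirroring the field's practice, not confirmatory tests.

## PCA, clustering, and the small-n regime

PCA standardizes each variable (n−1 denominator) and eigendecomposes the
correlation matrix; component signs are fixed by making each component's
largest-magnitude loading positive.  Scores are exact projections of the
z-scored data, so `scores @ loadingsᵀ` reconstructs it.

Clustering fits Gaussian mixtures to the PC scores by EM
(`sklearn.mixture.GaussianMixture`) for k = 1..5, selecting k by lowest
BIC (−2·loglik + params·ln n).  Three choices matter at a dozen
subjects:

1. **Pooled ("tied") covariance by default.**  Per-component full
   covariances in several dimensions are unidentifiable at n ≈ 11 and
   let EM collapse onto near-singleton components whose vanishing
   variance produces arbitrarily low, meaningless BIC.
2. **A minimum component size (default 3).**  Candidate solutions in
   which any component captures fewer subjects are rejected as outlier
   pockets rather than clusters.
3. **Ward-linkage initialization plus seeded random restarts** — the
   classic model-based-clustering recipe; the deterministic start makes
   the selected solution stable across seeds (20/20 in our checks).

By default clustering uses all principal components, which preserves the
full standardized feature space (the likelihood is rotation-invariant).
Both the component count and the covariance structure are arguments: for
larger cohorts (n ≳ 25) per-component full covariance on the leading
three components (those the distinction criteria are defined on, with a
minimum component size of d+1) is the better-specified choice, and is
what the synthetic-cohort recovery analyses use.

Two honest caveats.  The BIC margin for two clusters over one on the
reference derived-variable table is small (<1 BIC unit): eleven subjects
simply cannot provide strong evidence, and the selection should be read
together with the distinction criteria and downstream comparisons, which
corroborate the two-cluster structure independently (the two clusters'
pooled curve comparison gives F(3,60) = 6.44, and they separate on 4/6
variables).  Second, derived-variable tables carried at full numerical
precision contain exact functional relations (AUC is a product of
amplitude and width; essential value a function of elasticity), so their
trailing principal components are numerically degenerate; the analysis
of record uses the table at its published precision, which the pipeline
supports directly via its `variables=` argument (supplied tables are
treated as already screened — re-screening a post-exclusion table would
re-flag borderline subjects).

**Distinction criteria.**  A two-cluster solution is "distinct" when
(1) the cluster centers differ along PC1 — operationalized as a Welch
test on PC1 scores at α = 0.05, since the criterion concerns centers,
and the reference clusters' PC1 *ranges* in fact overlap slightly while
their centers separate cleanly — and (2) the clusters' convex hulls are
disjoint in (PC1, PC2) and in (PC1, PC2, PC3), decided exactly by a
linear-programming separability check that also handles degenerate
(collinear or single-point) clusters.  On the reference analysis the
clusters and the amplitude split pass all criteria; the mean-dose split
fails PC1 separation — the published pattern.

## Median splits and partition comparison

The median is the standard sample median; subjects exactly at the median
go to the high group (the tie rule that yields the reference 5-low /
6-high splits for odd n, where the median is a data point).  Partition
agreement is reported as a contingency table with compositions both ways
(share of each cluster, share of each split group).  `split_consistency`
quantifies the instability that motivates the whole exercise: per-dose
splits plus a dose × dose agreement matrix (on the reference cohort,
subject D is a high responder at the three lowest doses and a low
responder at the four highest).

## Synthetic cohorts

`PhenotypeSpec` describes a latent-cluster generative model: each subject
draws a cluster, then (log10 amplitude, log10 mean dose, width) from
that cluster's trivariate normal; noiseless responses follow the Gaussian
curve on the dose grid; multiplicative log-normal noise (default
sd 0.03 log10 units, matching the reference fits' residual scale) is
applied; a zero dose receives a phenotype-independent baseline (default
5 infusions, the observed drug-free responding level).  Demand-side
quantities are *not* sampled: consumption is response × dose by
construction, so fitted demand parameters are internally consistent with
the generated curves.

`paperlike_spec()` mixes two clusters 45/55 with centers straddling the
reference medians (low vs high area/essential-value), amplitudes inside
the observed 12–30 infusion band.  `elasticity_only_spec()` gives both
clusters identical amplitude and peak-dose distributions and separates
them only in width — hence only in demand elasticity — which is the
structure an intake median split is blind to.  The recovery analyses run
ten seeded cohorts of 40 subjects (a size at which full-covariance
mixtures on three PCs are identifiable): the pipeline recovers the
latent labels at ARI ≥ 0.9 in ≥ 8/10 seeds while the amplitude split
stays at chance (|ARI| ≈ 0.03).

What the generator does not emulate: session-level event structure
(within-session loading, inter-infusion intervals), dose-order and
between-series effects averaged away in the mean-response table,
pharmacokinetics, and any systematic relation between drug-free
responding and phenotype.  Passing recovery tests therefore demonstrate
that the pipeline works when the modelled structure is present, not that
real cohorts satisfy the model.

## Degenerate inputs and numerical conventions

Log base 10 throughout.  Curve fits require ≥ 4 positive (dose, response)
points; demand fits ≥ 3 points.  Zero-variance inputs: the Grubbs
statistic is undefined and flags nothing; correlation pairs are flagged
`undefined` rather than NaN-propagated; constant PCA columns raise an
error naming the column.  EM degeneracy is handled by the minimum
component size plus a 1e−6 covariance ridge; mixtures whose every
candidate fit is degenerate raise rather than return.  Identical groups
yield t = 0, p = 1 and F ≈ 0.  JSON reports serialize with sorted keys so
identical analyses are byte-identical.

## Problem sizes

The test-suite and the acceptance script run the reference cohort
(12 × 7) end to end, recovery sweeps of 30–40 random six-point curves,
and ten 40-subject synthetic cohorts — a couple of minutes on one CPU in
total, with the acceptance script itself a few seconds.
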