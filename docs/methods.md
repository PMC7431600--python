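# Methods

## Scientific setting

A vasoconstriction elicited at one point on an afferent arteriole (for
example by local electrical stimulation at the glomerular entrance) does
not stay local: it is conducted upstream along the vessel wall, decaying
with distance. The standard summary of this spread is an exponential
spatial decay of the relative constriction,

    y(x) = a · e^(b·x),        λ = −1/b,

where `y` is the relative diameter reduction at distance `x` (μm) from the
stimulation site, `a` is the local constriction at `x = 0`, `b` (1/μm,
negative for a decaying response) is the decay rate, and `λ` is the length
constant — the distance over which the response falls to `1/e` of its
local amplitude. Comparing `λ` between genotypes (e.g. connexin
wild-type vs. knockout) quantifies how gap-junctional coupling shapes the
spread.

## Trace reduction

Inputs are per-vessel diameter time series sampled every 10 s at positions
spaced 50 μm from the stimulation site, over 30 s each of baseline,
stimulation and recovery. A sample at time `t` summarises the 10-s
interval ending at `t`, so the samples "after 10, 20 and 30 s of
stimulation" are the three stimulation-phase samples.

Per position:

* resting diameter = mean of the baseline-phase samples;
* stimulated diameter = mean of exactly the three samples 10, 20 and 30 s
  after stimulation onset (an error if any is missing);
* relative constriction = (rest − stim) / rest, positive for narrowing.

From the first distance at which the profile reaches 0 or a negative
value, all values from that distance onward are set to exactly 0 (the
conducted response is treated as extinguished; upstream dilations before
that point are retained as negative values). The rule is idempotent.

Vessels enter the pooled analysis only if (1) the local constriction is at
least 5%, (2) the mean recovery-phase diameter at the stimulation site is
at least 50% of the resting diameter there, and (3) diameters are
measurable at three or more positions, the stimulation site included.
Criterion 2 is read literally as a diameter fraction (not as a fraction of
the constriction reversed); the ambiguity and this choice are deliberate.
Excluded vessels contribute nothing, not even partial profiles.

## Pooled fit and weighting

All (distance, constriction) points of a group's included vessels are
pooled and `y = a·e^(b·x)` is fitted by nonlinear least squares over the
individual points, with no per-distance averaging. Because every vessel
contributes a point at each distance it could be traced to, and fewer
vessels reach the longer distances, short distances automatically carry
more points: the pooling *is* the weighting. Minimising over pooled
points is algebraically identical to an n-weighted fit of per-distance
means (the within-distance scatter contributes a parameter-free constant);
the test suite checks the two routes agree to 1e-6.

Zero-truncated values enter the fit as exact 0s — they are data ("set to
0 for the remaining measurements"), not missing.

Numerical details: Levenberg–Marquardt with analytic Jacobian
(`scipy.optimize.least_squares`, xtol = ftol = gtol = 1e-10, at most
10,000 function evaluations). Start values: `a₀` = mean constriction at
the shortest distance; `b₀` = slope of the ordinary regression of `ln y`
on `x` over strictly positive `y` (fallback −5 × 10⁻³ μm⁻¹, i.e.
λ = 200 μm, when fewer than two distances have positive values). `b` is
unconstrained during optimisation; a non-negative `b` is rejected only
when a length constant is derived from it. Standard errors come from the
Gauss–Newton curvature at the optimum, `cov = σ̂²(JᵀJ)⁻¹` with
`σ̂² = RSS/(n−2)`; the convergence flag is the optimizer's own.

## Hypothesis tests

* Per distance: two-sided one-sample t-test of the per-vessel
  constrictions against 0; α = 0.05, no multiple-testing correction
  (matching the original analysis). Distances with n < 2 or zero sample
  variance are reported as not testable rather than raising.
* The "significant constriction measurable up to X μm" summary is the
  largest distance that is significant with *all shorter testable
  distances also significant* — an isolated significant point beyond a
  non-significant one does not extend the range. This contiguity rule is
  an interpretation choice, documented here because the phrase itself does
  not pin it down.
* Local (0 μm) constriction between two groups: one-way ANOVA; with two
  groups F = t² of the pooled-variance two-sample t-test, which the tests
  verify to 1e-10.

## Bootstrap

Per group, each of 1,000 replicates draws N points with replacement from
the pooled point set (N = the original count) and refits the model;
the (a, b) estimates are collected. Replicates whose resample has fewer
than two distinct distances, or whose refit does not converge, are
discarded and counted (`n_failed`) — never silently refit with altered
settings. Intervals are percentile intervals under the Hazen convention
(order statistic interpolated at rank q·n + ½; samples 1…100 give
(3.0, 98.0) at the 95% level). The resampling unit is the individual
pooled point, not the vessel, mirroring resampling "from the original
data set" after pooling; this ignores within-vessel clustering, which is
why the calibration test below accepts a wide 85–99% coverage band.

Decay rates of two groups are compared with a two-tailed Welch t-test on
the two sets of bootstrap `b` samples. A caveat stated prominently: a
t-test across bootstrap replicates treats each of the 1,000 refits as an
independent observation and therefore overstates the effective degrees of
freedom; the percentile interval of the paired `b` difference is reported
alongside as a more conservative summary. The Welch (unequal-variance)
form is used because nothing constrains the two replicate variances to be
equal.

## Synthetic cohorts

No per-vessel recordings are published for this kind of experiment, so
the package generates them. The generator reproduces the *statistical
structure* the analysis assumes — not membrane potentials, Ca²⁺ dynamics
or electrotonic cable physics:

    d(x, t) = D₀ · (1 − c(x) · g(t)) + vasomotion + measurement noise
    c(x)    = a · e^(−x/λ)

* `g(t)` rises mono-exponentially from 0 toward 1 during stimulation
  (τ_on = 10 s) and relaxes toward 0 during recovery (τ_off = 5 s),
  calibrated so a strong local response reaches ≈ 40% constriction within
  20 s of stimulation and reverses ≈ 85% of it within 10 s of stimulation
  end. Setting τ_on = 0 gives instantaneous onset, used for exact
  round-trip tests.
* Consequence of τ_on = 10 s: the stimulated diameter averages the three
  samples at 10/20/30 s after onset, where g = 0.632/0.865/0.950, so the
  *extracted* intercept is attenuated to ≈ 0.816·a. The decay rate and
  length constant are unaffected (the attenuation is multiplicative in
  `c`), which is why parameter-recovery claims are made for λ, not a.
* Vasomotion is a stationary AR(1) per position over the 10-s grid
  (lag-1 correlation 0.5, marginal sd 0.75 μm) — the simplest slowly
  varying correlated noise; measurement noise is white with sd 0.4 μm
  (sub-micrometre edge-tracking error). Neither magnitude is reported
  for the original recordings; both are assumptions, chosen once as
  physiologically plausible (vasomotion a few percent of a ~25 μm
  diameter), and are *not* estimates.
* The traceable length of each vessel is uniform over the 50-μm multiples
  of a per-group [min, max] window chosen so the uniform mean matches the
  group's reported mean length within the overall 100–500 μm span.
* Per-group defaults (vessel counts, resting diameters, generative a and
  λ) follow the published cohort and fit tables: 8/7/9/11 vessels,
  diameters 28.7/15.5/30.6/23.6 μm, a = 0.26/0.15/0.23/0.17,
  λ = 263/179/455/222 μm for Cx40 WT/KO and Cx45 WT/KO respectively.
  The printed dispersion of resting diameters is taken as the
  between-vessel sd. (For one published group the printed decay rate and
  length constant are mutually inconsistent; λ is always derived from the
  decay rate, λ = −1/b.)
* Seeding: every vessel's generator seed derives from the master seed via
  `SeedSequence(master_seed, spawn_key=(group_index, vessel_index))`, so
  appending a group or vessel never perturbs earlier draws, and identical
  seeds reproduce cohorts bit-exactly.

What the generator does **not** emulate: between-vessel heterogeneity of
the conducted response (all vessels of a group share one a and λ),
along-vessel correlation of vasomotion, drift, or tracking dropouts
within a trace. Passing the recovery and coverage tests therefore shows
the estimator chain is consistent and calibrated under the assumed noise
structure, not that it is robust to everything real recordings contain.

## Simulation study sizes

The packaged checks run, per invocation: a noiseless exact round trip;
100 seeded cohorts for λ recovery (median |λ̂−λ|/λ < 15% at the default
noise level); 200 cohorts × 500 bootstrap replicates for 95%-interval
coverage of b (accepted band 85–99%); and 50 WT-vs-KO cohort pairs × 500
replicates for genotype discrimination (two-tailed p ≤ 0.05 with the
knockout decaying faster, required in ≥ 80% of runs). Replicate counts
of 500 in the repeated-simulation studies (vs. the 1,000 used for a
single analysis) keep percentile intervals stable while holding the whole
suite to minutes on one core.

## Known limitations

* Point-level resampling understates vessel-level sampling variability;
  a cluster (vessel-level) bootstrap would be the stricter choice and the
  pooled structure retains `vessel_id` to allow one.
* The replicate-level t-test inherits the original procedure's inflated
  degrees of freedom (see Bootstrap above).
* Truncated-to-zero points make the error distribution non-Gaussian near
  the noise floor; with the default noise this affects mainly the
  shortest-λ group at its farthest distances.
* The intercept attenuation under default onset kinetics (≈ 0.816) means
  fitted `a` values from synthetic cohorts sit below the generative `a`;
  comparisons *between* groups are unaffected.
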