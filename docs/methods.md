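# Methods

## Model and assumptions

`suvtraj` reconstructs a population-level biomarker trajectory S(t) from
short longitudinal series by exploiting the autonomy assumption: the annual
rate of change depends on the current level, not on calendar time or on who
is measured. Under that assumption the (level, rate) pairs contributed by
different subjects at different disease stages are samples from a single
function f(S), and the trajectory solves the scalar ODE

    dS/dt = f(S),    S(0) = μ_norm,

where μ_norm is the normative mean (amyloid-negative, cognitively normal
subjects). The reconstruction is only as good as the assumption: it ignores
between-subject heterogeneity in rate (everyone is assumed to traverse the
same curve at staggered onsets) and cannot separate a cohort mixture of
fast/slow progressors from a single intermediate curve.

### Per-interval rates

Each subject's consecutive visit pairs give rate = ΔSUVR/Δt and a level for
the interval. Two level conventions are provided:

- `interval_start` (default): the first SUVR of the pair. This mirrors the
  convention of modelling "slope versus baseline level".
- `interval_midpoint`: the mean of the two SUVRs. For intervals that are
  long relative to the trajectory's curvature, the start convention biases
  the estimated rate at a given level (the chord slope equals the
  instantaneous rate near the interval's middle, not its start); the
  midpoint convention removes the first-order term of that bias, which is
  why the recovery analyses in the test-suite and acceptance script use it.

Intervals shorter than `min_interval` (default 0.25 years) are dropped:
near-coincident visits produce rate estimates whose noise variance scales
as 1/Δt², and a quarter-year floor bounds that amplification. No slope
outliers are removed by default; an optional symmetric quantile trim is
available. Only consecutive pairs are used — pooling all C(n,2) pairs would
re-introduce the long-interval bias and correlate rows strongly.

### Penalized spline and REML

f is a cubic B-spline with basis dimension min(40, number of unique levels)
and interior knots at quantiles of the unique levels. Knots closer than half
the nominal uniform spacing are thinned: heavily tied data (e.g. a normative
cluster at one level) can otherwise place quantile knots arbitrarily close
together and make the penalty numerically explosive. A
knots-at-every-unique-level mode (`knot_strategy="unique"`) is available for
fidelity checks against knot-rich smoothers.

The roughness penalty is λ‖Dc‖² where D takes second *divided* differences
of the coefficients across the basis's Greville abscissae. Because B-splines
reproduce straight lines through their Greville sites, the null space of D
is exactly the set of linear functions of the level — so the λ→∞ limit of
the fit is the ordinary least-squares line even with non-uniform knots, and
the λ→0 limit (with enough basis functions) interpolates. D is rescaled to
unit mean-squared row norm so λ is comparable across data sets.

λ is chosen by restricted maximum likelihood. The default optimizer is a
Fellner–Schall-type fixed-point update

    λ ← σ̂² · [(p − M) − λ·tr((BᵀB + λS)⁻¹S)] / (cᵀSc),

iterated until the relative change in λ falls below 1e-4 (cap 200
iterations), with σ̂² the REML variance estimate, p the basis dimension and
M = 2 the penalty null-space dimension. On non-convergence the code falls
back to a log-grid search (81 points over λ ∈ [1e-8, 1e12] with bounded
local refinement) on the explicit REML criterion; the two routes agree to
well under 0.1% in REML value on standard problems and the grid route is
exposed as `smoothing="grid"`. Observations are unweighted by default;
weighting rows by interval length is available but off, matching the
convention of treating every interval as one observation.

Final coefficients are always solved from the augmented least-squares system
[B; √λ·D], which stays accurate at extreme λ where the normal equations
are ill-conditioned.

### Integration and landmarks

The ODE is solved by fixed-step RK4 (default step 0.01 years, horizon 40
years). The right-hand side is the fitted spline, clamped to its boundary
value outside the fitted level domain; for fitted rate functions the
integrator evaluates a 4097-point tabulation of the spline with linear
interpolation (error ~1e-9 SUVR on these scales) rather than the spline
itself, which makes bootstrap re-runs cheap. Integration stops at the
horizon, at the domain's upper edge, or when the rate falls below the stall
threshold (1e-5 SUVR/year); the stall time is recorded on the curve so a
plateauing fit is visible. Starting at a fixed point returns a constant
curve with stall time 0 and a warning, not an exception. There is no
backward (pre-anchor) integration.

Crossing times are obtained by piecewise-linear interpolation between the
bracketing grid points, never by grid snapping; levels the curve never
attains are reported as not reached. Landmark tables attach the z-score
(level − μ_norm)/σ_norm to each level.

### Cutoffs

The positivity cutoff is μ_norm + z·σ_norm with default magnitude z = 2.
Part of the PET literature writes such cutoffs with a negative sign ("z-score
−2.0"); since the cutoff of an accumulating biomarker lies above the
normative mean, the package stores the magnitude and treats the sign as a
reporting convention. Normative statistics use each qualifying subject's
first visit only, so n counts subjects rather than correlated visits;
whether to use all visits instead is a genuinely open choice, and the
baseline-only rule was preferred as the more conservative one.

### Stratified comparison

Strata are fitted independently end-to-end. By default all strata share one
anchor (the pooled normative mean) so their curves differ only through their
rate functions; per-stratum anchors are available
(`shared_anchor=False`). The cutoff likewise comes from the pooled
reference. Between-stratum differences in time-to-cutoff are reported
descriptively — the method offers no sampling distribution for the curves —
with an optional subject-level bootstrap (resample subjects with replacement
within stratum, re-run the whole pipeline, percentile interval; default
B = 200, off by default) as an extension.

## Synthetic cohorts and what they do (not) show

The generator emulates the assumed data structure: subjects follow a common
logistic curve S_i(t) = A + (K − A)/(1 + e^(−r(t − τ_i))) with onsets τ_i
drawn uniformly; defaults are floor A = 0.8, ceiling K = 1.9, growth rate
r = 0.3/year, N = 500 subjects, 3–4 visits 1–2 years apart, additive
homoscedastic Gaussian noise (SD 0.02 SUVR, truncated by redraw to keep
observations positive), and a 30% normative subgroup sitting flat at the
floor. The onset window defaults to ±6/r years, which places baseline levels
within a fraction of a percent of both asymptotes — the staggered onsets
must tile the whole level range or parts of the rate curve are simply
unobserved (this matters when the growth rate is lowered). The logistic's
rate-versus-level form g(S) = r(S − A)(K − S)/(K − A) and its closed-form
time-at-level are the recovery oracles; a linear-growth mode exercises the
constant-rate regime. Diagnosis (CN/MCI/Dementia) is assigned from the
noise-free level (thresholds 1.2 and 1.5) and the per-visit amyloid flag is
set when the noise-free level crosses floor + 2·noise SD.

Recovery analyses anchor the integration at 0.863 and score the time to the
cutoff 1.045 (the mean + 2 SD arithmetic of a cortical-scale normative
reference) against the closed form between the same two levels. The anchor
is supplied explicitly rather than estimated because the estimated normative
mean equals the logistic floor, where the closed-form time diverges; with an
anchor strictly inside the level range, anchor-estimation noise is excluded
from what the recovery error measures (spline, slope transformation and
integrator only).

Between-stratum "shifts" are injected by rescaling the growth rate so the
oracle time from anchor to cutoff changes by exactly the requested number of
years. Shifting the onset distribution alone would change nothing: under
autonomy, onsets affect where subjects are observed, not the rate-vs-level
relation, so a pure onset shift is unidentifiable from slope data.

What passing these tests does *not* show about real data: the generator has
no between-subject rate heterogeneity, no level-dependent noise, no
informative dropout, no diagnosis misclassification, and one biomarker at a
time; real trajectories need not be logistic, and real normative groups are
defined by clinical adjudication rather than construction.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use N = 300–500 subjects per
cohort, 20 seeds for the realistic-recovery medians, 5 seeds per injected
shift, and a scaled-down bootstrap coverage check (N = 100 per stratum,
B = 99, 50 replicates, nominal 90% intervals, ±10 percentage-point band) —
sizes chosen so the whole suite runs in a few minutes while the medians are
stable. Determinism: every stochastic step takes an explicit seed;
`generate_cohort` is byte-reproducible, the integrator uses fixed steps, and
pipeline outputs embed a hash of the analytic configuration.

Known limitations: no confidence bands on f or S(t) outside the bootstrap
extension; no monotonicity constraint on f (a fitted rate can dip negative,
in which case integration stalls rather than reverses); no cross-biomarker
time alignment (each biomarker has its own time zero at its own normative
mean); and time-to-landmark estimates inherit the full bias of the autonomy
assumption when the cohort mixes distinct progression subtypes.
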