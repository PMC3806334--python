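# Methods

## Model and procedure

`metasynth` combines evidence at two levels. At the study level, estimate
θ̂_ij of study i in meta-analysis j is taken as normal with known variance
σ²_ij (the reported sampling variance), and the true effects follow
θ_ij = θ + u_ij with u_ij ~ N(0, τ²); τ² = 0 gives the fixed-effects
model. Pooling is inverse-variance weighted: fixed-effects weights 1/σ²,
random-effects weights 1/(σ² + τ̂²) with τ̂² the DerSimonian–Laird moment
estimator truncated at zero. Cochran's Q always uses the fixed-effects
weights, never τ-adjusted ones. Confidence intervals are symmetric Wald
intervals throughout.

At the meta-analysis level, published summaries (estimate, variance or
CI) are combined with weights equal to inverse summary variances, the
summary variances treated as fixed. No second-level heterogeneity across
meta-analyses is estimated: the two-step random-effects path uses each
meta-analysis's own τ̂²_j inside its summary and plain inverse-variance
weighting across summaries. Under fixed effects the two-step synthesis is
algebraically equal to one-stage pooling of all studies (verified to
1e-10 on a thousand randomized tables); under random effects the paths
differ only through the τ² estimates — per-group versus pooled — and the
package exposes both (`two_step_equivalence_gap` reports the discrepancy).

## Effect-size conversions

Mixed-type synthesis targets the SMD scale. Log odds ratios divide by the
constant 1.81; this is the conventional two-decimal rounding of π/√3 (the
ratio of logistic to normal standard deviations), kept at 1.81 — and
exposed as a parameter — because applied work and the desk examples this
package reproduces use the rounded value. Correlations transform to
Fisher's z; the exact z-to-SMD map m = e^z − e^(−z) is linearized to
m ≈ 2z so pooling remains a linear combination. Variances move by the
delta method (r→z: ×1/(1−r²)²; z→SMD: ×4; log-OR→SMD: ÷1.81²). Odds
ratios are log-transformed immediately on ingestion, CI limits included.
Missing variances derive from Wald limits as (UL − LL)²/(2·1.96)²; 1.96
(not the exact quantile 1.95996) is the default multiplier for the same
reproduce-the-printed-arithmetic reason, with exact quantiles used for
non-0.95 levels. Records with neither variance nor CI carry no weight
information and are dropped with a warning rather than an error. When
both are present the explicit variance wins; a >10% disagreement with the
CI-implied value warns.

Correlation meta-analyses pool on the raw r scale with the reported
var(r) by default, matching how the source meta-analyses of the packaged
tables were computed; a Fisher-z pooling mode (`r_scale="fisher_z"`) is
available but is not the default.

## The mixed-type closed form

The combined SMD over mixed-type summaries is, as conventionally printed,

num = Σ w_m m + 1.81 Σ w_OR ln(OR) + ½ Σ w_r ln((1+r)/(1−r)),
den = Σ w_m + 1.81² Σ w_OR + ¼ Σ w_r,  θ̂ = num/den, var = 1/den,

with w_m = 1/var(m), w_OR = 1/var(ln OR), w_r = (1−r²)²/var(r). The
correlation numerator coefficient ½ is not the one implied by the
conversion chain: m = 2z with var(m) = 4·var(z) gives SMD-scale weight
w_r/4 and hence coefficient ¼·w_r on ln((1+r)/(1−r)) = 2z. The package's
default (`numerator_mode="as_printed"`) keeps ½ for fidelity to the
published form and its worked example; `delta_consistent` uses ¼, which
makes every term exactly weight × converted estimate and guarantees the
combined estimate lies within the range of the converted inputs (the
as_printed form can leave that range when correlation summaries dominate,
which is why the range invariant is property-tested in delta-consistent
mode only). Both modes share the same denominator and variance.

## Overlap correction

Meta-analyses being synthesized often share primary studies; treating
their summaries as independent leaves the point estimate unbiased but
understates the variance — by a factor of exactly J when J meta-analyses
use identical study sets. With p studies (of fixed-effects weight sum
S_p) common to all J meta-analyses and S_rest the remaining weight, the
naive variance is multiplied by IF = (J²S_p + S_rest)/(JS_p + S_rest).
IF is 1 iff p = 0 or J = 1, is nondecreasing in p, and reaches J under
complete overlap. When per-study weights cannot be retrieved the
investigator must supply an explicit IF; the package never guesses one.
Whenever an overlap specification is applied, both the naive and the
corrected variances are reported.

## Synthetic data

The generator draws σ²_ij ~ Uniform[0.005, 0.05] by default — the
precision range typical of the small-to-moderate behavioural studies in
the packaged correlation table — and per-study random effects
u_ij ~ N(0, τ²). The per-study placement of the random effect is the
structure the DerSimonian–Laird estimator targets (and the one the
mixed-type model indexes); it is what makes τ² recovery and CI coverage
meaningful checks. Mixed-type tables put the truth on the SMD scale and
invert the conversions: log-OR studies report 1.81·m with variance
1.81²σ², correlation studies observe on the Fisher-z scale and report
tanh(z) with its delta-method variance, which keeps |r| < 1 by
construction and makes forward conversion recover the generating scale
exactly. Overlap is emulated by duplicating the first p studies of the
first meta-analysis into all groups. One master seed drives everything;
replicate streams are derived from (seed, replicate index), so reports
are bit-reproducible.

What the generator does *not* emulate: raw two-arm data (2×2 tables,
means/SDs), non-normal random effects, publication-bias selection, and
correlated within-study estimates. Passing recovery tests therefore show
the estimators are implemented correctly under their own assumptions, not
that those assumptions hold in any given literature.

## Numerical choices and problem sizes

Accumulation is plain floating-point in input order — instances are tens
of studies, far below where compensated summation would matter. Q is
clamped at zero against roundoff; τ̂² truncates at zero by definition.
Degenerate inputs error early: pooling requires positive variances, τ²
estimation at least two studies, the equivalence comparison at least two
meta-analyses, intervals must be properly ordered, odds ratios and their
limits positive, correlations inside (−1, 1). Single-study groups
meta-analyze to the study itself with τ̂² = 0.

Validation problem sizes were chosen to keep the full suite fast on one
CPU: the fixed-effects equivalence theorem is exercised on 1000 random
tables of 2–4 meta-analyses with up to 11 studies each; τ² recovery uses
100 replicates of 200 studies at τ = 0.2; calibration of the generator
uses 200 replicates of 3×50 studies; coverage and bias summaries use
replicate counts of 30–200. The worked-example regressions are desk-scale
and effectively instantaneous.

## Known limitations

Only the DerSimonian–Laird τ² estimator is provided (no REML,
Paule–Mandel, or Knapp–Hartung adjustment); conversions cover the
correlation / Fisher-z / log-OR / SMD family (no hazard ratios, risk
differences, or Hedges' small-sample correction); the overlap correction
addresses studies shared by *all* J meta-analyses, not arbitrary partial-
overlap dependence patterns; and Wald intervals are used everywhere,
which can undercover when study counts are very small.
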