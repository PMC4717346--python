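# Methods

This note records the statistical models implemented in `felidcam`, the
choices made where the methods literature leaves the design open, and what
the synthetic-data generator does and does not emulate.

## Detection events and histories

Photographs of the same species at the same site are collapsed into
independent events when separated by more than a configurable window (60
minutes by default). Two readings of the rule were possible; we assess each
photograph against the most recent **retained** event, not the most recent
raw photograph, so a burst of sub-hour photographs cannot extend suppression
indefinitely and the filter is idempotent. A gap of exactly 60 minutes is
*not* independent (the rule is strict). Photographs of distinguishable marked
individuals within the window count as separate events; dependent young are
excluded before filtering.

Daily occasions run noon-to-noon, so a single crepuscular/nocturnal activity
bout is never split across occasions: occasion *d* covers
[day_d 12:00, day_{d+1} 12:00). The number of daily occasions *t* equals the
inclusive calendar-day span of the configured survey window; it is never
hard-coded. Daily effort is 1 if the camera was active for any part of the
interval, else 0; a cell with zero effort is *missing* (not a nondetection)
and contributes no likelihood factor. Pooling into *L*-day occasions takes
the max over days with data, sums effort, drops trailing remainder days
(e.g. 113 daily occasions pool to 5 × 22 with 3 dropped), and leaves a pool
missing only when all of its days are missing. Timestamps are naive local
time; no solar-time correction is applied.

## Covariates

**Human development (HD).** Each structure point contributes a truncated
Gaussian kernel, exp(−d²/2σ²) with σ = radius/3 and a hard zero beyond the
radius, summed over points. The original GIS tool's absolute normalization is
not recoverable, so only relative (standardized) HD values are meaningful;
the kernel family, σ-rule and amplitude are configurable. Coordinates are
assumed planar (projected, metres). The spatial scale is chosen by ranking
univariate p(HD_r) detection models across candidate radii by AICc; exact
ties go to the smallest radius with a tie flag, non-convergent radii are
excluded with a warning.

**Lag covariates (P1–P4).** Pk_it = 1 iff the dominant species was detected
at site *i* on any of days t−k+1 … t — the detection day plus k−1 following
days, windows from multiple detections unioned and truncated at the survey
end. P1 is the dominant species' daily history itself, and P1 ≤ P2 ≤ P3 ≤ P4
elementwise. Lags are daily constructs; pooled input is rejected. Same-day
ordering within an occasion is ignored (the occasion is the atomic unit).
Grid interactions are elementwise products with the 0/1 grid indicator.

**Standardization.** Continuous covariates are z-scored with the population
(ddof = 0) standard deviation; binary columns are untouched; zero-variance
columns are left unscaled with a warning. The transform is stored so slopes
can be back-converted to raw units.

## Single-species occupancy

The single-season likelihood for site *i* is
Ψ_i Π_t p_it^y (1−p_it)^{1−y} + (1−Ψ_i) I(no detection), with missing
occasions skipped. Links are logit for both Ψ and p (the standard choice for
this family). Detection may depend on site covariates, occasion covariates
and interactions; K counts one intercept per formula plus one slope per term.
Fitting is quasi-Newton (BFGS) from a zero start plus jittered restarts
(5 by default); standard errors come from the inverse observed information
with a central-difference Hessian; a non-positive-definite Hessian is
reported, never silently accepted. Estimates with |logit| > 6 on the Ψ or
baseline-p intercept set a boundary flag (saturated data legitimately drive
Ψ̂, p̂ → 1). Detection-probability predictions use the delta method on the
logit scale and are back-transformed, keeping intervals inside [0, 1].

## Two-species conditional occupancy

The dominant/subordinate parameterization uses Ψ^A, Ψ^BA, Ψ^Ba and
detection parameters p^A, r^A, p^B, r^BA, r^Ba; the site likelihood sums over
the four joint latent states (see the module docstring for the exact
factors). r^BA applies on occasions where the dominant was detected,
r^Ba otherwise — occasion-level conditioning, the standard reading of
"given both present and the dominant is detected". Constraint sets are
expressed as equality groups in the field's table notation
(e.g. `(pB=rBA=rBa(G+HD))`); names in a group share one intercept and one
slope per covariate, and K is the number of groups plus the number of group
covariates. With Ψ^BA=Ψ^Ba, p^A=r^A and p^B=r^BA=r^Ba the likelihood factors
exactly into the two single-species likelihoods, which the tests verify to
1e−6.

When the dominant species' estimated occupancy reaches a boundary threshold
(0.99 by default) — effectively no dominant-absent sites — the split
p^B ≠ r^B. is unidentifiable; such fits are flagged and excluded from
ranking with an audit record rather than ranked on a spurious likelihood.

## Model selection

AICc = −2logL + 2K + 2K(K+1)/(n−K−1) with effective sample size n defaulting
to the number of sites (standard occupancy practice; configurable). Plain
AIC is also reported, and for n ≤ K+1 the correction is undefined and AIC is
returned with a warning. Weights are ω_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2),
invariant to shifting all AICc by a constant. Exact AICc ties break by
smaller K then label order, with a tie flag.

## Circadian activity and overlap

Clock times map to radians as 2π·(seconds since midnight)/86400. Densities
are von Mises KDEs with the circular plug-in concentration
κ* = [3n κ̂² I₂(2κ̂) / (4√π I₁(κ̂)²)]^{2/5} (κ̂ the ML von Mises
concentration), scaled by an adjustment constant: 0.8 for the grid estimator
Δ̂1 and 1.0 for the point estimator Δ̂4, the conventional smoothing choices.
Δ̂1 averages min(f̂, ĝ) over a 512-point grid (configurable) and is used
when the smaller sample is below 75; Δ̂4 averages min(1, ĝ/f̂) over the
first sample and min(1, f̂/ĝ) over the second. Which variant a given
comparison uses is exposed as a parameter since sample sizes in real surveys
straddle the 75 threshold.

Confidence intervals use a smoothed bootstrap: each replicate resamples the
data with replacement, adds von Mises kernel noise, and recomputes Δ̂. The
smoothed bootstrap is biased upward for Δ, so the reported interval is the
percentile interval shifted by the bootstrap bias and the adjusted point
estimate is the bias-corrected median, clipped to [0, 1]; this keeps
ci_low ≤ Δ̂′ ≤ ci_high by construction. Fewer than 100 replicates are
refused (unstable percentiles).

Two confidence intervals are compared by intersection width divided by the
mean interval width, and by the mean margin of error (half-width) — exactly
twice the first. These two definitions reproduce both published value pairs
they were checked against (16%/32% on one study area; 97%/complete on the
other). A margin-of-error proportion ≥ 1 is reported as complete overlap.

## Synthetic-data generator

The generator emulates: two 80 km² grids of twenty 2×2 km cells with one
camera per cell (jittered cell centres), structure points from a homogeneous
Poisson process whose intensity differs by grid (2 per km² urbanized, 0.05
wildland), latent two-species occupancy, daily Bernoulli detection with a
standardized-HD effect on the logit scale (β_HD = −0.4 for both species),
and detection timestamps drawn from species-specific von Mises mixtures
(subordinate: crepuscular peaks at 06:00 and 20:00; dominant:
evening/nocturnal peaks at 21:00 and 02:00, weights 0.6/0.4, κ = 2).

Default rates are calibrated once to the photographic rates of a realistic
felid survey — dominant daily detection 0.03 and occupancy 0.6; subordinate
daily detection 0.045 and occupancy 0.85, independent of the dominant — so
that a 92-day, 40-site survey yields on the order of 60–80 dominant and
140–180 subordinate events, with per-site dominant counts in the single
digits. The avoidance mechanism multiplies the subordinate's daily detection
probability by s for ℓ days starting with each dominant detection day, on
the wildland grid only; the default is complete 3-day avoidance (s = 0,
ℓ = 3). Suppression acts on detection (frequency of use), never on latent
occupancy, matching the behavioural interpretation of p. Setting s = 1 or
ℓ = 0 gives the null mechanism used for false-positive-rate checks.

Sub-hour "burst" photographs (probability 0.3 per event, 1–2 extras within
55 minutes) exercise the independence filter; consecutive-day event times
are redrawn when they would land within the independence window of the
previous day's event, so each simulated daily detection maps to exactly one
independent event and truth-record counts are exact.

Not emulated: animal movement or home ranges (site-days are independent
given the latent state), abundance-driven detection heterogeneity beyond the
HD effect, camera failure (effort is complete by default, though the
pipeline handles missing cells), seasonal drift in activity, and
observation/identification error. Passing recovery tests therefore show the
estimators work when the model's independence assumptions hold, not that
real surveys satisfy them.

## Problem sizes and numerical choices

The acceptance checks run at the study's scale: 40 sites × 92 daily
occasions (5 pooled occasions of 18 days), 50 simulation replicates each for
the lag-effect power and false-positive rate, 1000 random parameter draws
for likelihood normalization (two-species enumeration every 10th draw),
200 sample pairs × 1000 bootstrap replicates for interval coverage, and
n = 1000 samples for overlap-estimator accuracy. Optimizer tolerances:
BFGS gradient tolerance 1e−6, ≤ 500 iterations, 5 jittered starts for
reported fits (1–2 for simulation replicates, where the zero start is
reliable); likelihood floors at 1e−300 guard log(0) at probability-zero
corners. The power criterion counts a replicate as a detection when the
2-df likelihood-ratio test of {P3, G×P3} has p < 0.05 and the wildland lag
coefficient is negative.

## Known limitations

- Raw β magnitudes depend on covariate standardization; comparisons with
  coefficients fitted by other software are meaningful only in sign and
  relative magnitude.
- The HD kernel reproduces the *shape* of a GIS kernel-density covariate,
  not any particular tool's absolute units.
- The two-species likelihood assumes the two species' detections are
  conditionally independent across occasions given the latent states, apart
  from the occasion-level r^BA/r^Ba switch.
- One published model-selection table prints a parameter count (K = 12) that
  no consistent counting of its model string reproduces (11), and a weight
  column inconsistent with its own ΔAICc column; the package documents and
  recomputes rather than matches such internal inconsistencies.
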