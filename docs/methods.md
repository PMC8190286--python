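# Methods

This note documents the statistical procedures, the synthetic-data
generator's assumptions, and the numerical choices made where the design
was genuinely open. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Event definitions

**Independent visits.** A visit is a maximal run of same-species images
at one site whose consecutive gaps are all shorter than the independence
interval (default 30 min). The threshold is *inclusive*: a gap of
exactly 30 min starts a new visit, reading "at least 30 min without
detection" as 30 min sufficing for independence. Segmentation refuses
unsorted input rather than silently reordering.

**Displacement events.** One species "displaces" the other when the last
image of an A-visit is followed, at the same site, by the first image of
a B-visit within the displacement window (default 10 min, which allows
for one unidentifiable image given a 5-min camera dead time), *and* A
records no image for a full independence interval after B's arrival. The
absence requirement is our operationalization of "displaced" — the bare
definition ("left within 10 min of the other's arrival") does not say
how long the displaced animal must stay away; we reuse the 30-min
independence constant for internal consistency. Each A-visit yields at
most one event (the earliest qualifying B arrival).

Note an irreducible property of this observational definition: two
species visiting the same attractive site at similar times of day will
occasionally produce the displacement pattern by coincidence (A happens
to leave, B happens to arrive within the window, A happens not to
return). On synthetic data with known truth this false-positive floor is
a handful of events per study-scale dataset, which is why the recovery
report compares detected to true event counts with a ±max(60%, 6)
tolerance rather than demanding equality.

**Peri-event histogram.** Offsets of subordinate-species images are
measured relative to the dominant-species *presence interval*: negative
offsets to the visit's first image, positive offsets from its last
image, and images during the presence interval are excluded. This avoids
double-counting images while both species are on site. The alternative
single-reference-point convention ("arrival") is available via
`AnalysisConfig.histogram_convention`, since the choice is not dictated
by the event definitions. Each (image, reference visit) pair within the
±2 h half-width contributes one count, so counts are conserved by
construction.

## Rate inference

Displacement rates x/n get exact Clopper–Pearson intervals from beta
quantiles: lower = B(α/2; x, n−x+1), upper = B(1−α/2; x+1, n−x), with
the closed-form boundary cases (x = 0 ⇒ lower exactly 0, upper
1 − (α/2)^(1/n)). Clopper–Pearson was chosen as the default exact
method; Wald and Wilson are also exposed (`proportion_ci`) because
published intervals computed with unknown software can only be bracketed
by showing several standard methods agree at presentation precision.

The two-rate comparison deliberately reports *two* answers, since a
single "P[rate₂ > rate₁]" is method-ambiguous:

* the one-sided Fisher exact p from the 2×2 table
  [[x₁, n₁−x₁], [x₂, n₂−x₂]] (a frequentist tail probability), and
* the Monte-Carlo posterior P(p₂ ≥ p₁ | data) under independent
  Beta(x+1, n−x+1) posteriors (uniform priors), ≥ 10⁵ draws, seeded.

Neither is privileged; they answer different questions and for the
study-scale counts (21/6117 vs 0/1359) they give ≈ 0.015 and ≈ 0.012
respectively.

## Vigilance model

Each classifiable image is one Bernoulli observation: vigilant = 1,
feeding or other non-vigilant = 0; images whose posture could not be
classified are excluded. Images dated on or before 22 January of their
winter are excluded so that every site has ≥ 14 days of monitored
history before its use covariates are trusted (cameras go up in early
January). By default each image is one observation regardless of group
size; a per-individual expansion mode exists because pair images could
equally be scored per animal — neither mode is asserted as "the"
convention.

**Use classes.** For a focal image at instant t, heterospecific
detections at the same site and winter *strictly before* t determine the
class: none ⇒ NO_USE; some but none within 24 h ⇒ USED_GT_24H; otherwise
the within-24 h count is compared to the median of such counts compiled
over all focal observations that had ≥ 1 heterospecific detection in the
prior 24 h (pooled across sites and winters; per-year medians are a
config option). Ties go to LOW ("equal to or less than the median").
Strict causality — never counting a detection at or after t — is a
package invariant tested against the generator's internal bookkeeping.

**Model and fitting.** Random-intercept logistic regression with winter
as the grouping factor, fitted by Laplace-approximated maximum
likelihood: for each winter the conditional mode of the random effect is
found by 1-D Newton iteration, the marginal likelihood is the Laplace
integral at that mode, and a quasi-Newton search (L-BFGS-B) runs over
(β, log σ). statsmodels has no frequentist binomial mixed model, so the
fit is implemented here; it reproduces lme4::glmer (which uses the same
Laplace approximation) to about four decimals in coefficients, standard
errors, σ, and log-likelihood on test data, and collapses to the plain
logistic MLE when σ → 0. Inference is Wald (Z, p from the numerical
Hessian), matching the form in which such models are reported; no
likelihood-ratio tests. Non-convergence and separation raise an error
carrying diagnostics and a fixed-effect-year fallback suggestion. An
empty NO_USE class would make the intercept and the three use dummies
collinear; in that case the stalest level (USED_GT_24H) is folded into
the intercept and the change is recorded in `dropped_levels`.

With only 2–3 winter levels, σ is weakly identified (its estimate often
sits near 0 or wanders); the use-class contrasts, which vary within
site-winters, are insensitive to this. The intercept, snow, and
day-of-year terms are not: snow depth is a single shared series per
winter, so with 3 winters those covariates partially absorb the realized
year effects and their Wald CIs are anti-conservative. Synthetic-truth
experiments make this visible directly — average coefficient coverage
at study scale drops from ~5.6/6 with no year effect in truth to
~4.8/6 with a year-effect SD of 0.15 — and it applies equally to any
real study of this design, which is why the full-study recovery check
asks 4 of 6 coefficients to be covered while the model-only recovery
experiment (independent covariates) holds all six to nominal coverage. Predictions fix the random effect
at 0 and transform a Wald interval on the linear predictor through the
inverse logit (delta method).

**Covariate centering.** The fitter accepts reference values subtracted
from days and snow (default 0 = raw scale). Slopes and contrasts are
invariant; only the intercept's meaning shifts. The simulator generates
with day 43 / snow 45 cm references so that published-scale coefficient
magnitudes (snow ≈ 0.1 per cm) coexist with realistic baseline
vigilance; recovery experiments fit with the same references.

## Diel activity

Clock times map to angles (time/24 h × 2π); no solar-time correction is
applied (a deliberate simplification — see limitations). Densities are
von Mises kernel estimates on a 512-point grid, renormalized to
integrate to exactly 1 (trapezoid rule on the wrapped grid). The
bandwidth rule is a Silverman-style plug-in adapted to the circle: κ is
chosen so the kernel's circular SD equals 1.06 n^(−1/5) times the sample
circular SD (κ recovered from the SD by inverting A(κ) = I₁/I₀ with
Brent's method on exponentially-scaled Bessel functions). Published
overlap values depend on whatever bandwidth rule the original software
used, so cross-study comparisons of Δ at the second decimal are not
meaningful; within-pipeline comparisons are.

The overlap coefficient is the single estimator Δ = ∫ min(f₁, f₂) on the
shared grid. Bootstrap CIs resample each sample independently with
replacement, recompute both KDEs *including their bandwidths* each
iteration (default B = 1000), and take percentile quantiles. On
synthetic pairs with known truth the percentile CI covers at close to
the nominal rate; the KDE's smoothing bias inflates Δ slightly (both
densities widen the same way), which is why the point estimate is
checked against quadrature truth at ±0.03 for n = 2000 rather than
something tighter.

The three-way comparison (subordinate at previously-used sites,
subordinate at never-used sites, dominant) computes the "previously
used" flag causally — an image at the exact instant of the first
dominant-species detection counts as *not* used — and skips (with a log
entry) any comparison whose subset is empty.

## Occupancy and operability

"Occupied" means ≥ 1 independent visit within scope; no minimum-visit
threshold. The two directional co-occupancy percentages are independent
quantities. Operability intervals are date-inclusive; inoperable runs
merge when they touch or abut (next start ≤ previous end + 1 day) before
the maximum continuous run is measured. Site-day totals come from the
interval table itself, never from hard-coded season dates.

## The synthetic study generator

Defaults emulate a 52-site, 3-winter, 56-day (8-week) survey with a
5-min camera dead time — the scale at which the motivating study
operated — and carry ground truth for every downstream estimator.

* **Visit arrivals**: per site-winter and species, an inhomogeneous
  Poisson process thinned against the species' diel law. Defaults:
  crepuscular two-component von Mises mixture (peaks 06:00 and 18:00,
  κ = 2) for the subordinate, unimodal nocturnal (peak 01:00, κ = 1.5)
  for the dominant — chosen to reproduce the qualitative ordering
  "subordinate more diurnal than dominant", not any exact curve.
  Site heterogeneity: mean-one lognormal rate multipliers (σ = 0.5
  subordinate, 0.6 dominant) plus an explicit per-site-winter absence
  probability (0.12 / 0.15) mirroring observed within-winter
  co-occupancy of 78–88%; the absence mechanism is what keeps the
  NO_USE vigilance class populated. Base rates (0.80 and 0.18
  visits/site-day) are back-calculated so realized independent-visit
  totals land near the published 6117 and 1359; per-site-day rates are
  not published, so these are approximate by construction.
* **Images**: visit durations lognormal (median 20 min, σ = 0.8);
  images at the dead time plus exponential jitter (mean 3 min); the
  camera additionally enforces its dead time *across* species, and
  monitoring stops at season end.
* **Interaction dynamics**: an arrival during the other species'
  presence displaces the occupant with configurable probability
  (default: dominant always displaces, subordinate never); the
  displaced animal's remaining images are dropped and it stays away a
  lognormal lag (median 90 min). Separately, the subordinate abandons
  arrivals within 80 min of recent dominant presence with probability
  0.9 — the short-term avoidance that produces the depressed
  post-presence histogram and suppresses coincidental
  reverse-displacement patterns, both features of the real system.
* **Vigilance**: each image's behavior is drawn from the logistic model
  with configured coefficients (defaults: the published
  marten and fisher coefficient vectors), with the use class computed
  causally inside the generator by the same rule the pipeline applies,
  a per-winter random effect (σ = 0.15), ~11% unclassifiable images,
  and pair visits (all images n = 2) at 3.8% of subordinate visits.
* **Environment**: daily snow is a reflected Gaussian random walk in
  [10, 100] cm (start 45, step SD 1.5); camera failures hit 30% of
  site-winters for a geometric number of days (mean 4, cap 14),
  deleting images and emitting the operability gap.

Everything derives from one `rng_seed`; identical configs give
byte-identical CSVs.

**What the generator does not emulate** — and hence what passing
recovery tests do not establish about real data: spatially explicit
movement (sites are independent), individual identity and repeat
visitors, site-level vigilance heterogeneity (the vigilance model's only
grouping is winter, matching the fitted model's structure but not
necessarily reality), avian scavenger interference, clock drift, and
misclassification of species or behavior (labels are noiseless apart
from the unclassifiable mechanism). Recovery results show the pipeline
estimates what the generative model encodes, at study scale, under the
stated noise — not that the published field estimates are correct.

## Numerical choices and degenerate inputs

* Exact boundary ties in event rules are honored in nanosecond
  timestamp arithmetic (threshold comparisons are ≥ / ≤ exactly as
  defined, with window widths converted to integer nanoseconds).
* `kappa_for_circular_sd` brackets κ in [1e−8, 1e9] and refuses
  automatic bandwidth for n < 2 or degenerate (all-identical) samples,
  suggesting an explicit κ.
* Bootstrap CIs are clamped so ci_low ≤ Δ ≤ ci_high ≤ 1 (percentile
  quantiles can straddle the point estimate at extreme Δ).
* GLMM optimizer bounds log σ in [−8, 3]; σ² = 0 data drive the
  estimate to the boundary and the fixed effects to the plain-logistic
  MLE. Constant responses and single-winter data raise immediately.
* The pipeline is files-first and idempotent: identical inputs, config,
  and seed reproduce `report.json` byte-for-byte (no timestamps inside).

## Problem sizes used in the test suite

Oracle-equivalence checks run 10⁴ random ≤ 12-image streams against
brute-force rule transcriptions. Coefficient recovery runs 20 seeds at
the study-scale observation count (~17,900) with the published
subordinate coefficient vector as truth. Overlap calibration uses
n = 2000 samples against quadrature truth and 200 replicate pairs at
n = 500 with B = 200 for CI coverage; the pipeline-level bootstrap
default remains B = 1000. These sizes were chosen to make each check
statistically meaningful at interactive runtimes.

## Known limitations

* Clock time, not solar time: over an 8-week mid-winter window at one
  study area the sun-time drift is modest, but cross-latitude or
  cross-season comparisons of diel estimates would need a solar
  transform the package does not provide.
* Published overlap and coefficient values cannot be reproduced exactly
  without the raw data (and, for overlaps, the original bandwidth
  rule); the package targets the reproducible arithmetic and verifies
  the estimators on synthetic truth instead.
* The displacement definition cannot distinguish true displacement from
  coincidental turnover (see the false-positive floor above); at the
  published event counts (~21) this uncertainty is material and is why
  rates carry exact intervals rather than point interpretation.
* σ for the winter random effect is estimated from at most 3 levels and
  should be read as a nuisance parameter, not an estimate of
  between-year variance.
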