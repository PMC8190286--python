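# scavcam

Analysis pipeline for winter camera-trap studies of **interference
competition between a dominant and a subordinate carnivore at baited
carcass sites** — fishers (*Pekania pennanti*) and American martens
(*Martes americana*) being the motivating pair — together with a
synthetic-data generator that produces detection streams with known
ground truth, so every estimator in the pipeline can be verified without
access to raw field data.

It is intended for behavioral ecologists working with per-image camera
detections (site, species, timestamp, classified behavior, group size)
who want to quantify a "landscape of fear": displacement events,
vigilance responses to heterospecific site use, and diel-activity
partitioning.

## What it computes

Given a detections CSV, a daily snow-depth CSV, and a camera-operability
CSV, the pipeline runs five stages:

1. **Events** — segments each (site, species) stream into *independent
   visits* (a gap of ≥ 30 min without the species ends a visit), detects
   *displacement events* (species A's last image followed within 10 min
   by species B's first image, with A absent for the next 30 min), and
   tabulates the peri-event histogram of subordinate-species images in
   5-min bins within ±2 h of dominant-species presence.
2. **Rates** — displacement rates x/n with exact (Clopper–Pearson)
   binomial CIs from beta quantiles, the field's "1 per k visits"
   presentation, and a two-rate comparison reported both as a one-sided
   Fisher exact p and as the posterior P(p₂ ≥ p₁) under uniform priors.
3. **Vigilance** — builds one Bernoulli observation per classifiable
   image (vigilant = 1) with covariates *days since 1 January*, *daily
   snow depth (cm)*, and a four-level heterospecific-use factor
   (no use this winter / used > 24 h ago / low ≤ median vs high > median
   image count in the past 24 h, median split pooled over sites and
   winters, strictly causal), then fits the mixed-effects logistic model

   logit P(vigilant) = β₀ + β₁·days + β₂·snow + β₃·high + β₄·low +
   β₅·used + u_year,  u_year ~ N(0, σ²),

   by Laplace-approximated maximum likelihood (agrees with lme4::glmer
   to ~4 decimals), with Wald inference and probability-scale
   predictions via the delta method.
4. **Activity** — von Mises circular kernel density estimates of diel
   activity on a 512-point grid (plug-in bandwidth: kernel circular SD =
   1.06 n^(−1/5) × sample circular SD), overlap coefficients
   Δ = ∫ min(f₁, f₂), and percentile bootstrap CIs (both KDEs recomputed
   per iteration), comparing the subordinate's activity at sites with vs
   without previous dominant-species use, and each against the dominant.
5. **Occupancy** — directional co-occupancy percentages per winter and
   pooled, pair-visit statistics, and camera-operability accounting
   (site-days, inoperable rate, longest continuous gap).

The simulator (`scavcam.simulate`) generates the same three CSVs from a
configurable generative model — diel-modulated Poisson visit arrivals
with site heterogeneity, camera dead time, displacement and short-term
avoidance dynamics, a logistic vigilance process with known
coefficients, random-walk snow, and camera failures — and
`recover_all` re-analyzes its output against the ground truth.

## Worked example

Compare the displacement rates observed in a study where the dominant
species displaced the subordinate 21 times in 6117 subordinate visits,
and the subordinate displaced the dominant 0 times in 1359 dominant
visits:

```bash
$ scavcam rates --events1 21 6117 --events2 0 1359 --seed 1
{
  "rate1": {
    "reciprocal": "1 per 291",
    "ci": [0.002126333024842603, 0.0052430272494273]
  },
  "rate2": {
    "reciprocal": "0",
    "ci": [0.0, 0.0027107265786758747]
  },
  "p_fisher_one_sided": 0.014707441815646512,
  "p_posterior_rate2_ge_rate1": 0.012065
}
```

Reading this: the subordinate was displaced once per 291 visits (exact
95% CI, expressed as rates, about 1:470 to 1:191); the reverse rate is 0
with upper bound about 1:369; and both the Fisher exact test (p ≈ 0.015)
and the posterior probability (≈ 0.012) say the asymmetry is unlikely
to be chance — the dominant displaces the subordinate, not vice versa.

An end-to-end run on synthetic data:

```bash
scavcam simulate --seed 2 --outdir simdata          # writes the 3 CSVs
scavcam report simdata/detections.csv simdata/snow.csv \
        simdata/operability.csv --seed 2 --outdir out
scavcam check --seed 2 --boot 150                   # truth-recovery verdicts
```

`check` prints one PASS/FAIL line per recovery quantity, e.g.

```
[PASS] n_visits_marten: estimate=5605 truth=5822 (relative error <= 10%)
[PASS] vigilance_beta_coverage_marten: estimate=6 truth=6 (>= 5 of 6 coefficients inside Wald 95% CI)
[PASS] overlap_ordering: estimate=0.951 truth=0.581 (marten-marten overlap exceeds marten-fisher overlap (distinct diel laws))
8/8 checks passed
```

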