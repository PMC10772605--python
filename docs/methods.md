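# Methods

This note documents the models, algorithms and design choices behind
`thermnorm`, in the order the pipeline runs.

## 1. Synthetic studies (`thermnorm.simulate`)

The generator emulates a slow-cooling repeated-measures study: `n_fish`
(default 73) juveniles in 5 holding aquaria, measured at 14, 11, 8, 5 and
2 °C while cooled at 0.12 °C/day (25 days between measurement
temperatures).  Body masses start at 7.27 ± 1.75 g.

**Reaction norms.**  Each fish carries, per trait, an (intercept, slope)
pair drawn from a bivariate normal with covariance matrix `G`, around fixed
effects of centred temperature (centre 8 °C) and z-scaled body mass.
Defaults encode the structure the pipeline is meant to detect:

| trait | scale | intercept | temp slope | V_int | V_slope | Cov (cor) | V_res |
|---|---|---|---|---|---|---|---|
| smr | mg O₂/h | 0.90 | 0.07 | 0.04 | 0.0016 | 0.0064 (0.8) | 0.04 |
| mmr | mg O₂/h | 4.0 | 0.22 | 0.36 | 0.0144 | 0.0576 (0.8) | 0.36 |
| sgr | %/day | 0.30 | 0.08 | 0.02 | 0.0008 | 0.0032 (0.8) | 0.02 |
| activity (day/night) | probit latent | derived | 0.15/0.12 | 1.0 | 0 | 0 | 1 (fixed) |
| feeding | probit latent | derived | 0.25 | 1.0 | 0 | 0 | 1 (fixed) |

Metabolic and growth traits have slope sd = 20% of intercept sd with
intercept–slope correlation 0.8, so among-individual variance — and hence
repeatability — rises with temperature.  Behavioural traits have *no* slope
variance: all individuals share one thermal sensitivity.  Magnitudes are
chosen to be physiologically plausible for a ~7 g temperate fish (SMR near
0.5–1.3 mg O₂/h across 2–14 °C; MMR a factor ~4 above SMR; growth turning
slightly negative at the coldest interval midpoints, as expected for a
winter-dormant species).  Aerobic scope is not generated separately; it is
MMR − SMR by construction, which also induces a negative correlation
between SMR plasticity and AS plasticity (an emergent property the pipeline
can then detect).

**Zero inflation.**  Binary traits use a latent-threshold (probit) model:
latent = fixed effects + individual effects + arena effect + standard-normal
residual; the fish moves (eats) iff the latent value is positive.  The
latent intercept is derived from the configured marginal zero proportion
(default 55% of activity trials without movement; 49% of feeding
observations at zero) by inverting the probit at the marginal scale
`sqrt(1 + V_int + V_arena + V_aquarium)`.  Conditional on eating, a fish
takes its full 10-pellet ration with probability 0.34/0.51 (the two
marginal masses), else a uniform partial ration — the generator reproduces
the "nothing or everything" bimodality without claiming a mechanistic
feeding model.  A shared-component construction adds a configurable
cross-trait intercept correlation (default: activity–feeding 0.42).

**Masses and growth.**  Mass trajectories invert the SGR definition:
`m_next = m · exp(SGR_true/100 · days)`, with the true SGR evaluated at the
interval midpoint temperature plus interval-level residual noise.  Measured
SGR computed from these masses therefore recovers the generative reaction
norm exactly (up to the residual, which *is* the model's residual).

**O₂ traces.**  Each trial is an intermittent-closed sequence: a first
(post-chase) closed phase of 3–11 min, then alternating 4-min flushes and
closed phases of 5 min (14 °C) to 21 min (2 °C) — both linearly
interpolated across temperatures, since only the endpoints are part of the
protocol — for 17.5 h, sampled every 2 s in a 126.5 mL chamber.  During
closed phases O₂ falls linearly at `(MO₂(t) + background(t)) / (V_chamber −
V_fish)` plus Gaussian measurement noise (default sd 0.005 mg/L — a free
knob, not a claim about any particular oxygen meter); flushes ramp back to
saturation.  The fish holds its post-chase maximum through the first closed
phase, then recovers exponentially toward the SMR plateau with a 1 h time
constant; the recovery clock starts when the first phase ends, so the first
recording measures MMR itself rather than a partially recovered rate.
Background (microbial) respiration is zero until an onset time (default
8 h; chambers are bleached between trials), then grows linearly; each
chamber scales the common profile by a lognormal factor, and the three
post-trial background recordings are simulated at the final cycle's
midpoint level, which keeps the blank-rescaling correction exact in the
noise-free limit.

**Seeding.**  All randomness derives from one integer seed through named
`SeedSequence` sub-streams (individuals, masses, metabolic, activity,
feeding, per-trial traces), so any component can be regenerated
independently and traces are lazily synthesised yet byte-identical per
trial id.

## 2. Respirometry processing (`thermnorm.respirometry`)

Per closed phase, the O₂ decline is fit by ordinary least squares; the
slope (mg/L/h) times (chamber volume − fish volume, density 1 kg/L) gives
MO₂ in mg/h.  R² is defined as 0 for a zero-variance response so the
outlier rule below never divides by zero.  Cycles with fewer than 3 samples
are flagged unusable, never silently dropped.

**Background correction.**  The blank chamber's per-cycle MO₂ series gives
the *shape* of background growth.  Its onset is the first cycle (at or
after the k=3 baseline cycles) exceeding baseline mean + 2 sd for m=2
consecutive cycles — an operationalisation of "significantly different from
zero" chosen for robustness at tiny baseline counts.  From onset onward the
blank curve is rescaled **multiplicatively** so its final value meets the
mean of the three post-trial recordings of the fish's own chamber; an
additive shift was rejected because it would create a discontinuity at
onset.  If the blank curve ends at or below zero while the post-trial mean
is positive, a linear ramp is used instead, with a warning.  Increasing the
post-trial mean can only decrease corrected MO₂ (order preservation; tested).

**SMR/MMR/AS.**  The first corrected cycle is MMR; the remaining overnight
pool yields SMR as the mean of the ⌈0.1 N⌉ lowest values after dropping any
whose R² falls more than 2 sd below the trial-wide mean R² (if all are
dropped, the single highest-R² member is kept, with a warning).  AS = MMR −
SMR holds exactly in every output row; negative AS warns rather than
errors, since measurement noise can produce it.  The cycle-count formula
`max{k+1 : k(closed+flush) + closed ≤ trial}` counts the manually started
phase at time zero and reproduces 117 recordings per trial at 14 °C and 42
at 2 °C for the default schedule.

## 3. Trait table (`thermnorm.traits`)

Long format, one row per fish × trait × context: trait value, raw and
centred temperature, body mass and z-scaled mass, aquarium, and measurement
unit (respirometry chamber for metabolic traits, behavioural arena for
activity/feeding; none for SGR).  Mass is scaled once per trait over
retained rows; the mass covariate attached to an SGR row is the
interval-start mass.  Exclusions are configuration, not computation: a list
of fish ids removed entirely plus (fish, trait, temperature) triples, with
unknown ids rejected and a mandatory retention report so exclusion effects
are auditable.

## 4. Mixed models (`thermnorm.models`)

A single Gibbs sampler covers all cases: Gaussian or binary family,
univariate or bivariate, random intercepts or slopes.

* **Fixed effects** — intercept, centred temperature, scaled mass, and
  optionally their interaction; diffuse normal prior (variance 1e8).
  Interaction dropping is a deliberate two-pass workflow: the summary
  carries a `drop_interaction` directive when the term is non-significant,
  and the caller refits; nothing happens implicitly inside one fit.
* **Random effects** — individual (q = 1 or 2 per trait; a joint G across
  both traits in bivariate fits), aquarium, and unit intercepts.  Aquarium
  and unit terms are always included, even when their variances are tiny.
* **Binary traits** — probit latent-variable augmentation: the latent
  liability is drawn from a truncated normal each sweep and the residual
  variance is fixed at 1.  A probit link keeps every conditional conjugate;
  latent-scale estimates differ from a logistic parameterisation by the
  usual link scaling (logit residual π²/3 vs 1), which matters only when
  comparing absolute latent variances across packages.
* **Variance priors** — parameter-expanded: the Huang–Wand hierarchical
  inverse-Wishart (scalars: inverse-gamma) whose marginals are half-t(ν=1,
  scale=5) on standard deviations, i.e. half-Cauchy(5) — weakly informative
  on the scales of all traits here.  All hyperparameters sit in
  `PriorConfig`.
* **Sampling** — every conditional is conjugate; individual-effect updates
  are vectorised (batched Cholesky across fish) and inverse-Wishart draws
  use a Bartlett construction, so a 365-row fit at the test profile takes a
  few seconds.  Chains are deterministic given the spec seed.
* **Chain lengths** — defaults mirror a long production run (650 000
  iterations, 50 000 burn-in, thinning 40 → 15 000 draws).  `TEST_MCMC`
  (26 000 / 2 000 / 8 → 3 000 draws) is used throughout the test suite and
  acceptance script; with these conjugate updates its posterior summaries
  are amply stable for the recovery checks.  Effective sample sizes are
  computed (arviz) for variance components and leading fixed effects; fits
  below the ESS floor carry a warning flag.

**DIC.**  The conditional-deviance convention: `DIC = 2·mean(D) − D(θ̄)`
with D the deviance given fixed *and* random effects, and θ̄ the posterior
means of the linear predictor and residual variance.  This makes pD count
the effective number of random-effect parameters, which is what the
intercepts-vs-slopes comparison must price.  For binary traits the deviance
is on the data (Bernoulli-probit) scale.  Support categories: ΔDIC =
DIC(intercepts) − DIC(slopes) ≥ 10 strong, 5–10 substantial, else none.

## 5. Repeatability and correlations (`thermnorm.repeatability`)

`R_C(t) = V_id(t)/(V_id(t) + V_res)` with `V_id(t) = V_int + 2t·Cov +
t²·V_slope`, computed **per posterior draw** and then summarised (mean of
ratios, not ratio of means), so the 95% intervals propagate
variance-component uncertainty.  Draws where the quadratic form goes
numerically negative are clipped to zero and counted.  The denominator
excludes aquarium and unit variances by default — the ratio of
among-individual to among-individual-plus-residual variance — with a switch
to include them for sensitivity analyses.  Binary-trait R_C is on the
latent (liability) scale with residual 1; no observed-scale transformation
is attempted.  The grid is 1 °C (0.1 °C for SGR, whose skewed-U curve needs
the finer grid to locate its minimum); extremes are the grid arg-min/max of
the posterior mean with ties broken toward the warmer temperature, and flat
curves are flagged.

Correlations are per-draw `Cov/√(V_a·V_b)`: intercept–slope within a trait
from its univariate slopes fit; cross-trait intercept–intercept and
slope–slope from bivariate fits.  Slope–slope correlations are refused for
traits without random-slope support — there is no plasticity variation to
correlate.  In bivariate fits the residuals, aquarium and unit effects are
independent between traits; only the individual-level G is joint.  The full
five-trait joint model is out of scope; pairwise bivariate models answer
the same questions one pair at a time, at the cost of not sharing
information across pairs.

## 6. Pipeline (`thermnorm.pipeline`, `thermnorm.cli`)

`run_pipeline` chains simulate → respirometry → trait table → per-trait
intercepts and slopes fits → DIC comparison → repeatability and
correlations → report, aborting with the stage name on failure.
Repeatability is reported from the slopes fit when support is strong,
otherwise from the intercepts fit (flat).  `trace_level=False` skips trace
synthesis and uses the simulator's trial-level truth directly — faster, and
it isolates the statistical stages from trace-processing error; the default
(`True`) exercises the full fidelity path.  Every output CSV begins with
comment lines recording package version, seed and a configuration hash;
floats are written in shortest round-trip form and parsed with round-trip
precision.  The CLI is a thin layer over these functions.

## 7. What the synthetic tests do and do not show

Passing recovery tests show the estimation machinery is *internally*
consistent: data generated from the assumed model, at the assumed scale,
yield correct support calls, parameter coverage and repeatability curves.
Real respirometry data differ in ways the generator deliberately omits:
probe drift and temperature-dependent O₂ solubility, non-linear within-cycle
mixing, diel activity cycles inside the chamber, non-Gaussian residuals,
non-linear reaction norms, and tracking artefacts in the behavioural data.
Conclusions about any real dataset rest on the usual model checks, not on
these tests.

## 8. Numerical choices and edge cases

* R² := 0 for zero-variance responses; slope := NaN and cycle unusable for
  < 3 points or zero time variance.
* Lowest-10% pool size is ⌈0.1 N⌉ with minimum 1; the SMR pool must hold at
  least 2 cycles.
* `G` draws are guarded by the positive-definiteness of the full
  conditional (scale matrix includes the diagonal prior term); every stored
  draw is checked PSD in the tests.
* Truncated-normal draws use the inverse-CDF with clipping and a sign
  guard for the astronomically deep tail (|η| > 8).
* pMCMC = 2·min(P(draw > 0), P(draw < 0)), floored at 1/n_draws.
* The acceptance script and test suite size their simulations (test MCMC
  profile; 4-fish noise-free round trip; 20-replicate recovery) as the
  package's standard quick-verification configuration.

## 9. Known limitations

* Linear reaction norms only; the repeatability quadratic follows from
  that linearity.
* No zero-altered count family for activity/feeding; binary only.
* Binary-trait repeatability is latent-scale; no observed-scale
  back-transformation.
* Single-chain sampling; convergence is monitored by ESS, not cross-chain
  diagnostics.
* The bivariate (not five-trait) correlation structure ignores
  conditioning on the remaining traits.
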