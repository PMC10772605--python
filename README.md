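# thermnorm

**Among-individual variation in thermal plasticity of fish metabolic and
behavioural traits.**

`thermnorm` is a reusable Python pipeline for a classic question in
ecophysiology: when the environment cools, do individuals differ in *how
much* their physiology and behaviour change — and do those plasticities
co-vary?  It targets the study design in which the same fish (here modelled
on juvenile cunner, a winter-dormant temperate wrasse) are repeatedly
measured at a ladder of temperatures (14, 11, 8, 5, 2 °C) for:

* **SMR** — standard metabolic rate, from overnight intermittent-closed
  respirometry (mean of the lowest 10% of oxygen-uptake recordings after
  R²-based outlier exclusion),
* **MMR** — maximum metabolic rate (first post-chase recording), and
  **AS = MMR − SMR**, the aerobic scope,
* **SGR** — specific growth rate, `100 · (ln m₁ − ln m₀)/days`, aligned at
  growth-interval midpoint temperatures,
* **movement activity** and **food intake**, heavily zero-inflated and
  analysed as binary traits.

## The model

Each trait is a linear thermal reaction norm per individual *j*:

```
y_ij = β₀ + β₁·t_ij + β₂·mass_ij + u0_j + u1_j·t_ij + a_aq(ij) + c_unit(ij) + e_ij
(u0_j, u1_j) ~ N(0, G),   G = [[V_int, Cov], [Cov, V_slope]]
```

with temperature centred at 8 °C and body mass z-scaled.  The package fits
**random-intercepts** (`u1 ≡ 0`) against **random-slopes** models by Gibbs
sampling (probit latent-variable augmentation for binary traits, residual
variance fixed at 1) and compares them by **DIC**: ΔDIC ≥ 10 is strong
support for among-individual variation in plasticity, 5–10 substantial,
less is none.  From the posterior of `G` it derives the headline
quantities:

* **conditional repeatability**
  `R_C(t) = V_id(t) / (V_id(t) + V_res)` with
  `V_id(t) = V_int + 2t·Cov + t²·V_slope`, per 1 °C (0.1 °C for SGR, to
  locate its repeatability minimum), and
* **reaction-norm correlations**: intercept–slope within traits, and
  intercept–intercept / slope–slope across traits from bivariate fits.

A first-class synthetic-data module generates complete studies — raw O₂
traces with background (microbial) respiration, masses, activity and
feeding records — from known parameters, so every stage is testable end to
end with ground truth.

## Worked example

```python
from thermnorm import RunConfig, SimulationConfig, TEST_MCMC, run_pipeline

report = run_pipeline(RunConfig(
    seed=1,
    simulation=SimulationConfig(seed=1),   # 73 fish, 5 aquaria, 14→2 °C
    mcmc=TEST_MCMC,                        # 26k iterations; default is 650k
))
print(report.comparisons[["trait", "delta_dic", "support"]].to_string(index=False))
```

prints (seed 1):

```
         trait   delta_dic support
           smr  176.557817  strong
           mmr  175.314244  strong
            as  183.144228  strong
           sgr   42.562537  strong
  activity_day   -0.336529    none
activity_night    2.805343    none
```

Metabolic and growth traits show strong support for among-individual
plasticity variation; behaviour shows none — the generator's defaults
encode exactly this structure (intercept–slope correlation 0.8 and
temperature-increasing individual variance for metabolic traits, zero slope
variance for behaviour).  Correspondingly `report.correlations` gives the
SMR intercept–slope correlation as 0.83 [0.67, 0.96], and
`report.repeatability` shows SMR repeatability falling from 0.80 at 14 °C
to 0.29 at 2 °C, while the activity curves are flat.

The same stages are exposed on the command line
(`thermnorm simulate | process-respirometry | build-traits | fit | compare |
repeatability | correlate | all`), reading and writing plain CSV with
traceability headers.

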