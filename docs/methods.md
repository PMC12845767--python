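# Methods

## Scope and structure

`iasrisk` implements a forward Monte Carlo exposure model: environmental
concentration reconstruction → simulated population → per-individual
aggregate dose → risk characterisation → global sensitivity analysis. Each
stage is a separate module with a declarative parameter model, so the same
machinery runs with the shipped configuration, a user YAML file, or inputs
calibrated from raw field-measurement tables.

## Input distributions

Every stochastic input is a `DistributionSpec` (point, uniform, truncated
normal, or lognormal) with units. Defaults (all editable in
`src/iasrisk/data/default_config.yaml`):

| Input | Distribution | Units | Rationale |
|---|---|---|---|
| well-water total As | Lognormal, range-calibrated to 0.000735–0.11 | mg/L | trace-metal concentrations are canonically right-skewed |
| soil total As | Uniform[1.92, 7.91] | mg/kg | only a survey range is known → maximum entropy |
| lake-water total As | Uniform[0.005, 0.0097] | mg/L | same |
| clam tissue total As (dw) | TruncNorm(5.67, 3, [0, 14.67]) | mg/kg | measured mean/SD; cap at mean + 3 SD |
| bioaccumulation factor (BAF) | Uniform[10.3, 22] | L/kg | literature range |
| dry-season factor | TruncNorm(6.71, 4.50, [2.21, 13.66]) | – | dry-season concentration enrichment in lake fish |
| aquatic iAs fraction | Uniform[0.117, 0.142] | – | inorganic share of total As in aquatic tissue |
| crop transfer factors | Uniform per crop (rice 0.006–0.036, corn 0.005–0.027, vegetables 0.0003–0.028, root crops 0.0028–0.007) | – | literature soil-to-crop ranges |
| food intakes | TruncNorm(mean, SD, [0, mean + 3 SD]) per food | g/day | national consumption survey; SD ≫ mean, so truncation at 0 is what creates the realistic right-skewed intake shape |
| water intake | fixed 1.791 | L/day | survey mean; no variability reported |
| body weight / height | sex-specific TruncNorm (male BW 61.3 ± 9.0 kg in [40, 155]; female 54.3 ± 8.5 kg in [35, 145]) | kg / cm | census + anthropometric surveys; sex Bernoulli(0.506 male) |
| RfD / CSF | 0.06 µg/kg-day / 0.032 (µg/kg-day)⁻¹ | | US EPA oral toxicity values for iAs |

### Drinking-water calibration

Only a min–max range from a 72-sample well survey is available. The package
fits a lognormal whose central interval reproduces that range:
`gm = √(lo·hi)`, `σ = ln(hi/gm)/z`. The choice of `z` encodes how the range
is read. Because the printed endpoints are the *sample extremes of n = 72
measurements*, the default uses Hazen plotting positions — the extremes sit
at quantiles 0.5/n and 1 − 0.5/n, i.e. central coverage `1 − 1/n ≈ 0.986` —
giving gm ≈ 9.0 µg/L, σ_log ≈ 1.018 and arithmetic mean ≈ 15.1 µg/L. Reading
the range as a literal 95% interval (σ_log ≈ 1.278, mean ≈ 20.3 µg/L) or as
a uniform (mean ≈ 55 µg/L) inflates the water pathway well beyond its
observed share of total dose; the sample-extremes reading is both the
statistically correct interpretation of a min–max and the one consistent
with the water pathway contributing ~14–15% of the mean aggregate dose.
`calibrate_lognormal_from_range` itself defaults to `coverage=0.95` for
generic use; the `1 − 1/n` convention is applied wherever a range is known
to be the extremes of n samples (the shipped water entry, and
`fit_inputs_from_tables` on raw tables).

## Simulation design

- **One draw per individual per variable.** Concentration variability is
  treated as across-individual variability in a single 10,000-iteration
  loop; there is no nested uncertainty/variability separation.
- **Seasons.** Each individual is assigned rainy or dry with probability
  0.5 each; dry rows multiply the fish chain by a dry-season factor draw.
  The equal mixture is a modelling choice (the seasonal structure of
  consumption is unknown); it reproduces the fish pathway's share of total
  dose to within about a percentage point.
- **Shared soil draw.** One soil concentration is drawn per individual and
  reused across all four crops (one soil environment per person). This does
  not affect pathway means but concentrates soil variance in a single
  sensitivity input — see Limitations.
- **Scenario coupling.** LB and UB differ *only* in the terrestrial iAs
  fraction (0.5 vs 0.9). Under a shared seed, crop concentrations satisfy
  UB = 1.8 × LB exactly and the aquatic/water columns are identical, which
  the tests exploit.
- **Independence.** Intakes, body weight and concentrations are mutually
  independent; no intake–body-weight correlation is modelled.
- **Clam dry-weight basis.** The dry-weight tissue concentration is applied
  to fresh-weight intake with no moisture conversion — a conservative
  convention that overstates the clam pathway relative to a
  moisture-corrected model.
- **Water speciation.** Drinking-water total As is used directly (iAs
  fraction 1.0) in both scenarios, so the absolute water dose is
  scenario-invariant.
- **Reproducibility.** One master seed per scenario; every input variable
  draws from an independent child generator keyed by a hash of the variable
  name (`child_rng(seed, name)`). Same seed ⇒ bit-identical tables; adding
  a variable never perturbs existing draws.

## Risk characterisation

HQ = dose/RfD and ECR = dose × CSF per individual, so ECR/HQ ≡ RfD·CSF =
0.00192 exactly. Exceedance fractions use strict inequality (HQ > 1,
ECR > 10⁻⁶, ECR > 10⁻⁴), and 1001-point empirical CDF grids are exported
for plotting. ECR is deliberately not capped at 1: at the simulated doses
the linear low-dose extrapolation is far outside its validity range, and
values above ~0.1 should be read as "orders of magnitude beyond the
benchmark", not as calibrated probabilities.

## Sensitivity analysis

The 18 sampled primitives (4 environmental concentrations, BAF, dry-season
factor, aquatic iAs fraction, 4 transfer factors, 6 intakes, body weight)
form the design matrix; the binary season flag is excluded (its multiplier
is included). SRC is OLS on z-scored columns (p-values from the usual t
statistics). PRCC rank-transforms every column (average ranks for ties) and
computes each input's partial correlation with the response ranks
controlling for all 17 other inputs, via the precision matrix of the rank
correlation matrix; p-values use t = r·√(df/(1−r²)) with **df = n − 19**
(n − 2 − 17 controlled covariates). Tornado exports sort by |coefficient|
with alphabetical tie-breaks and flag significance at p < 0.05.

## Synthetic field tables

`generate_field_tables` emulates raw field data: 72 well-water values from
the range-calibrated lognormal (inverse-CDF sampled between the range
quantiles, so all values respect the survey range), plus soil, lake and
clam values uniform within their survey ranges. These are synthetic
stand-ins with the right marginal structure — they carry no spatial
correlation, no well-type or danger-zone covariates, no measurement error
model, and no temporal trend. Tests passing on them demonstrate the
calibration loop (table → fitted inputs → simulated doses) is
self-consistent, not that the pipeline has been validated against real
monitoring data.

## Numerical choices and problem sizes

Truncated-normal sampling and moments use `scipy.stats.truncnorm`;
lognormal draws use the generator's native method. Analytic truncated
means are cross-checked in tests against direct quadrature and large-n
simulation. The default run size is n = 10,000 iterations per scenario
(the unit-test fixtures use n = 4,000, with 10⁵ draws for moment checks);
a dual-scenario run with sensitivity completes in seconds. Headline-number
checks average population means over five seeds to reduce seed-to-seed
noise.

## Subgroups

The pregnancy subgroup is a *mechanism*, not a calibrated model: a
configurable fraction of individuals is relabelled with female
anthropometrics, and per-food intake multipliers can be applied to the
flagged rows. No published parameterisation of that subgroup's intakes
exists, so the default (no modifiers) is exploratory and the subgroup is
excluded from the reproduction checks.

## Known limitations

- No mechanistic uptake modelling (soil chemistry, arsenite/arsenate
  kinetics), no spatial stratification, no age stratification (intake data
  unavailable), no dermal or inhalation routes, no lifetime averaging
  beyond the daily-dose convention.
- The shared-soil design concentrates the soil contribution of all four
  crop pathways in the single `soil_As` sensitivity input. Reported
  rankings that label per-crop concentration variables (e.g. "iAs in
  rice") fold soil and transfer-factor variance together; here that
  variance splits between `soil_As` (top-5) and the crop's `TF_*` input,
  which lands at rank 5–6. Interpret cross-study ranking comparisons with
  that mapping in mind.
- Transfer and bioaccumulation factors come from other geochemical
  settings; volcanic soils may transfer arsenic differently.
- The drinking-water distribution is a documented reconstruction from a
  printed range, not a fit to the underlying 72-sample dataset (not
  published).
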