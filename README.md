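# iasrisk

Probabilistic aggregate exposure and health-risk assessment for **inorganic
arsenic (iAs)** through food and drinking-water pathways, built for
post-disaster settings where only sparse environmental measurements exist.
The motivating application is a volcanic-eruption scenario (Taal 2020,
Batangas, Philippines): ashfall mobilises arsenic into well water,
agricultural soil, lake water and lake-harvested shellfish, and the question
is how much inorganic arsenic residents ingest each day and what health risk
that implies.

The package is for exposure scientists and environmental-health analysts who
need a transparent, fully reproducible Monte Carlo pipeline from raw
concentration ranges to population risk metrics and sensitivity rankings.

## The model

For each of *n* simulated individuals (default *n* = 10,000), the aggregate
daily dose is

```
E = Σᵢ Cᵢ · IRᵢ / BW        [µg/kg bw/day]
```

where `Cᵢ` is the iAs concentration in medium *i* (µg/g food, µg/L water),
`IRᵢ` the individual's intake rate (g/day; water fixed at 1.791 L/day) and
`BW` the individual's body weight (kg). Concentrations in edible media are
reconstructed from environmental measurements:

- **fish** = lake-water As × bioaccumulation factor (Uniform[10.3, 22] L/kg)
  × seasonal factor (1 in the rainy season, TruncNorm(6.71, 4.50, [2.21,
  13.66]) in the dry season) × aquatic iAs fraction (Uniform[0.117, 0.142]);
- **clam** = tissue total As (TruncNorm(5.67, 3, [0, 14.67]) mg/kg dw) × the
  same aquatic iAs fraction;
- **crops** (rice, corn, vegetables, root crops) = soil As × crop-specific
  soil-to-crop transfer factor × terrestrial iAs fraction — 0.5 in the
  lower-bound (LB) scenario, 0.9 in the upper-bound (UB) scenario;
- **drinking water**: well-water total As used directly, sampled from a
  lognormal calibrated to the surveyed range 0.000735–0.11 mg/L.

Risk metrics: hazard quotient `HQ = E / RfD` (RfD = 0.06 µg/kg-day) and
excess lifetime cancer risk `ECR = E × CSF` (CSF = 0.032 (µg/kg-day)⁻¹).
Global sensitivity of the total dose to the 18 sampled inputs is quantified
with standardized regression coefficients (SRC) and partial rank correlation
coefficients (PRCC).

All model parameters live in a validated YAML configuration
(`src/iasrisk/data/default_config.yaml`); every input distribution is
declarative and every random draw comes from a named child stream of one
master seed, so runs are bit-reproducible and adding an input never perturbs
the others.

## Worked example

```sh
iasrisk run --scenario both --n 10000 --seed 1 --out results/
iasrisk report --in results/
```

prints

```
run seed=1 n=10000 config=3d41bb6b153c

scenario LB (terrestrial iAs fraction 0.5)
  total dose (ug/kg bw/day): mean 3.11 +/- 1.62, median 2.79, p5-p95 1.12-6.18
  pathway shares: clam 25.5%, rice 23.2%, drinking_water 15.4%, fish 14.7%, vegetables 11.0%, corn 9.6%, root_crops 0.6%

scenario UB (terrestrial iAs fraction 0.9)
  total dose (ug/kg bw/day): mean 4.21 +/- 2.2, median 3.77, p5-p95 1.5-8.42
  pathway shares: rice 30.8%, clam 18.8%, vegetables 14.6%, corn 12.7%, drinking_water 11.4%, fish 10.9%, root_crops 0.8%
  [LB] fraction HQ>1: 1.0, fraction ECR>1e-6: 1.0
  [UB] fraction HQ>1: 1.0, fraction ECR>1e-6: 1.0
```

Reading: under conservative speciation assumptions (LB) the average
simulated resident ingests ~3.1 µg iAs per kg body weight per day — about
fifty times the reference dose — with clams the largest contributor; under
worst-case speciation (UB) the mean rises to ~4.2 and rice dominates. Every
simulated individual exceeds both the non-cancer threshold (HQ > 1) and the
10⁻⁶ cancer-risk benchmark.

`iasrisk sensitivity --scenario both --out results/` writes the SRC/PRCC
table; `iasrisk fixtures --seed 1 --out fixtures/` generates synthetic raw
field-measurement tables for testing calibration workflows. As a library:

```python
from iasrisk import ScenarioConfig, load_default_config, run_scenario

result = run_scenario(ScenarioConfig.lower_bound(random_seed=1),
                      load_default_config())
print(result.doses["total_dose"].mean())   # ~3.1 µg/kg bw/day
```

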