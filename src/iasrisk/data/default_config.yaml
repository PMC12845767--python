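# Default parameterisation: inorganic-arsenic exposure, post-eruption Taal
# (Batangas, Philippines) study inputs.
#
# Conventions:
#   - lognormal given as a lo/hi range is calibrated so that range is the
#     central `coverage` interval.  The drinking-water range is the min-max
#     of 72 well samples, read with Hazen plotting positions:
#     coverage = 1 - 1/72 = 0.9861111...
#   - truncated_normal intakes are bounded at 0 and ~mean + 3*SD.
environmental:
  water_As:
    family: lognormal
    lo: 0.000735
    hi: 0.11
    coverage: 0.98611111111
    units: mg/L
  soil_As:
    family: uniform
    lo: 1.92
    hi: 7.91
    units: mg/kg
  lake_As:
    family: uniform
    lo: 0.005
    hi: 0.0097
    units: mg/L
  clam_total_As_dw:
    family: truncated_normal
    mean: 5.67
    sd: 3.0
    lo: 0.0
    hi: 14.67          # mean + 3*SD cap convention
    units: mg/kg
  BAF:
    family: uniform
    lo: 10.3
    hi: 22.0
    units: L/kg
  dry_season_multiplier:
    family: truncated_normal
    mean: 6.71
    sd: 4.50
    lo: 2.21
    hi: 13.66
    units: dimensionless
  aquatic_iAs_fraction:
    family: uniform
    lo: 0.117
    hi: 0.142
    units: dimensionless
transfer_factors:
  factors:
    rice:
      family: uniform
      lo: 0.006
      hi: 0.036
      units: dimensionless
    corn:
      family: uniform
      lo: 0.005
      hi: 0.027
      units: dimensionless
    vegetables:
      family: uniform
      lo: 0.0003
      hi: 0.028
      units: dimensionless
    root_crops:
      family: uniform
      lo: 0.0028
      hi: 0.007
      units: dimensionless
intakes:
  water_intake_L_day: 1.791
  foods:
    fish:
      family: truncated_normal
      mean: 59.0
      sd: 488.8
      lo: 0.0
      hi: 1525.4
      units: g/day
    clam:
      family: truncated_normal
      mean: 8.5
      sd: 70.4
      lo: 0.0
      hi: 219.8
      units: g/day
    rice:
      family: truncated_normal
      mean: 263.0
      sd: 872.8
      lo: 0.0
      hi: 2881.4
      units: g/day
    corn:
      family: truncated_normal
      mean: 6.0
      sd: 541.2
      lo: 0.0
      hi: 1629.6
      units: g/day
    vegetables:
      family: truncated_normal
      mean: 58.0
      sd: 680.8
      lo: 0.0
      hi: 2100.5
      units: g/day
    root_crops:
      family: truncated_normal
      mean: 7.0
      sd: 104.7
      lo: 0.0
      hi: 321.1
      units: g/day
anthropometrics:
  sex_proportion_male: 0.506
  male_body_weight:
    family: truncated_normal
    mean: 61.3
    sd: 9.0
    lo: 40.0
    hi: 155.0
    units: kg
  female_body_weight:
    family: truncated_normal
    mean: 54.3
    sd: 8.5
    lo: 35.0
    hi: 145.0
    units: kg
  male_height:
    family: truncated_normal
    mean: 163.0
    sd: 6.5
    lo: 60.0
    hi: 220.0
    units: cm
  female_height:
    family: truncated_normal
    mean: 154.0
    sd: 6.0
    lo: 55.0
    hi: 210.0
    units: cm
risk:
  rfd: 0.06
  csf: 0.032
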