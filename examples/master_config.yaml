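# Annotated master configuration for the projection pipeline.
#
# Units follow what people quote: prevalences and trends in percent /
# percentage points, mortality as per-person-year hazards, incidence as
# annual new cases per 100,000.  See examples/custom_config.py for a
# runnable end-to-end use of this schema.

label: demo-country

horizon:
  start: 2010          # baseline year (initial states are set here)
  end: 2030            # last projected year (inclusive)

# Reporting bands; the engine itself runs on single-year age cells unless
# engine.grid is set to "band".
bands: ["25-34", "35-44", "45-54", "55-64", "65-74", "75+"]

demography:
  # CSV columns: year,sex,age_lower,age_upper,count (empty age_upper = open band).
  # Sparse anchor years are densified by per-stratum geometric interpolation.
  population_csv: inputs/population.csv
  interpolate: true

baseline_prevalence:
  diabetes:            # percent, either one value per sex or per (sex, band)
    M: {25-34: 1.0, 35-44: 3.0, 45-54: 8.0, 55-64: 15.0, 65-74: 18.0, 75+: 18.0}
    F: {25-34: 1.0, 35-44: 4.0, 45-54: 10.0, 55-64: 18.0, 65-74: 20.0, 75+: 20.0}

rates:
  mortality:           # all-cause mortality, per person-year
    M: {25-34: 0.002, 35-44: 0.003, 45-54: 0.007, 55-64: 0.016, 65-74: 0.04, 75+: 0.12}
    F: {25-34: 0.001, 35-44: 0.002, 45-54: 0.005, 55-64: 0.011, 65-74: 0.03, 75+: 0.11}
  incidence:
    # either sex-level rates applied across bands ...
    per_100k: {M: 900, F: 1100}
    denominator: total          # "total" population or "susceptible" person-time
    # ... or fully band-specific hazards:
    # per_band_hazard:
    #   M: {25-34: 0.004, ...}

relative_risks:
  rr_mort_dm: 1.8      # all-cause mortality, diabetic vs non-diabetic
  rr_dm_obese: 7.2     # diabetes incidence, obese vs non-obese
  rr_dm_smoker: 1.44   # diabetes incidence, daily smoker vs non-smoker
  # any of these may be sex-specific: rr_mort_dm: {M: 1.5, F: 2.5}

trends:
  obesity:
    baseline_pct: {M: 20.0, F: 28.0}
    trend_pp_per_year: 0.5      # absolute percentage points per year
    trend_pp_overrides: {}      # per-band exceptions, e.g. {25-34: 0.2}
    cap_pct: 80                 # saturation level of the obesity rise
  smoking:
    baseline_pct: {M: 45.0, F: 10.0}
    trend_pp_per_year: 0.0      # flat by default

# Optional counterfactual prevention program.
scenario:
  start_year: 2012
  duration: 10                  # linear phase-in window, years
  target_fraction_healthy: 0.1  # parsed and stored; inert under "population"
  target_fraction_obese: 0.4
  target_fraction_smoker: 0.2
  obesity_reduction: 0.2        # relative reduction reached at full phase-in
  smoking_reduction: 0.3
  reading: population           # "population" or "targeted"

engine:
  grid: single_year             # "single_year" (exact cohort aging) or "band" (1/w)
  demography: rescale           # "rescale" to exogenous denominators or "closed"
  joint_rr: multiplicative      # combined obese-smoker incidence RR rule
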