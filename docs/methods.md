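# Methods

## Model structure

`dmproj` implements a discrete-time multi-state cohort model of adult type
2 diabetes. Each (sex, age) stratum holds seven compartments: four
mutually exclusive exposure states among the non-diabetic — healthy,
obese-only, smoker-only, obese-smoker — the diabetes state, and two
absorbing death states (diabetes-related and other causes). One cycle is
one calendar year. Within a cycle the operations run in a fixed,
result-defining order:

1. **Deaths.** Every living compartment loses `1 − exp(−m₀)` of its
   members to other-cause death; the diabetes compartment faces the
   competing total `1 − exp(−(m₀+e))`, split between causes in proportion
   to the hazards.
2. **Incidence.** Each exposure compartment `g` loses a fraction `q_g` to
   the diabetes compartment. There is no remission: no edge leaves
   diabetes except to the death states.
3. **Aging.** A fraction `1/w` of every living compartment advances to the
   next age cell, `w` being the cell width in years. The engine's age grid
   is configurable: with single-year cells (`w = 1`, the default) this is
   exact cohort aging; with band-wide cells it is the usual
   exponential-sojourn approximation. The top cell is open-ended.
4. **Entrants / demographic alignment.** Entrants join the youngest cell
   diabetes-free, distributed over exposure compartments by the youngest
   band's current prevalences. Under demographic alignment (`rescale`
   mode) every band's living population is then scaled to its exogenous
   trajectory; the residual is booked as net migration at the band's
   current composition. In `closed` mode nothing is rescaled and person
   conservation holds exactly: living(t+1) + new deaths = living(t) +
   entrants, per sex, to machine precision (with the recorded migration
   term, the same identity holds exactly in rescale mode).
5. **Trend rebalance.** The non-diabetic pool of each stratum is re-split
   into the four exposure compartments at the trend-updated (and
   scenario-adjusted) prevalences, assuming independence of obesity and
   smoking. Rebalancing never creates or destroys diabetes cases.

The engine is fully deterministic; identical configurations produce
bit-identical trajectories.

Changing the within-cycle order changes results; one visible consequence
of rebalancing last is that an intervention's first cycle still runs on
pre-program exposure, so the counterfactual gap opens one cycle after the
program starts.

### Why single-year cells for the reference configuration

Band-wide `1/w` aging moves band-*average* members between bands. Where
the prevalence age-gradient is steep (e.g. ~22% at 45–54 against ~42% at
55–64 in the Syrian baseline), that flow dilutes the older band by several
percentage points per year — an artefact of the sojourn approximation, not
of the epidemiology — and visibly corrupts 20-year trajectories. Running
the same transition rates on single-year cells (people cross band
boundaries carrying their own prevalence) removes the artefact at
negligible cost; band-wide cells remain available via `grid_mode="band"`
and are used in tests of the approximation itself.

## Rates and parameters

| parameter | units | default (Syria preset) | provenance |
|---|---|---|---|
| all-cause mortality `m` | per person-year, by sex × band | 0.0010–0.13 | reconstructed abridged schedule at plausible pre-conflict Syrian levels; config-supplied |
| mortality RR `rr_mort_dm` | dimensionless | 1.5 (M) / 2.5 (F) | unpublished in the source analysis; sex pattern follows cohort studies reporting higher relative mortality in diabetic women; magnitudes reconstructed (see below) |
| obesity incidence RR `rr_dm_obese` | dimensionless | 12.41 | upper end of meta-analytic estimates (reviews span ≈7.2–12.4) |
| smoking incidence RR `rr_dm_smoker` | dimensionless | 1.44 | meta-analytic active-smoking estimate |
| population incidence | per 100,000/yr, by sex | 1,190 (M) / 1,570 (F) | published illness–death back-calculation output for 2003 |
| obesity trend | percentage points/yr | +1.0 (+0.2 for 25–34), cap 80% | published trend rule |
| smoking trend | percentage points/yr | 0 | published no-change assumption |
| under-diagnosis multiplier | — | 1.5 (already folded into the published prevalences) | published convention |

**Mortality partition.** All-cause mortality is split at baseline
prevalence: `m₀ = m/(1 − p + p·RR)`, `m₁ = RR·m₀`, excess
`e = m₀(RR − 1)`. The partition is computed once at baseline and the
resulting hazards are held fixed over the horizon; as prevalence rises the
implied all-cause mortality therefore rises with it, which is the intended
behaviour of a worsening epidemic.

**Incidence conventions.** Sex-level incidence figures quoted "per
100,000 per year" are interpreted as new cases per total adult population
(the convention of published population incidence figures) and converted
to a susceptible-pool hazard by dividing by `1 − p` at baseline;
`denominator: susceptible` switches to the literal-hazard reading.
Band-specific hazards (e.g. from the package's own back-calculation) can
be supplied instead.

**Probability-scale apportionment.** The aggregate incidence hazard is
first converted to an annual probability (`1 − exp(−i)`) and *then*
apportioned over exposure compartments by relative risk. Apportioning
hazards first and converting each compartment separately introduces a
convexity (Jensen) error of order `i²·var(RR)` in the aggregate inflow,
which breaks exact share-weighted conservation and strict monotonicity in
the RRs; the probability-scale construction keeps both exact, and makes
the engine agree with the two-compartment closed form exactly under flat
exposure trends.

**Overlap handling.** The source analysis states that conditional
membership probabilities were estimated but not how. We adopt independence
of obesity and smoking within (sex, band) among the non-diabetic;
exposure prevalences are read as prevalences among the non-diabetic
population. The joint obese-smoker incidence RR is multiplicative by
default (`joint_rr: max` is available).

## Incidence back-calculation

`estimate_incidence_from_prevalence` inverts a cross-sectional prevalence
curve under zero remission. A disease-free cohort enters at the model's
lower age bound and is swept upward; within each band a constant incidence
hazard is solved by bisection on [0, 1] (tolerance 1e−10, 200-iteration
cap, error naming the offending band on failure) so that the simulated
single-year recursion matches the target prevalence at the band midpoint.
The open-ended last band uses the nominal band width for midpoint
placement. Where the target curve falls faster than excess mortality can
explain, incidence is floored at zero and a diagnostic logged — with zero
remission a declining prevalence is otherwise infeasible, and the
round-trip guarantee (forward simulation reproduces the inputs) holds only
for curves that are realizable under the supplied mortality.

## Scenarios

A prevention program is a phased relative reduction of obesity and/or
smoking prevalence acting only on the non-diabetic pool, linear over its
duration and persistent afterwards. Two operational readings of
"target a fraction of each pool for a stated reduction" are implemented:
`targeted` (pool-level multiplier `1 − fraction·reduction·phase`) and
`population` (multiplier `1 − reduction·phase`, ignoring the targeting
fractions). The reference configuration uses the `population` reading,
which is the one that reproduces the published intervention trajectory;
under the `targeted` reading the program's full effect is a ~10% exposure
reduction and the 2022 relative prevalence reduction stays below 6%. The
healthy-target fraction is parsed and stored but has no operational
meaning under either reading (healthy members have no exposure to
reduce).

## Demography

Populations are stratum-indexed count tables. Sparse anchors are densified
by per-stratum geometric interpolation (constant annual growth rate
between anchors, anchor values preserved bit-exactly, extrapolation
refused). Published report cells of the form `count (prevalence%)` are
inverted to denominators (`count/prevalence`); totals rows are reserved as
checksums. Printed prevalences are rounded to one decimal, so
reconstructed denominators carry a relative uncertainty of up to half a
unit in the last printed digit — largest where prevalence is small (the
youngest bands) — which is one reason the reproduction tolerances below
are as wide as they are.

## The synthetic generator

`generate_country` builds complete input bundles from constant
per-stratum hazards: population anchors densified geometrically, baseline
prevalence either flat or derived from the generating hazards
(`baseline_from_hazards`), an all-cause mortality schedule assembled as
`(1−p)m₀ + p(m₀+e)` so the downstream partition recovers the generating
rates exactly, and a ground-truth record holding the hazards and the
closed-form two-compartment prevalence trajectory. It emulates the
*structure* of national inputs (stratified counts and rates with known
generative process), not their texture: no survey noise unless requested,
no cohort effects, no migration, no age curvature within bands. Passing
tests on synthetic bundles therefore demonstrates correctness of the
machinery, not goodness-of-fit of the model family to any real country.
Noise (`perturb`) is mean-one multiplicative lognormal
(`exp(N(−σ²/2, σ))`) applied to input rates and prevalences with clipping
to [0, 1]; the engine itself is never stochastic.

## Numerical choices

* Hazard→probability conversion `1 − exp(−h)` throughout; competing risks
  within the diabetes compartment split the total death probability in
  proportion to hazards.
* Bisection everywhere a scalar root is needed (robustness over speed at
  this scale); tolerances as above.
* The open top band is seeded across single-year cells with a geometric
  survival-like decay (0.10/yr by default) — a crude stand-in for the
  within-band age distribution; its influence on band-level outputs is
  limited to the 75+ stratum.
* Exposure rebalancing clips trend output to [0, cap] for obesity and
  [0, 1] for smoking; floating-point dust below −1e−9 in occupancies is
  scrubbed to zero, anything more negative raises with the stratum and
  compartment named.
* The 20–79 comparison view retains a configurable fraction (default 0.5)
  of the open 75+ band as "75–79", applied to counts and denominators
  alike so the band's prevalence is unchanged, and adds a zero-prevalence
  20–24 population to the denominator.

## Reproduction scope and known limitations

The Syria preset reproduces the published 2022 endpoints closely (overall
prevalence 21.3% vs 21.3%, case count within 0.1%, sex-specific relative
increases within the stated tolerance bands, 20–79 view 18.1% vs 18.4%,
intervention endpoint 17.4% vs 16.4%). Three published quantities are
*not* reproducible from the published inputs under any configuration we
could construct, and we report our model's honest values instead:

* **Interior years** (2011 overall 14.1% vs 13.1%; 2013 under the
  intervention 14.2% vs 12.6%). The published trajectory is more convex in
  time than constant per-sex transition rates plus the stated obesity
  trend can produce: obesity rising linearly moves the compartment-mixture
  incidence roughly linearly, while the published young-band prevalences
  accelerate sharply after 2011.
* **The young-band surge** (25–34 fold increase 8.2 vs 12.2). A band whose
  2003 prevalence is 0.8% cannot reach 11.1% by 2022 with entrants
  arriving diabetes-free unless its incidence is roughly triple the
  published sex-level rate; the published age-specific incidence
  (405 per 100,000 at 25–34) is lower still. We run the sex-level rates
  age-invariantly — the only reading that reproduces the endpoint totals —
  and accept the young-band shortfall.
* **Back-calculated incidence totals.** The published baseline prevalence
  curve is flat above age 55, which under stationarity caps the implied
  older-age incidence at the replacement level for excess mortality; the
  resulting population rates (≈870 per 100,000 women, ≈540 men with the
  preset mortality) sit well below the published 1,570/1,190. The original
  estimation evidently used age detail (and possibly non-stationarity
  options) that was never printed. The machinery itself round-trips
  exactly on realizable curves, which is what the property tests certify.

Parameters that were used but never published (the three relative risks,
the mortality schedule, the population anchors beyond the report years)
are reconstructed: set once to literature-plausible values chosen to be
jointly consistent with the published endpoint checkpoints, documented in
`dmproj/syria.py`, and exposed as ordinary configuration. They are point
reconstructions, not estimates with uncertainty; no probabilistic
sensitivity analysis is attempted (deliberately out of scope, as are
urban/rural stratification, physical activity and other unmodelled risk
factors, remission, and half-cycle correction).

Problem sizes: the reference projection is 2 sexes × 75 single-year cells
× 7 compartments × 19 cycles and runs in well under a second; property
tests use 6-band or single-band grids and horizons of 8–20 years; the
noisy-recovery check uses 100 replicate seeds at σ = 0.05.
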