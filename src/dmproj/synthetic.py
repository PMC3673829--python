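"""Synthetic country generator with analytic ground truth.

Builds complete, internally consistent input bundles for the projection
pipeline — population trajectories, baseline disease prevalence, mortality
schedules, risk-factor baselines — from *known constant hazards*, so that
every downstream stage (incidence back-calculation, the Markov engine, the
scenario machinery) can be tested against closed-form answers without any
external data.

Constant per-stratum hazards keep the two-compartment illness–death system
solvable in closed form; the generator records those hazards and the
implied prevalence trajectories as ground truth alongside the bundle.
Noise, when requested, is applied to the *inputs* only (the engine itself
stays deterministic) as mean-one multiplicative lognormal perturbations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import CORE_BANDS, SEXES, AgeBand
from .demography import PopulationTable, build_population_trajectory
from .markov import IncidenceSpec, ProjectionConfig, RiskFactorSpec
from .rates import RelativeRisks, forward_prevalence


@dataclass(frozen=True)
class SyntheticCountrySpec:
    """Generating parameters for a synthetic country.

    Hazards are per person-year and constant within stratum over the whole
    horizon; ``growth`` is the annual population growth rate per stratum.
    Uniform-by-sex values may be given as floats.
    """

    seed: int = 0
    start_year: int = 2000
    end_year: int = 2020
    bands: Sequence[AgeBand] = CORE_BANDS
    base_pop: float | Mapping[str, float] = 100_000.0
    growth: float | Mapping[str, float] = 0.02
    incidence: float | Mapping[str, float] = 0.01
    mortality_background: float | Mapping[str, float] = 0.01
    excess_mortality: float | Mapping[str, float] = 0.005
    dm_prev0: float | Mapping[str, float] = 0.05
    obesity0: Mapping[str, float] = field(default_factory=lambda: {"M": 0.25, "F": 0.30})
    smoking0: Mapping[str, float] = field(default_factory=lambda: {"M": 0.40, "F": 0.15})
    obesity_trend: float = 0.0
    smoking_trend: float = 0.0
    obesity_cap: float = 0.80
    rr_dm_obese: float = 2.0
    rr_dm_smoker: float = 1.5
    #: derive the baseline prevalence curve from the generating hazards
    #: (band-midpoint values of the illness–death recursion) instead of the
    #: flat ``dm_prev0`` — yields an age-realizable curve for recovery tests
    baseline_from_hazards: bool = False

    def _by_sex(self, v) -> dict[str, float]:
        return dict(v) if isinstance(v, Mapping) else {s: float(v) for s in SEXES}

    def validate(self) -> None:
        for name in ("incidence", "mortality_background", "excess_mortality", "growth", "base_pop"):
            for s, v in self._by_sex(getattr(self, name)).items():
                if name != "growth" and v < 0:
                    raise ValueError(f"{name}[{s}] must be >= 0")
        for s, v in self._by_sex(self.dm_prev0).items():
            if not 0.0 <= v < 1.0:
                raise ValueError(f"dm_prev0[{s}] must be in [0, 1)")
        i = self._by_sex(self.incidence)
        m = self._by_sex(self.mortality_background)
        e = self._by_sex(self.excess_mortality)
        for s in SEXES:
            if i[s] + m[s] >= 1.0 or m[s] + e[s] >= 1.0:
                raise ValueError(
                    f"hazards for sex {s} imply a per-cycle transition probability >= 1"
                )
            if e[s] > 0.0 and m[s] < 1e-12:
                raise ValueError(
                    f"excess mortality for sex {s} requires positive background mortality "
                    "(the implied mortality rate ratio is otherwise unbounded)"
                )
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")


def closed_form_prevalence(
    p0: float, i: float, m0: float, e: float, n_years: int
) -> np.ndarray:
    """Prevalence trajectory of a closed cohort under constant hazards.

    Matches the engine's within-cycle order (deaths, then incidence) with
    hazard→probability conversion ``q = 1 − exp(−h)``::

        S' = S·(1−q_m0)·(1−q_i)
        C' = C·(1−q_tot) + S·(1−q_m0)·q_i

    where ``q_tot = 1 − exp(−(m0+e))``.  Returns p_t for t = 0..n_years.
    """
    q_i = 1.0 - np.exp(-i)
    q_m0 = 1.0 - np.exp(-m0)
    q_tot = 1.0 - np.exp(-(m0 + e))
    S, C = 1.0 - p0, p0
    out = np.empty(n_years + 1)
    out[0] = p0
    for t in range(1, n_years + 1):
        S, C = S * (1 - q_m0) * (1 - q_i), C * (1 - q_tot) + S * (1 - q_m0) * q_i
        out[t] = C / (S + C)
    return out


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the generating ground truth."""

    spec: SyntheticCountrySpec
    population: PopulationTable          # annual, all strata
    dm_prevalence: dict                  # (sex, band label) -> proportion
    mortality: dict                      # (sex, band label) -> all-cause rate
    incidence_hazard: dict               # (sex, band label) -> per person-year
    risk: RiskFactorSpec
    truth: dict                          # generating hazards & analytic curves

    def config(self, demography_mode: str = "closed", scenario=None) -> ProjectionConfig:
        """A ready-to-run projection configuration over the bundle."""
        return ProjectionConfig(
            start_year=self.spec.start_year,
            end_year=self.spec.end_year,
            bands=tuple(self.spec.bands),
            population=self.population,
            dm_prevalence=self.dm_prevalence,
            risk=self.risk,
            relative_risks=RelativeRisks(
                rr_mort_dm=self.truth["rr_mort_dm"],
                rr_dm_obese=self.spec.rr_dm_obese,
                rr_dm_smoker=self.spec.rr_dm_smoker,
            ),
            mortality=self.mortality,
            incidence=IncidenceSpec(per_band_hazard=self.incidence_hazard, denominator="susceptible"),
            grid_mode="band",
            demography_mode=demography_mode,
            scenario=scenario,
            label=f"synthetic-{self.spec.seed}",
        )

    def write(self, directory) -> None:
        """Emit the bundle as the CSV layout the pipeline reads."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.population.to_csv(directory / "population.csv")
        rows = []
        for (s, label) in sorted(self.dm_prevalence):
            band = AgeBand.parse(label)
            rows.append(
                {
                    "sex": s,
                    "age_lower": band.lower,
                    "age_upper": "" if band.upper is None else band.upper,
                    "prevalence": self.dm_prevalence[(s, label)],
                    "mortality_all_cause": self.mortality[(s, label)],
                    "incidence": self.incidence_hazard[(s, label)],
                    "excess_mortality": self.truth["excess"][s],
                }
            )
        pd.DataFrame(rows).to_csv(directory / "rates.csv", index=False)
        pd.DataFrame(
            [
                {"sex": s, "parameter": k, "value": v[s] if isinstance(v, Mapping) else v}
                for s in SEXES
                for k, v in self.truth.items()
                if k != "prevalence_trajectory"
            ]
        ).to_csv(directory / "ground_truth.csv", index=False)


def generate_country(spec: SyntheticCountrySpec) -> SyntheticBundle:
    """Build a consistent input bundle with known generating hazards.

    All-cause mortality is assembled from the generating background and
    excess hazards (``m = (1−p)·m0 + p·(m0+e)``) so that the Barendregt
    partition applied downstream recovers ``m0`` and ``e`` exactly; the
    analytic prevalence trajectory of each stratum is stored for oracle
    tests.  The stored trajectory is the aggregate two-compartment
    solution; the engine apportions incidence over exposure compartments
    on the probability scale, so with flat exposure trends the aggregate
    inflow matches this solution exactly for any incidence RRs.
    Deterministic: the same spec yields a byte-identical bundle.
    """
    spec.validate()
    base = spec._by_sex(spec.base_pop)
    growth = spec._by_sex(spec.growth)
    inc = spec._by_sex(spec.incidence)
    m0 = spec._by_sex(spec.mortality_background)
    exc = spec._by_sex(spec.excess_mortality)
    p0 = spec._by_sex(spec.dm_prev0)

    anchors = PopulationTable()
    n_years = spec.end_year - spec.start_year
    for s in SEXES:
        for b in spec.bands:
            anchors.set(spec.start_year, s, b, base[s])
            anchors.set(spec.end_year, s, b, base[s] * (1.0 + growth[s]) ** n_years)
    population = build_population_trajectory(
        anchors, range(spec.start_year, spec.end_year + 1)
    )

    dm_prev, mort, inc_hazard = {}, {}, {}
    for s in SEXES:
        nb = len(spec.bands)
        if spec.baseline_from_hazards:
            curve = forward_prevalence([inc[s]] * nb, [m0[s]] * nb, [exc[s]] * nb)
        else:
            curve = [p0[s]] * nb
        for k, b in enumerate(spec.bands):
            p_band = float(curve[k])
            dm_prev[(s, b.label)] = p_band
            mort[(s, b.label)] = (1.0 - p_band) * m0[s] + p_band * (m0[s] + exc[s])
            inc_hazard[(s, b.label)] = inc[s]

    risk = RiskFactorSpec.uniform(
        spec.bands,
        obesity=spec.obesity0,
        smoking=spec.smoking0,
        obesity_trend=spec.obesity_trend,
        smoking_trend=spec.smoking_trend,
        obesity_cap=spec.obesity_cap,
    )

    # implied mortality rate ratio between diseased and non-diseased
    rr_mort = {s: (m0[s] + exc[s]) / m0[s] if m0[s] > 0 else 1.0 for s in SEXES}
    truth = {
        "incidence": inc,
        "background_mortality": m0,
        "excess": exc,
        "rr_mort_dm": rr_mort,
        "dm_prev0": p0,
        "prevalence_trajectory": {
            s: closed_form_prevalence(p0[s], inc[s], m0[s], exc[s], n_years) for s in SEXES
        },
        "prevalence_by_band_midpoint": {
            s: forward_prevalence(
                [inc[s]] * len(spec.bands), [m0[s]] * len(spec.bands), [exc[s]] * len(spec.bands)
            )
            for s in SEXES
        },
    }
    return SyntheticBundle(spec, population, dm_prev, mort, inc_hazard, risk, truth)


def perturb(bundle: SyntheticBundle, sigma: float, seed: int) -> SyntheticBundle:
    """Mean-one multiplicative lognormal noise on the bundle's rate inputs.

    ``sigma`` is the log-scale standard deviation; factors are drawn as
    ``exp(N(−σ²/2, σ))`` so the noise is unbiased on the natural scale.
    Proportions are clipped back to [0, 1] after perturbation.  ``sigma=0``
    returns an identical (deep-copied) bundle.
    """
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)

    def jitter(x: float) -> float:
        if sigma == 0.0:
            return x
        return x * float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))

    dm_prev = {k: min(1.0, jitter(v)) for k, v in bundle.dm_prevalence.items()}
    mort = {k: jitter(v) for k, v in bundle.mortality.items()}
    inc = {k: jitter(v) for k, v in bundle.incidence_hazard.items()}
    return SyntheticBundle(
        spec=bundle.spec,
        population=bundle.population,
        dm_prevalence=dm_prev,
        mortality=mort,
        incidence_hazard=inc,
        risk=bundle.risk,
        truth=bundle.truth,
    )
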