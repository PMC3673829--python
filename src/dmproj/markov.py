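"""The discrete-state Markov projection engine.

States per (sex, age cell): four mutually exclusive exposure compartments
among the non-diabetic — healthy, obese-only, smoker-only, obese-smoker —
plus the diabetes compartment and two absorbing death compartments
(diabetes-related and other).  Each annual cycle applies, in this fixed
order:

1. deaths are removed from every living compartment (the diabetes
   compartment faces competing other-cause and disease-related mortality);
2. incident cases move from the exposure compartments to diabetes;
3. aging advances a fraction ``1/w`` of each living compartment to the next
   age cell (``w`` = cell width; single-year cells make this exact cohort
   aging);
4. entrants join the youngest cell, diabetes-free, distributed over the
   exposure compartments by the youngest band's current prevalences; under
   demographic alignment every band is then scaled to its exogenous
   population target (the residual is recorded as net migration at the
   band's current composition);
5. the exposure compartments of the non-diabetic pool are re-split to the
   trend-updated (and scenario-adjusted) exposure prevalences, assuming
   independence of obesity and smoking.

There is no remission: the only outflow from the diabetes compartment is to
the death compartments.  The engine is fully deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import CORE_BANDS, SEXES, SEX_INDEX, AgeBand, AgeGrid
from .demography import PopulationTable
from .rates import RelativeRisks, partition_mortality
from .scenarios import ScenarioSpec, check_within_horizon

log = logging.getLogger(__name__)

# compartment indices
HEALTHY, OBESE, SMOKER, OBESE_SMOKER, DM, DEAD_DM, DEAD_OTHER = range(7)
N_COMP = 7
EXPOSURE = slice(HEALTHY, OBESE_SMOKER + 1)
LIVING = slice(HEALTHY, DM + 1)
COMPARTMENTS = (
    "healthy", "obese_only", "smoker_only", "obese_smoker",
    "diabetes", "dead_dm", "dead_other",
)


class ConfigError(ValueError):
    """Raised when a projection configuration is incomplete or inconsistent."""


# ---------------------------------------------------------------------------
# risk-factor trends


@dataclass(frozen=True)
class RiskFactorSpec:
    """Baseline exposure prevalences and their secular trends per (sex, band).

    Prevalences are proportions of the *non-diabetic* population; trends are
    absolute changes per year (``0.01`` = +1 percentage point per year).
    The obesity trend saturates at ``obesity_cap``; both prevalences are
    clipped to [0, 1].
    """

    obesity0: Mapping[tuple[str, str], float]
    smoking0: Mapping[tuple[str, str], float]
    obesity_trend: Mapping[tuple[str, str], float]
    smoking_trend: Mapping[tuple[str, str], float]
    obesity_cap: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.obesity_cap <= 1.0:
            raise ValueError("obesity cap must lie in (0, 1]")
        for name in ("obesity0", "smoking0"):
            for k, v in getattr(self, name).items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}{k} = {v} outside [0, 1]")

    @classmethod
    def uniform(
        cls,
        bands: Sequence[AgeBand],
        obesity: Mapping[str, float],
        smoking: Mapping[str, float],
        obesity_trend: float = 0.0,
        obesity_trend_overrides: Mapping[str, float] | None = None,
        smoking_trend: float = 0.0,
        obesity_cap: float = 0.80,
    ) -> "RiskFactorSpec":
        """Same baseline for every band of a sex, with per-band trend overrides."""
        overrides = obesity_trend_overrides or {}
        ob0, sm0, obt, smt = {}, {}, {}, {}
        for s in SEXES:
            for b in bands:
                ob0[(s, b.label)] = obesity[s]
                sm0[(s, b.label)] = smoking[s]
                obt[(s, b.label)] = overrides.get(b.label, obesity_trend)
                smt[(s, b.label)] = smoking_trend
        return cls(ob0, sm0, obt, smt, obesity_cap)

    def at(
        self,
        years_elapsed: float,
        factors: tuple[float, float] = (1.0, 1.0),
    ) -> dict[tuple[str, str], tuple[float, float]]:
        """Exposure prevalences after ``years_elapsed`` of trend.

        ``factors`` are scenario multipliers applied to the trend output
        (obesity, smoking); results are capped/clipped so the applied trend
        never pushes a prevalence above the cap or outside [0, 1].
        """
        if years_elapsed < 0:
            raise ValueError("years_elapsed must be >= 0")
        f_o, f_s = factors
        out = {}
        for key in self.obesity0:
            q_o = min(self.obesity_cap, self.obesity0[key] + self.obesity_trend[key] * years_elapsed)
            q_s = self.smoking0[key] + self.smoking_trend[key] * years_elapsed
            q_o = min(1.0, max(0.0, q_o * f_o))
            q_s = min(1.0, max(0.0, q_s * f_s))
            out[key] = (q_o, q_s)
        return out


def apply_risk_trend(
    risk: RiskFactorSpec, years_elapsed: float
) -> dict[tuple[str, str], tuple[float, float]]:
    """Trend-updated (obesity, smoking) prevalences per (sex, band)."""
    return risk.at(years_elapsed)


# ---------------------------------------------------------------------------
# transition probabilities


@dataclass
class TransitionSet:
    """Annual transition probabilities per (sex, age cell).

    ``q_inc`` has one column per exposure compartment (healthy, obese-only,
    smoker-only, obese-smoker); ``q_death_other`` applies to every living
    compartment; the diabetes compartment additionally faces ``q_death_dm``
    (the two computed jointly from competing hazards so their sum never
    exceeds the total death probability).
    """

    q_inc: np.ndarray          # (n_sex, n_cells, 4)
    q_death_other: np.ndarray  # (n_sex, n_cells)
    q_death_other_dm: np.ndarray
    q_death_dm: np.ndarray

    def __post_init__(self) -> None:
        for name in ("q_inc", "q_death_other", "q_death_other_dm", "q_death_dm"):
            a = getattr(self, name)
            if np.any(a < 0) or np.any(a > 1):
                raise ValueError(f"{name} contains values outside [0, 1]")
        if np.any(self.q_death_other_dm + self.q_death_dm > 1.0 + 1e-12):
            raise ValueError("death probabilities from diabetes exceed 1")

    @classmethod
    def from_hazards(
        cls,
        i_comp: np.ndarray,
        m0: np.ndarray,
        e: np.ndarray,
        incidence_is_probability: bool = False,
    ) -> "TransitionSet":
        """Convert per-person-year hazards to annual probabilities (1 − exp(−h)).

        The diabetes compartment's total death probability
        ``1 − exp(−(m0+e))`` is split between causes in proportion to the
        hazards (competing risks).  Table-S4-style inputs that are already
        annual probabilities pass ``incidence_is_probability=True`` and are
        used directly.
        """
        if incidence_is_probability:
            q_inc = np.asarray(i_comp, dtype=float)
        else:
            q_inc = 1.0 - np.exp(-np.asarray(i_comp, dtype=float))
        m0 = np.asarray(m0, dtype=float)
        e = np.asarray(e, dtype=float)
        q_oth = 1.0 - np.exp(-m0)
        tot = m0 + e
        q_tot = 1.0 - np.exp(-tot)
        with np.errstate(invalid="ignore", divide="ignore"):
            share_dm = np.where(tot > 0, e / np.where(tot > 0, tot, 1.0), 0.0)
        q_dm = q_tot * share_dm
        q_oth_dm = q_tot - q_dm
        return cls(q_inc, q_oth, q_oth_dm, q_dm)


def exposure_specific_incidence(
    i_pop: float,
    shares: Sequence[float],
    rr_obese: float,
    rr_smoker: float,
    joint: str = "multiplicative",
) -> np.ndarray:
    """Apportion a population incidence hazard over exposure compartments.

    With compartment relative risks (1, RR_ob, RR_sm, joint) and occupancy
    ``shares`` of the non-diabetic pool, the healthy-reference hazard is
    ``i_ref = i_pop / Σ share_g·RR_g`` and each compartment receives
    ``i_ref·RR_g``, so the share-weighted mean reproduces ``i_pop`` exactly.
    ``joint`` is the combined obese-smoker risk: product of the two RRs
    (default) or their maximum.
    """
    shares = np.asarray(shares, dtype=float)
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError("exposure shares must sum to 1")
    if i_pop < 0:
        raise ValueError("population incidence must be >= 0")
    if not (rr_obese > 0 and rr_smoker > 0):
        raise ValueError("relative risks must be positive")
    if joint == "multiplicative":
        rr_joint = rr_obese * rr_smoker
    elif joint == "max":
        rr_joint = max(rr_obese, rr_smoker)
    else:
        raise ValueError(f"unknown joint RR rule {joint!r}")
    rr = np.array([1.0, rr_obese, rr_smoker, rr_joint])
    i_ref = i_pop / float(shares @ rr)
    out = i_ref * rr
    if np.any(out > 1.0):
        raise ValueError(
            "exposure-specific incidence exceeds 1/year; review cycle length or relative risks"
        )
    return out


def independence_split(q_o: float, q_s: float) -> np.ndarray:
    """Shares of the four exposure compartments under obesity ⊥ smoking."""
    return np.array(
        [(1 - q_o) * (1 - q_s), q_o * (1 - q_s), (1 - q_o) * q_s, q_o * q_s]
    )


# ---------------------------------------------------------------------------
# state


@dataclass
class StateVector:
    """Compartment occupancy per (sex, age cell) at one cycle."""

    occ: np.ndarray  # (n_sex, n_cells, 7)
    grid: AgeGrid
    year: int

    def __post_init__(self) -> None:
        if self.occ.shape != (len(SEXES), self.grid.n_cells, N_COMP):
            raise ValueError("state array shape does not match grid")
        if np.any(self.occ < -1e-9):
            neg = np.argwhere(self.occ < -1e-9)[0]
            raise ValueError(
                f"negative occupancy in sex={SEXES[neg[0]]} cell={neg[1]} "
                f"compartment={COMPARTMENTS[neg[2]]}"
            )

    def living(self, sex: str | None = None) -> float:
        occ = self.occ if sex is None else self.occ[SEX_INDEX[sex]][None]
        return float(occ[..., LIVING].sum())

    def band_array(self) -> np.ndarray:
        """Aggregate cells into reporting bands → (n_sex, n_bands, 7)."""
        nb = len(self.grid.bands)
        out = np.zeros((len(SEXES), nb, N_COMP))
        for c, b in enumerate(self.grid.cell_band):
            out[:, b, :] += self.occ[:, c, :]
        return out

    def to_frame(self) -> pd.DataFrame:
        arr = self.band_array()
        rows = []
        for si, s in enumerate(SEXES):
            for bi, b in enumerate(self.grid.bands):
                for ci, comp in enumerate(COMPARTMENTS):
                    rows.append(
                        {
                            "year": self.year,
                            "sex": s,
                            "age_lower": b.lower,
                            "age_upper": "" if b.upper is None else b.upper,
                            "compartment": comp,
                            "count": arr[si, bi, ci],
                        }
                    )
        return pd.DataFrame(rows)


def initialize_states(
    pop_by_band: Mapping[tuple[str, str], float],
    dm_prev: Mapping[tuple[str, str], float],
    risk: RiskFactorSpec,
    grid: AgeGrid,
    year: int,
    open_band_decay: float = 0.10,
) -> StateVector:
    """Split each stratum into the six model compartments at baseline.

    The diabetic fraction is set by ``dm_prev``; the remainder is split into
    the four exposure compartments under independence of obesity and smoking
    (prevalences taken among the non-diabetic).  Band populations are spread
    uniformly over the band's age cells; an open-ended top band decays
    geometrically at ``open_band_decay`` per year of age, a crude stand-in
    for old-age survival.
    """
    occ = np.zeros((len(SEXES), grid.n_cells, N_COMP))
    q0 = risk.at(0.0)
    for si, s in enumerate(SEXES):
        for bi, b in enumerate(grid.bands):
            key = (s, b.label)
            n = pop_by_band[key]
            p = dm_prev[key]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"diabetes prevalence {p} outside [0, 1] for {key}")
            cells = grid.cells_in_band(bi)
            if len(cells) == 1:
                weights = np.array([1.0])
            elif b.open_ended:
                ages = np.array([grid.lowers[c] - b.lower for c in cells], dtype=float)
                weights = np.exp(-open_band_decay * ages)
                weights /= weights.sum()
            else:
                weights = np.full(len(cells), 1.0 / len(cells))
            q_o, q_s = q0[key]
            split = independence_split(q_o, q_s)
            if np.any(split < 0):
                raise ValueError(f"negative exposure compartment for {key}")
            for c, w in zip(cells, weights):
                occ[si, c, DM] = n * w * p
                occ[si, c, EXPOSURE] = n * w * (1.0 - p) * split
    return StateVector(occ, grid, year)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class IncidenceSpec:
    """How diabetes incidence enters the engine.

    Either sex-level annual rates (``per_100k``, interpreted against the
    ``denominator`` — ``"total"`` population, the convention of published
    population incidence figures, or directly ``"susceptible"`` person-time)
    applied uniformly across age bands, or fully band-specific hazards
    (``per_band_hazard``, per person-year among susceptibles), e.g. from
    :func:`dmproj.rates.estimate_incidence_from_prevalence`.
    """

    per_100k: Mapping[str, float] | None = None
    denominator: str = "total"
    per_band_hazard: Mapping[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        if (self.per_100k is None) == (self.per_band_hazard is None):
            raise ValueError("specify exactly one of per_100k or per_band_hazard")
        if self.denominator not in ("total", "susceptible"):
            raise ValueError(f"unknown incidence denominator {self.denominator!r}")


@dataclass
class ProjectionConfig:
    """Everything a deterministic projection run needs."""

    start_year: int = None
    end_year: int = None
    bands: Sequence[AgeBand] = CORE_BANDS
    population: PopulationTable = None
    dm_prevalence: Mapping[tuple[str, str], float] = None
    risk: RiskFactorSpec = None
    relative_risks: RelativeRisks = None
    mortality: Mapping[tuple[str, str], float] = None
    incidence: IncidenceSpec = None
    grid_mode: str = "single_year"      # "single_year" | "band"
    demography_mode: str = "rescale"    # "rescale" | "closed"
    joint_rr: str = "multiplicative"
    scenario: ScenarioSpec | None = None
    entrants: Mapping[tuple[int, str], float] | None = None  # closed-mode inflow
    top_age: int = 99
    open_band_decay: float = 0.10
    label: str = ""

    REQUIRED = (
        "start_year", "end_year", "population", "dm_prevalence", "risk",
        "relative_risks", "mortality", "incidence",
    )

    def validate(self) -> None:
        missing = [f for f in self.REQUIRED if getattr(self, f) is None]
        if missing:
            raise ConfigError("incomplete projection config; missing: " + ", ".join(missing))
        if self.end_year <= self.start_year:
            raise ConfigError("end_year must exceed start_year")
        if self.grid_mode not in ("single_year", "band"):
            raise ConfigError(f"unknown grid mode {self.grid_mode!r}")
        if self.demography_mode not in ("rescale", "closed"):
            raise ConfigError(f"unknown demography mode {self.demography_mode!r}")
        if self.scenario is not None:
            check_within_horizon(self.scenario, self.start_year, self.end_year)
        for s in SEXES:
            for b in self.bands:
                key = (s, b.label)
                for name, mapping in (
                    ("dm_prevalence", self.dm_prevalence),
                    ("mortality", self.mortality),
                ):
                    if key not in mapping:
                        raise ConfigError(f"{name} is missing stratum {key}")

    def digest(self) -> str:
        """Short reproducibility hash over the run-defining parameters."""
        payload = {
            "horizon": (self.start_year, self.end_year),
            "bands": [b.label for b in self.bands],
            "pop_years": None if self.population is None else self.population.years(),
            "dm": sorted((k, v) for k, v in (self.dm_prevalence or {}).items()),
            "mort": sorted((k, v) for k, v in (self.mortality or {}).items()),
            "grid": self.grid_mode,
            "demo": self.demography_mode,
            "joint": self.joint_rr,
            "scenario": None if self.scenario is None else repr(self.scenario),
        }
        return hashlib.sha256(json.dumps(payload, default=str).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# the engine


def build_transitions(cfg: ProjectionConfig, grid: AgeGrid) -> tuple[TransitionSet, dict]:
    """Derive per-cell transition probabilities from the configured rates.

    All-cause mortality is partitioned at baseline prevalence (Barendregt);
    excess mortality is ``m0·(rr−1)``.  The population incidence hazard is
    apportioned over exposure compartments at the baseline compartment
    shares, after which the per-compartment hazards are held fixed — the
    aggregate inflow then tracks the evolving exposure shares.
    """
    n_sex, nc = len(SEXES), grid.n_cells
    q_comp = np.zeros((n_sex, nc, 4))
    m0_arr = np.zeros((n_sex, nc))
    e_arr = np.zeros((n_sex, nc))
    q0 = cfg.risk.at(0.0)
    detail: dict = {"m0": {}, "e": {}, "i_pop_hazard": {}}

    # sex-level baseline prevalence for the total-population incidence convention
    p_sex_total = {}
    for s in SEXES:
        num = den = 0.0
        for b in cfg.bands:
            n = cfg.population.get(cfg.start_year, s, b)
            num += n * cfg.dm_prevalence[(s, b.label)]
            den += n
        p_sex_total[s] = num / den if den else 0.0

    for si, s in enumerate(SEXES):
        for bi, b in enumerate(cfg.bands):
            key = (s, b.label)
            p = cfg.dm_prevalence[key]
            m = cfg.mortality[key]
            rr_m = cfg.relative_risks.mort(s)
            m0, m1, _ = partition_mortality(m, p, rr_m)
            e = m1 - m0
            if cfg.incidence.per_band_hazard is not None:
                i_pop = cfg.incidence.per_band_hazard[key]
            else:
                rate = cfg.incidence.per_100k[s] / 1e5
                if cfg.incidence.denominator == "total":
                    i_pop = rate / (1.0 - p_sex_total[s])
                else:
                    i_pop = rate
            shares = independence_split(*q0[key])
            # convert the aggregate hazard to an annual probability first,
            # then apportion by RR: the share-weighted mean of the
            # per-compartment probabilities then equals 1 − exp(−i_pop)
            # exactly, which keeps inflow conservation and RR-monotonicity
            # free of convexity error
            q_pop = 1.0 - math.exp(-i_pop)
            comp = exposure_specific_incidence(
                q_pop, shares, cfg.relative_risks.obese(s),
                cfg.relative_risks.smoker(s), cfg.joint_rr,
            )
            detail["m0"][key] = m0
            detail["e"][key] = e
            detail["i_pop_hazard"][key] = i_pop
            for c in grid.cells_in_band(bi):
                q_comp[si, c] = comp
                m0_arr[si, c] = m0
                e_arr[si, c] = e
    return TransitionSet.from_hazards(q_comp, m0_arr, e_arr, incidence_is_probability=True), detail


@dataclass
class StepAccounting:
    """Per-cycle bookkeeping needed for conservation checks."""

    deaths_other: np.ndarray   # per sex
    deaths_dm: np.ndarray
    entrants: np.ndarray
    migration: np.ndarray


def step_one_cycle(
    state: StateVector,
    ts: TransitionSet,
    q_next: Mapping[tuple[str, str], tuple[float, float]],
    pop_targets_next: Mapping[tuple[str, str], float] | None = None,
    entrants: Mapping[str, float] | None = None,
) -> tuple[StateVector, StepAccounting]:
    """Advance the state by one annual cycle (see module docstring for order).

    ``q_next`` are the exposure prevalences in force at the end of the cycle.
    With ``pop_targets_next`` the living population of each band is aligned
    to its exogenous target (demographic rescale); otherwise the population
    is closed apart from explicit ``entrants`` per sex.
    """
    grid = state.grid
    occ = state.occ.copy()
    n_sex = len(SEXES)

    # (1) deaths
    d_other = occ[:, :, EXPOSURE] * ts.q_death_other[:, :, None]
    occ[:, :, EXPOSURE] -= d_other
    d_dm_other = occ[:, :, DM] * ts.q_death_other_dm
    d_dm_dm = occ[:, :, DM] * ts.q_death_dm
    occ[:, :, DM] -= d_dm_other + d_dm_dm
    occ[:, :, DEAD_OTHER] += d_other.sum(axis=2) + d_dm_other
    occ[:, :, DEAD_DM] += d_dm_dm
    deaths_other = (d_other.sum(axis=(1, 2)) + d_dm_other.sum(axis=1))
    deaths_dm = d_dm_dm.sum(axis=1)

    # (2) incidence
    new_cases = occ[:, :, EXPOSURE] * ts.q_inc
    occ[:, :, EXPOSURE] -= new_cases
    occ[:, :, DM] += new_cases.sum(axis=2)

    # (3) aging: fraction 1/w of each living compartment advances one cell
    frac = np.array([0.0 if math.isinf(w) else 1.0 / w for w in grid.widths])
    moved = occ[:, :, LIVING] * frac[None, :, None]
    occ[:, :, LIVING] -= moved
    occ[:, 1:, LIVING] += moved[:, :-1]
    # moved[:, -1] is zero by construction (last cell open or kept closed)
    if frac[-1] != 0.0:
        occ[:, -1, LIVING] += moved[:, -1]  # bounded top cell retains its leavers

    # (4) entrants / demographic alignment
    entrants_vec = np.zeros(n_sex)
    migration = np.zeros(n_sex)
    youngest_band = 0
    young_label = grid.bands[youngest_band].label
    if pop_targets_next is not None:
        for si, s in enumerate(SEXES):
            # fill the youngest band with diabetes-free entrants first
            key = (s, young_label)
            cells = grid.cells_in_band(youngest_band)
            current = occ[si, cells][:, LIVING].sum()
            target = pop_targets_next[key]
            inflow = max(0.0, target - current)
            q_o, q_s = q_next[key]
            occ[si, cells[0], EXPOSURE] += inflow * independence_split(q_o, q_s)
            entrants_vec[si] = inflow
            # proportional alignment of every band to its target
            for bi, b in enumerate(grid.bands):
                bcells = grid.cells_in_band(bi)
                live = occ[si, bcells][:, LIVING].sum()
                tgt = pop_targets_next[(s, b.label)]
                if live <= 0.0:
                    if tgt > 0.0:
                        # repopulate an emptied band at entrant composition
                        q_o, q_s = q_next[(s, b.label)]
                        occ[si, bcells[0], EXPOSURE] += tgt * independence_split(q_o, q_s)
                        migration[si] += tgt
                    continue
                factor = tgt / live
                occ[si, bcells, LIVING] *= factor
                migration[si] += tgt - live
    elif entrants is not None:
        for si, s in enumerate(SEXES):
            inflow = float(entrants.get(s, 0.0))
            if inflow < 0:
                raise ValueError("entrants must be non-negative")
            key = (s, young_label)
            q_o, q_s = q_next[key]
            first = grid.cells_in_band(youngest_band)[0]
            occ[si, first, EXPOSURE] += inflow * independence_split(q_o, q_s)
            entrants_vec[si] = inflow

    # (5) trend rebalance of the non-diabetic pool (never touches diabetes)
    for si, s in enumerate(SEXES):
        for bi, b in enumerate(grid.bands):
            q_o, q_s = q_next[(s, b.label)]
            split = independence_split(q_o, q_s)
            for c in grid.cells_in_band(bi):
                pool = occ[si, c, EXPOSURE].sum()
                occ[si, c, EXPOSURE] = pool * split

    occ[occ < 0] = np.where(occ[occ < 0] > -1e-9, 0.0, occ[occ < 0])  # scrub fp dust
    new_state = StateVector(occ, grid, state.year + 1)
    return new_state, StepAccounting(deaths_other, deaths_dm, entrants_vec, migration)


# ---------------------------------------------------------------------------
# full projection


@dataclass
class ProjectionResult:
    """Annual states plus derived prevalence/count accessors."""

    years: list[int]
    states: list[StateVector]
    grid: AgeGrid
    accounting: list[StepAccounting]
    config_digest: str
    label: str = ""

    def _state(self, year: int) -> StateVector:
        try:
            return self.states[self.years.index(year)]
        except ValueError:
            raise KeyError(f"year {year} not in projection horizon") from None

    def band_table(self, year: int) -> pd.DataFrame:
        """Living population, diabetes count and prevalence per (sex, band)."""
        arr = self._state(year).band_array()
        rows = []
        for si, s in enumerate(SEXES):
            for bi, b in enumerate(self.grid.bands):
                living = arr[si, bi, LIVING].sum()
                dm = arr[si, bi, DM]
                rows.append(
                    {
                        "year": year, "sex": s, "band": b.label,
                        "population": living, "diabetes": dm,
                        "prevalence": dm / living if living > 0 else 0.0,
                    }
                )
        return pd.DataFrame(rows)

    def diabetes_count(self, year: int, sex: str | None = None, band: str | None = None) -> float:
        arr = self._state(year).band_array()
        si = slice(None) if sex is None else SEX_INDEX[sex]
        bsel = slice(None) if band is None else [b.label for b in self.grid.bands].index(band)
        return float(np.sum(arr[si, bsel, DM]))

    def population(self, year: int, sex: str | None = None, band: str | None = None) -> float:
        arr = self._state(year).band_array()
        si = slice(None) if sex is None else SEX_INDEX[sex]
        bsel = slice(None) if band is None else [b.label for b in self.grid.bands].index(band)
        return float(np.sum(arr[si, bsel, LIVING]))

    def prevalence(self, year: int, sex: str | None = None, band: str | None = None) -> float:
        pop = self.population(year, sex, band)
        return self.diabetes_count(year, sex, band) / pop if pop > 0 else 0.0

    def to_tidy(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.states], ignore_index=True)


def run_projection(cfg: ProjectionConfig) -> ProjectionResult:
    """Run the full multi-year projection described by ``cfg``.

    Deterministic: identical configurations yield bit-identical results.
    """
    cfg.validate()
    grid = (
        AgeGrid.single_year(cfg.bands, cfg.top_age)
        if cfg.grid_mode == "single_year"
        else AgeGrid.from_bands(cfg.bands)
    )
    pop0 = {
        (s, b.label): cfg.population.get(cfg.start_year, s, b)
        for s in SEXES
        for b in cfg.bands
    }
    state = initialize_states(
        pop0, cfg.dm_prevalence, cfg.risk, grid, cfg.start_year, cfg.open_band_decay
    )
    ts, _ = build_transitions(cfg, grid)

    states = [state]
    accounting: list[StepAccounting] = []
    for year in range(cfg.start_year, cfg.end_year):
        elapsed_next = (year + 1) - cfg.start_year
        factors = (1.0, 1.0)
        if cfg.scenario is not None:
            factors = cfg.scenario.factors(year + 1)
        q_next = cfg.risk.at(elapsed_next, factors)
        if cfg.demography_mode == "rescale":
            targets = {
                (s, b.label): cfg.population.get(year + 1, s, b)
                for s in SEXES
                for b in cfg.bands
            }
            state, acct = step_one_cycle(state, ts, q_next, pop_targets_next=targets)
        else:
            entr = None
            if cfg.entrants is not None:
                entr = {s: cfg.entrants.get((year + 1, s), 0.0) for s in SEXES}
            state, acct = step_one_cycle(state, ts, q_next, entrants=entr)
        states.append(state)
        accounting.append(acct)

    return ProjectionResult(
        years=list(range(cfg.start_year, cfg.end_year + 1)),
        states=states,
        grid=grid,
        accounting=accounting,
        config_digest=cfg.digest(),
        label=cfg.label,
    )
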