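"""Counterfactual intervention scenarios on exposure-prevalence trajectories.

A scenario is a phased reduction of obesity and/or smoking prevalence in the
non-diabetic population: a prevention program starting in a given year
reaches its full stated reduction after ``duration`` years (linear phase-in)
and persists thereafter.  Two operational readings are supported:

``targeted``
    The stated reduction is achieved only in the targeted fraction of each
    exposure pool, so the pool-level prevalence multiplier at full effect is
    ``1 - target_fraction * reduction``.

``population``
    The stated reduction applies to the whole exposure pool regardless of
    the targeting fractions: multiplier ``1 - reduction``.

Reductions act on exposure *prevalences* (the compartment rebalancing step
of the Markov engine), never on the diabetes compartment itself: existing
cases are untouched and benefits accrue only through reduced inflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScenarioSpec:
    """A phased prevention program acting on obesity and smoking prevalence."""

    start_year: int
    duration: int = 10
    target_fraction_healthy: float = 0.0
    target_fraction_obese: float = 0.0
    target_fraction_smoker: float = 0.0
    obesity_reduction: float = 0.0
    smoking_reduction: float = 0.0
    reading: str = "population"  # "population" | "targeted"
    phase_in: str = "linear"

    def __post_init__(self) -> None:
        for name in (
            "target_fraction_healthy",
            "target_fraction_obese",
            "target_fraction_smoker",
            "obesity_reduction",
            "smoking_reduction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.duration < 1:
            raise ValueError("scenario duration must be >= 1 year")
        if self.reading not in ("population", "targeted"):
            raise ValueError(f"unknown scenario reading {self.reading!r}")
        if self.phase_in != "linear":
            raise ValueError("only linear phase-in is implemented")

    def phase(self, year: int) -> float:
        """Fraction of the full effect in force in ``year`` (0 before start)."""
        if year < self.start_year:
            return 0.0
        return min(1.0, (year - self.start_year + 1) / self.duration)

    def factors(self, year: int) -> tuple[float, float]:
        """(obesity, smoking) prevalence multipliers in force in ``year``."""
        ph = self.phase(year)
        if self.reading == "targeted":
            eff_o = self.target_fraction_obese * self.obesity_reduction
            eff_s = self.target_fraction_smoker * self.smoking_reduction
        else:
            eff_o = self.obesity_reduction
            eff_s = self.smoking_reduction
        return 1.0 - eff_o * ph, 1.0 - eff_s * ph

    @property
    def is_null(self) -> bool:
        return self.obesity_reduction == 0.0 and self.smoking_reduction == 0.0


def check_within_horizon(spec: ScenarioSpec, start_year: int, end_year: int) -> None:
    if not start_year <= spec.start_year <= end_year:
        raise ValueError(
            f"scenario start {spec.start_year} outside projection horizon {start_year}–{end_year}"
        )


def compare_scenarios(baseline, intervention, years: Sequence[int] | None = None) -> pd.DataFrame:
    """Year-by-year difference table between two projection results.

    Columns: total prevalence under each run (percent), prevalence difference
    in percentage points, relative reduction in percent, and cases averted
    (persons).  Both results must share horizon and strata.
    """
    if list(baseline.years) != list(intervention.years):
        raise ValueError("projection horizons differ; cannot compare scenarios")
    if baseline.grid.bands != intervention.grid.bands:
        raise ValueError("reporting bands differ; cannot compare scenarios")
    if years is None:
        years = list(baseline.years)
    rows = []
    for y in years:
        pb = baseline.prevalence(y) * 100.0
        pi = intervention.prevalence(y) * 100.0
        cb = baseline.diabetes_count(y)
        ci = intervention.diabetes_count(y)
        rows.append(
            {
                "year": y,
                "baseline_prevalence_pct": pb,
                "intervention_prevalence_pct": pi,
                "prevalence_diff_pp": pb - pi,
                "relative_reduction_pct": 0.0 if pb == 0 else 100.0 * (pb - pi) / pb,
                "cases_averted": cb - ci,
            }
        )
    return pd.DataFrame(rows)
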