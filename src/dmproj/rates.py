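"""Mortality partition and incidence back-calculation (illness–death model).

Two classical epidemiological computations live here:

* ``partition_mortality`` splits an all-cause mortality rate into the rates
  experienced by diseased and non-diseased people, given the prevalence and
  the mortality rate ratio between them (the Barendregt attributable-
  mortality partition).

* ``estimate_incidence_from_prevalence`` back-calculates age-specific
  incidence from a cross-sectional prevalence curve under zero remission,
  the generic illness–death ("DisMod"-style) inversion: with no remission
  and known background and excess mortality, the rise of prevalence with
  age identifies the incidence hazard band by band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import SEXES, AgeBand
from .demography import PopulationTable

log = logging.getLogger(__name__)

BISECT_TOL = 1e-10
BISECT_MAXITER = 200


@dataclass(frozen=True)
class RelativeRisks:
    """The three relative risks tying exposures to diabetes and diabetes to death.

    Each field is either a single float applied to both sexes or a mapping
    ``{"M": ..., "F": ...}``.  All values must be positive; they are
    dimensionless rate ratios.

    rr_mort_dm
        All-cause mortality in people with diabetes relative to people
        without (drives the mortality partition and excess mortality).
    rr_dm_obese
        Diabetes incidence in obese relative to non-obese individuals.
    rr_dm_smoker
        Diabetes incidence in daily smokers relative to non-smokers.
    """

    rr_mort_dm: float | Mapping[str, float] = 2.0
    rr_dm_obese: float | Mapping[str, float] = 7.19
    rr_dm_smoker: float | Mapping[str, float] = 1.44

    def _get(self, field: float | Mapping[str, float], sex: str) -> float:
        v = field[sex] if isinstance(field, Mapping) else float(field)
        if not v > 0:
            raise ValueError(f"relative risks must be positive, got {v}")
        return v

    def mort(self, sex: str) -> float:
        return self._get(self.rr_mort_dm, sex)

    def obese(self, sex: str) -> float:
        return self._get(self.rr_dm_obese, sex)

    def smoker(self, sex: str) -> float:
        return self._get(self.rr_dm_smoker, sex)


def partition_mortality(m: float, p: float, rr: float) -> tuple[float, float, float]:
    """Split all-cause mortality ``m`` by disease status.

    Given prevalence ``p`` and the mortality rate ratio ``rr`` between
    diseased and non-diseased, the rates that reproduce ``m`` as their
    prevalence-weighted mean are::

        m0 = m / (1 - p + p*rr)        (non-diseased)
        m1 = rr * m0                   (diseased)

    Returns ``(m0, m1, attributable)`` where ``attributable = p*m0*(rr-1)``
    is the death rate in the total population attributable to the disease.
    """
    if not rr > 0:
        raise ValueError(f"rr must be > 0, got {rr}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {p}")
    if m < 0:
        raise ValueError(f"mortality rate must be >= 0, got {m}")
    m0 = m / (1.0 - p + p * rr)
    m1 = rr * m0
    return m0, m1, p * m0 * (rr - 1.0)


def excess_mortality(m: float, p: float, rr: float) -> float:
    """Excess (disease-related) mortality hazard ``e = m1 - m0 = m0*(rr-1)``."""
    m0, m1, _ = partition_mortality(m, p, rr)
    return m1 - m0


def _simulate_band(S: float, C: float, i: float, m0: float, e: float, n_years: int) -> tuple[float, float]:
    """Advance a unit cohort ``n_years`` single-year steps at constant hazards.

    Discrete recursion (rates used directly as annual probabilities, valid
    for the small per-year hazards this model works with):
    ``S' = S*(1 - i - m0)``; ``C' = C*(1 - m0 - e) + S*i``.
    """
    for _ in range(n_years):
        S, C = S * (1.0 - i - m0), C * (1.0 - m0 - e) + S * i
    return S, C


def estimate_incidence_from_prevalence(
    p_by_band: Sequence[float],
    m0_by_band: Sequence[float],
    e_by_band: Sequence[float],
    band_width: int = 10,
    age_min: int = 25,
) -> np.ndarray:
    """Back-calculate band-wise incidence hazards from a prevalence curve.

    A disease-free cohort enters at ``age_min`` and is swept upward through
    the bands; within each band a constant incidence hazard is solved (by
    bisection on ``[0, 1]``) so that the simulated prevalence matches the
    target at the band midpoint.  Remission is fixed at zero, so prevalence
    can only fall through excess mortality; where the target curve falls
    faster than mortality allows, incidence is floored at 0 and a
    diagnostic is logged.

    The open-ended last band is treated as ``band_width`` years wide for
    midpoint placement.
    """
    p = np.asarray(p_by_band, dtype=float)
    m0 = np.asarray(m0_by_band, dtype=float)
    e = np.asarray(e_by_band, dtype=float)
    if not (len(p) == len(m0) == len(e)):
        raise ValueError("prevalence, mortality and excess arrays must align")
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("prevalence must lie in [0, 1)")
    n = len(p)
    half = band_width // 2
    out = np.zeros(n)
    S, C = 1.0, 0.0
    for k in range(n):
        target = p[k]

        def prev_at_mid(i: float) -> float:
            s, c = _simulate_band(S, C, i, m0[k], e[k], half)
            return c / (s + c)

        if prev_at_mid(0.0) >= target:
            if prev_at_mid(0.0) > target + 1e-12:
                log.info(
                    "band %d: prevalence target %.4g below zero-incidence path; flooring incidence at 0",
                    k, target,
                )
            i_k = 0.0
        else:
            lo, hi = 0.0, 1.0
            if prev_at_mid(hi) < target:
                raise RuntimeError(f"incidence root finding failed to bracket in band {k}")
            for it in range(BISECT_MAXITER):
                mid = 0.5 * (lo + hi)
                if prev_at_mid(mid) < target:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < BISECT_TOL:
                    break
            else:
                raise RuntimeError(
                    f"incidence root finding did not converge in band {k} after {BISECT_MAXITER} iterations"
                )
            i_k = 0.5 * (lo + hi)
        out[k] = i_k
        S, C = _simulate_band(S, C, i_k, m0[k], e[k], band_width)
    return out


def forward_prevalence(
    i_by_band: Sequence[float],
    m0_by_band: Sequence[float],
    e_by_band: Sequence[float],
    band_width: int = 10,
) -> np.ndarray:
    """Prevalence at band midpoints implied by band-wise hazards (round-trip check)."""
    i = np.asarray(i_by_band, dtype=float)
    m0 = np.asarray(m0_by_band, dtype=float)
    e = np.asarray(e_by_band, dtype=float)
    half = band_width // 2
    S, C = 1.0, 0.0
    out = np.zeros(len(i))
    for k in range(len(i)):
        s_mid, c_mid = _simulate_band(S, C, i[k], m0[k], e[k], half)
        out[k] = c_mid / (s_mid + c_mid)
        S, C = _simulate_band(S, C, i[k], m0[k], e[k], band_width)
    return out


def attributable_deaths(
    pop: PopulationTable,
    p: Mapping[tuple[str, str], float],
    m0: Mapping[tuple[str, str], float],
    rr: RelativeRisks,
    year: int,
) -> float:
    """Deaths attributable to the disease in ``year``: sum of N·p·m0·(rr−1) over strata."""
    strata = pop.strata()
    total = 0.0
    for sex, band in strata:
        key = (sex, band.label)
        if key not in p or key not in m0:
            raise ValueError(f"stratum {key} missing from prevalence/mortality inputs")
        total += pop.get(year, sex, band) * p[key] * m0[key] * (rr.mort(sex) - 1.0)
    return total


def rates_to_frame(per_hazard: Mapping[tuple[str, str], Mapping[str, float]]) -> pd.DataFrame:
    """Tidy rates table: sex, age_lower, age_upper, then one column per rate name."""
    rows = []
    for (sex, label), rates in per_hazard.items():
        band = AgeBand.parse(label)
        rows.append(
            {"sex": sex, "age_lower": band.lower, "age_upper": "" if band.upper is None else band.upper, **rates}
        )
    return pd.DataFrame(rows).sort_values(["sex", "age_lower"]).reset_index(drop=True)


def per_100k(hazard: float) -> float:
    """Present a per-person-year hazard on the conventional per-100,000 scale."""
    return hazard * 1e5


def from_per_100k(rate: float) -> float:
    return rate / 1e5
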