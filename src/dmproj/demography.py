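"""Population trajectories: interpolation, denominator reconstruction, cohort entry.

Populations are handled as :class:`PopulationTable` objects — counts indexed
by calendar year, sex and age band.  Sparse anchor years (e.g. a census year
plus projected totals) are densified by per-stratum geometric interpolation,
the demographic convention for smooth growth.  Published report tables that
print ``count (prevalence%)`` cells can be inverted into the denominators
that produced them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import SEXES, AgeBand

log = logging.getLogger(__name__)

_COLUMNS = ["year", "sex", "age_lower", "age_upper", "count"]


def _band_from_row(row) -> AgeBand:
    upper = row["age_upper"]
    if pd.isna(upper) or upper in ("", None):
        return AgeBand(int(row["age_lower"]), None)
    return AgeBand(int(row["age_lower"]), int(upper))


@dataclass
class PopulationTable:
    """Counts of persons per (year, sex, age band).

    Thin wrapper over a dict keyed ``(year, sex, AgeBand) -> count`` with
    CSV import/export (columns ``year,sex,age_lower,age_upper,count``; an
    empty ``age_upper`` encodes an open-ended band).
    """

    entries: dict = field(default_factory=dict)

    def set(self, year: int, sex: str, band: AgeBand, count: float) -> None:
        if count < 0:
            raise ValueError(f"negative population count for {year}/{sex}/{band.label}")
        self.entries[(int(year), sex, band)] = float(count)

    def get(self, year: int, sex: str, band: AgeBand) -> float:
        return self.entries[(int(year), sex, band)]

    def years(self) -> list[int]:
        return sorted({k[0] for k in self.entries})

    def strata(self) -> list[tuple[str, AgeBand]]:
        return sorted({(k[1], k[2]) for k in self.entries}, key=lambda t: (t[0], t[1]))

    def total(self, year: int, sex: str | None = None) -> float:
        return sum(
            v
            for (y, s, _), v in self.entries.items()
            if y == year and (sex is None or s == sex)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "year": y,
                "sex": s,
                "age_lower": b.lower,
                "age_upper": "" if b.upper is None else b.upper,
                "count": v,
            }
            for (y, s, b), v in sorted(self.entries.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))
        ]
        return pd.DataFrame(rows, columns=_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationTable":
        table = cls()
        for _, row in df.iterrows():
            table.set(int(row["year"]), str(row["sex"]), _band_from_row(row), float(row["count"]))
        return table

    @classmethod
    def from_csv(cls, path) -> "PopulationTable":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False, na_values=[]))


def build_population_trajectory(anchors: PopulationTable, horizon: Sequence[int]) -> PopulationTable:
    """Densify sparse anchor years over ``horizon`` by geometric interpolation.

    Between consecutive anchors each stratum grows at the constant annual
    rate implied by the two anchor counts; anchor-year values are copied
    bit-exactly.  Extrapolation outside the anchor span is refused.
    """
    years = sorted(int(y) for y in horizon)
    anchor_years = anchors.years()
    if len(anchor_years) < 2:
        raise ValueError("need at least two anchor years for interpolation")
    if years[0] < anchor_years[0] or years[-1] > anchor_years[-1]:
        raise ValueError(
            f"horizon {years[0]}–{years[-1]} extends beyond anchor span "
            f"{anchor_years[0]}–{anchor_years[-1]}; extrapolation is not supported"
        )
    strata = anchors.strata()
    for y in anchor_years:
        for sex, band in strata:
            if (y, sex, band) not in anchors.entries:
                raise ValueError(f"anchor year {y} is missing stratum {sex}/{band.label}")

    out = PopulationTable()
    for sex, band in strata:
        for y in years:
            if (y, sex, band) in anchors.entries:
                out.set(y, sex, band, anchors.get(y, sex, band))
                continue
            # bracketing anchors
            y0 = max(a for a in anchor_years if a < y)
            y1 = min(a for a in anchor_years if a > y)
            v0 = anchors.get(y0, sex, band)
            v1 = anchors.get(y1, sex, band)
            if v0 == 0.0:
                if v1 == 0.0:
                    out.set(y, sex, band, 0.0)
                    continue
                raise ValueError(
                    f"cannot interpolate geometrically from a zero count ({sex}/{band.label} at {y0})"
                )
            rate = (v1 / v0) ** (1.0 / (y1 - y0))
            out.set(y, sex, band, v0 * rate ** (y - y0))
    return out


def reconstruct_denominators(report: pd.DataFrame) -> PopulationTable:
    """Invert ``count (prevalence%)`` report cells into population denominators.

    ``report`` columns: ``sex, band, year, count, prevalence_pct``.  The
    denominator of each stratum is ``count / (prevalence_pct/100)``.  Rows
    whose band label is ``total`` are checksums, never denominator sources,
    and are skipped.  A zero prevalence with a positive count is impossible
    and raises; zero count with zero prevalence leaves the stratum unknown
    (logged, omitted from the table).
    """
    out = PopulationTable()
    for _, row in report.iterrows():
        label = str(row["band"]).strip().lower()
        if label == "total":
            continue
        band = AgeBand.parse(row["band"])
        count = float(row["count"])
        prev = float(row["prevalence_pct"])
        if count < 0:
            raise ValueError("negative count in report cell")
        if prev == 0.0:
            if count > 0:
                raise ValueError(
                    f"cell {row['sex']}/{band.label}/{row['year']} has count {count} but 0% prevalence"
                )
            log.warning(
                "denominator unknown for %s/%s/%s (0 count, 0%% prevalence)",
                row["sex"], band.label, row["year"],
            )
            continue
        out.set(int(row["year"]), str(row["sex"]), band, count / (prev / 100.0))
    return out


def cohort_entry(
    pop: PopulationTable,
    year: int,
    aging_out: Mapping[str, float] | float = 0.0,
    deaths: Mapping[str, float] | float = 0.0,
) -> dict[str, float]:
    """Entrants at the lower model age bound implied by the youngest band's change.

    For each sex, entrants reconcile the youngest band's year-over-year change
    with the number aging out of the band and deaths within it::

        entrants = N(year) - (N(year-1) - aging_out - deaths)

    Negative balances are floored at zero with a logged warning (the table may
    embed net out-migration the closed model cannot represent).
    """
    years = pop.years()
    if year - 1 not in years:
        raise ValueError(f"no prior year {year - 1} in population table; cannot infer entrants")
    youngest: dict[str, AgeBand] = {}
    for sex, band in pop.strata():
        if sex not in youngest or band.lower < youngest[sex].lower:
            youngest[sex] = band
    out: dict[str, float] = {}
    for sex, band in youngest.items():
        a_out = aging_out[sex] if isinstance(aging_out, Mapping) else float(aging_out)
        dth = deaths[sex] if isinstance(deaths, Mapping) else float(deaths)
        entrants = pop.get(year, sex, band) - (pop.get(year - 1, sex, band) - a_out - dth)
        if entrants < 0:
            log.warning("negative entrant balance %.1f for sex %s in %d; flooring at 0", entrants, sex, year)
            entrants = 0.0
        out[sex] = entrants
    return out
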