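"""Report tables, the 20–79 comparison view, summary statistics and plots.

Formats projection output the way chronic-disease burden tables are
conventionally printed: one ``count (prevalence%)`` cell per (sex, band,
year), counts rounded to integers, prevalence to one decimal, totals
recomputed from unrounded values.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import SEXES, AgeBand
from .demography import PopulationTable
from .markov import ProjectionResult

log = logging.getLogger(__name__)


def _cell(count: float, prev: float) -> str:
    return f"{count:.0f} ({round(prev * 100, 1):g})"


def tabulate(result: ProjectionResult, years: Sequence[int], band_set: str = "core") -> pd.DataFrame:
    """Burden report: rows per sex × band (plus totals), one column per year.

    ``band_set`` currently offers only ``"core"`` (the model's own bands);
    unknown names raise with the available choices listed.
    """
    if band_set != "core":
        raise ValueError(f"unknown band set {band_set!r}; available: ['core']")
    labels = [b.label for b in result.grid.bands]
    rows = []
    for sex_label, sexes in [("Men", ["M"]), ("Women", ["F"]), ("Total", list(SEXES))]:
        for band in labels + ["total"]:
            row = {"sex": sex_label, "band": band}
            for y in years:
                dm = pop = 0.0
                for s in sexes:
                    b = None if band == "total" else band
                    dm += result.diabetes_count(y, s, b)
                    pop += result.population(y, s, b)
                row[str(y)] = _cell(dm, dm / pop if pop else 0.0)
            rows.append(row)
    return pd.DataFrame(rows)


def idf_comparable(
    result: ProjectionResult,
    pop_20_24: PopulationTable,
    split_75_79: float = 0.5,
) -> pd.DataFrame:
    """Recompute prevalence on the 20–79 age window used by global atlases.

    People over 79 are dropped by retaining a ``split_75_79`` fraction of
    the open 75+ band (counts and population alike, so that band's
    prevalence is unchanged), and a 20–24 population with zero diabetes
    prevalence is added, diluting the denominator.  Returns one row per
    (year, sex) plus totals, with diabetes count, population and prevalence.
    """
    band_20_24 = AgeBand(20, 25)
    rows = []
    for y in result.years:
        try:
            p2024 = {s: pop_20_24.get(y, s, band_20_24) for s in SEXES}
        except KeyError:
            raise ValueError(f"no 20–24 population supplied for year {y}") from None
        per_sex = {}
        for s in SEXES:
            dm = pop = 0.0
            for b in result.grid.bands:
                w = split_75_79 if b.open_ended else 1.0
                dm += w * result.diabetes_count(y, s, b.label)
                pop += w * result.population(y, s, b.label)
            pop += p2024[s]
            per_sex[s] = (dm, pop)
            rows.append(
                {"year": y, "sex": s, "diabetes": dm, "population": pop, "prevalence": dm / pop}
            )
        dm = sum(v[0] for v in per_sex.values())
        pop = sum(v[1] for v in per_sex.values())
        rows.append(
            {"year": y, "sex": "T", "diabetes": dm, "population": pop, "prevalence": dm / pop}
        )
    return pd.DataFrame(rows)


def relative_increase(v0: float, v1: float) -> float:
    """Percent change from ``v0`` to ``v1``: 100·(v1 − v0)/v0."""
    if v0 == 0:
        raise ValueError("relative increase undefined for a zero baseline")
    return 100.0 * (v1 - v0) / v0


def fold_increase_by_band(result: ProjectionResult, y0: int, y1: int) -> pd.DataFrame:
    """Prevalence fold change per band between two years (sexes combined).

    Bands with zero baseline prevalence are flagged and excluded.
    """
    rows = []
    for b in result.grid.bands:
        p0 = result.prevalence(y0, band=b.label)
        p1 = result.prevalence(y1, band=b.label)
        if p0 == 0.0:
            log.warning("band %s has zero prevalence in %d; fold undefined, excluded", b.label, y0)
            continue
        rows.append({"band": b.label, "fold": p1 / p0})
    return pd.DataFrame(rows)


def plot_prevalence_trend(results: Mapping[str, ProjectionResult], path=None):
    """Total 25+ prevalence trajectories by sex for one or more runs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, res in results.items():
        for sex, style in (("M", "--"), ("F", ":"), (None, "-")):
            ys = [res.prevalence(y, sex) * 100 for y in res.years]
            lbl = f"{name} ({'total' if sex is None else sex})"
            ax.plot(res.years, ys, style, label=lbl)
    ax.set_xlabel("year")
    ax.set_ylabel("diabetes prevalence (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_scenario_comparison(comparison: pd.DataFrame, path=None):
    """Baseline vs intervention prevalence trajectories from a comparison table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(comparison["year"], comparison["baseline_prevalence_pct"], "-", label="baseline")
    ax.plot(comparison["year"], comparison["intervention_prevalence_pct"], "--", label="intervention")
    ax.set_xlabel("year")
    ax.set_ylabel("diabetes prevalence (%)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
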