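"""YAML master-config loading for the command-line interface.

The master config is a nested key-value file with sections ``horizon``,
``demography``, ``baseline_prevalence``, ``rates``, ``relative_risks``,
``trends`` and optionally ``scenario`` and ``engine``.  Prevalences and
trends are written in percent / percentage points (the units people quote);
they are converted to proportions internally.  An annotated example ships
in ``examples/syria_config.yaml``.

Schema validation is collective: every missing or malformed section is
reported in a single error, not one at a time.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .bands import SEXES, AgeBand
from .demography import PopulationTable, build_population_trajectory
from .markov import ConfigError, IncidenceSpec, ProjectionConfig, RiskFactorSpec
from .rates import RelativeRisks
from .scenarios import ScenarioSpec


def _per_stratum(section: Mapping[str, Any], bands, scale: float = 1.0) -> dict:
    """Expand ``{sex: value}`` or ``{sex: {band: value}}`` to (sex, label) keys."""
    out = {}
    for s in SEXES:
        v = section[s]
        for b in bands:
            if isinstance(v, Mapping):
                out[(s, b.label)] = float(v[b.label]) * scale
            else:
                out[(s, b.label)] = float(v) * scale
    return out


def load_config(path) -> ProjectionConfig:
    """Build a validated :class:`ProjectionConfig` from a YAML master config."""
    raw = yaml.safe_load(Path(path).read_text())
    problems: list[str] = []

    def need(section: str):
        if section not in raw:
            problems.append(f"missing section {section!r}")
            return None
        return raw[section]

    horizon = need("horizon")
    demo = need("demography")
    prev = need("baseline_prevalence")
    rates = need("rates")
    rrs = need("relative_risks")
    trends = need("trends")
    if problems:
        raise ConfigError("invalid master config: " + "; ".join(problems))

    start, end = int(horizon["start"]), int(horizon["end"])
    bands = tuple(AgeBand.parse(b) for b in raw.get("bands", ["25-34", "35-44", "45-54", "55-64", "65-74", "75+"]))

    anchors = PopulationTable.from_csv(demo["population_csv"])
    population = (
        build_population_trajectory(anchors, range(start, end + 1))
        if demo.get("interpolate", True)
        else anchors
    )

    dm_prev = _per_stratum(prev["diabetes"], bands, scale=0.01)

    mortality = _per_stratum(rates["mortality"], bands)
    inc_raw = rates["incidence"]
    if "per_100k" in inc_raw:
        incidence = IncidenceSpec(
            per_100k={s: float(inc_raw["per_100k"][s]) for s in SEXES},
            denominator=inc_raw.get("denominator", "total"),
        )
    else:
        incidence = IncidenceSpec(
            per_band_hazard=_per_stratum(inc_raw["per_band_hazard"], bands),
            denominator="susceptible",
        )

    def _rr(v):
        return {k: float(x) for k, x in v.items()} if isinstance(v, Mapping) else float(v)

    relative_risks = RelativeRisks(
        rr_mort_dm=_rr(rrs["rr_mort_dm"]),
        rr_dm_obese=_rr(rrs["rr_dm_obese"]),
        rr_dm_smoker=_rr(rrs["rr_dm_smoker"]),
    )

    ob = trends["obesity"]
    sm = trends["smoking"]
    risk = RiskFactorSpec.uniform(
        bands,
        obesity={s: float(ob["baseline_pct"][s]) / 100 for s in SEXES},
        smoking={s: float(sm["baseline_pct"][s]) / 100 for s in SEXES},
        obesity_trend=float(ob.get("trend_pp_per_year", 0.0)) / 100,
        obesity_trend_overrides={
            k: float(v) / 100 for k, v in ob.get("trend_pp_overrides", {}).items()
        },
        smoking_trend=float(sm.get("trend_pp_per_year", 0.0)) / 100,
        obesity_cap=float(ob.get("cap_pct", 80.0)) / 100,
    )

    scenario = None
    if raw.get("scenario"):
        sc = raw["scenario"]
        scenario = ScenarioSpec(
            start_year=int(sc["start_year"]),
            duration=int(sc.get("duration", 10)),
            target_fraction_healthy=float(sc.get("target_fraction_healthy", 0.0)),
            target_fraction_obese=float(sc.get("target_fraction_obese", 0.0)),
            target_fraction_smoker=float(sc.get("target_fraction_smoker", 0.0)),
            obesity_reduction=float(sc.get("obesity_reduction", 0.0)),
            smoking_reduction=float(sc.get("smoking_reduction", 0.0)),
            reading=sc.get("reading", "population"),
        )

    engine = raw.get("engine", {})
    cfg = ProjectionConfig(
        start_year=start,
        end_year=end,
        bands=bands,
        population=population,
        dm_prevalence=dm_prev,
        risk=risk,
        relative_risks=relative_risks,
        mortality=mortality,
        incidence=incidence,
        grid_mode=engine.get("grid", "single_year"),
        demography_mode=engine.get("demography", "rescale"),
        joint_rr=engine.get("joint_rr", "multiplicative"),
        scenario=scenario,
        label=raw.get("label", Path(path).stem),
    )
    cfg.validate()
    return cfg
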