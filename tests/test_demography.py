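import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmproj.bands import AgeBand
from dmproj.demography import (
    PopulationTable,
    build_population_trajectory,
    cohort_entry,
    reconstruct_denominators,
)

BAND = AgeBand(25, 35)


def _anchors(values: dict[int, float], sex="M", band=BAND) -> PopulationTable:
    t = PopulationTable()
    for y, v in values.items():
        t.set(y, sex, band, v)
    return t


class TestGeometricInterpolation:
    @pytest.mark.parametrize(
        "anchors, year, expected",
        [
            ({2003: 1000.0, 2022: 2000.0}, 2003, 1000.0),   # anchor exact
            ({2003: 1000.0, 2022: 2000.0}, 2022, 2000.0),   # doubling over span
            ({2003: 1500.0, 2010: 1500.0}, 2006, 1500.0),   # zero growth
            ({2003: 1000.0, 2005: 1210.0}, 2004, 1100.0),   # 1000·1.21^(1/2)
        ],
    )
    def test_values(self, anchors, year, expected):
        years = range(min(anchors), max(anchors) + 1)
        out = build_population_trajectory(_anchors(anchors), years)
        assert out.get(year, "M", BAND) == pytest.approx(expected, rel=1e-12)

    def test_anchors_bit_exact(self):
        out = build_population_trajectory(
            _anchors({2003: 1234.567, 2012: 8765.432}), range(2003, 2013)
        )
        assert out.get(2003, "M", BAND) == 1234.567
        assert out.get(2012, "M", BAND) == 8765.432

    def test_extrapolation_refused(self):
        with pytest.raises(ValueError, match="extrapolation"):
            build_population_trajectory(_anchors({2003: 1.0, 2010: 2.0}), range(2003, 2015))

    def test_missing_stratum_named(self):
        t = _anchors({2003: 1.0, 2010: 2.0})
        t.set(2003, "F", BAND, 5.0)  # F missing at 2010
        with pytest.raises(ValueError, match="F/25-34"):
            build_population_trajectory(t, range(2003, 2011))

    @given(
        v0=st.floats(1e2, 1e7),
        ratio=st.floats(0.5, 3.0),
        span=st.integers(2, 25),
    )
    @settings(max_examples=50, deadline=None)
    def test_growth_rate_constant(self, v0, ratio, span):
        """Interior years follow a constant annual growth rate (brute-force check)."""
        out = build_population_trajectory(
            _anchors({2000: v0, 2000 + span: v0 * ratio}), range(2000, 2000 + span + 1)
        )
        g = ratio ** (1.0 / span)
        for k in range(span + 1):
            assert out.get(2000 + k, "M", BAND) == pytest.approx(v0 * g**k, rel=1e-9)

    def test_band_sums_match_per_stratum_recompute(self):
        """Summing interpolated bands equals interpolating each band separately."""
        t = PopulationTable()
        bands = [AgeBand(25, 35), AgeBand(35, 45)]
        for b, (a0, a1) in zip(bands, [(1000.0, 1500.0), (2000.0, 2200.0)]):
            t.set(2003, "M", b, a0)
            t.set(2008, "M", b, a1)
        out = build_population_trajectory(t, range(2003, 2009))
        for y in range(2003, 2009):
            total = sum(out.get(y, "M", b) for b in bands)
            brute = 1000.0 * 1.5 ** ((y - 2003) / 5) + 2000.0 * 1.1 ** ((y - 2003) / 5)
            assert total == pytest.approx(brute, rel=1e-12)


class TestDenominatorReconstruction:
    def _report(self, rows):
        return pd.DataFrame(rows, columns=["sex", "band", "year", "count", "prevalence_pct"])

    @pytest.mark.parametrize(
        "count, prev, expected",
        [
            (16995, 1.2, 1_416_250.0),
            (249919, 11.3, 2_211_672.566),
            (0, 1.0, 0.0),
        ],
    )
    def test_cell_inversion(self, count, prev, expected):
        out = reconstruct_denominators(
            self._report([("M", "25-34", 2003, count, prev)])
        )
        assert out.get(2003, "M", AgeBand(25, 35)) == pytest.approx(expected, abs=0.5)

    def test_zero_prevalence_with_cases_rejected(self):
        with pytest.raises(ValueError, match="0%"):
            reconstruct_denominators(self._report([("M", "25-34", 2003, 10, 0.0)]))

    def test_unknown_stratum_flagged_not_fabricated(self):
        out = reconstruct_denominators(self._report([("M", "25-34", 2003, 0, 0.0)]))
        assert out.entries == {}

    def test_totals_rows_are_checksums_not_sources(self):
        out = reconstruct_denominators(
            self._report(
                [("M", "25-34", 2003, 100, 10.0), ("M", "total", 2003, 100, 5.0)]
            )
        )
        assert list(out.entries) == [(2003, "M", AgeBand(25, 35))]

    @given(
        denom=st.floats(1e4, 1e7),
        prev=st.floats(0.1, 60.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_within_printed_rounding(self, denom, prev):
        """counts → rounded prevalence → denominator → prevalence is stable to ±0.05 pp."""
        count = denom * prev / 100.0
        printed = round(prev, 1)
        out = reconstruct_denominators(
            self._report([("M", "25-34", 2003, count, printed)])
        )
        d2 = out.get(2003, "M", AgeBand(25, 35))
        assert abs(100.0 * count / d2 - prev) <= 0.05 + 1e-9


class TestCohortEntry:
    def test_growth_reconciliation(self):
        pop = _anchors({2003: 1000.0, 2004: 1100.0})
        out = cohort_entry(pop, 2004, aging_out=50.0, deaths=10.0)
        assert out["M"] == pytest.approx(160.0)

    def test_stationary_closed_population(self):
        pop = _anchors({2003: 1000.0, 2004: 1000.0})
        assert cohort_entry(pop, 2004)["M"] == 0.0

    def test_first_year_has_no_prior(self):
        pop = _anchors({2003: 1000.0, 2004: 1100.0})
        with pytest.raises(ValueError, match="prior year"):
            cohort_entry(pop, 2003)

    def test_negative_balance_floored(self, caplog):
        pop = _anchors({2003: 1000.0, 2004: 800.0})
        with caplog.at_level("WARNING"):
            out = cohort_entry(pop, 2004)
        assert out["M"] == 0.0
        assert "floor" in caplog.text


def test_population_csv_round_trip(tmp_path):
    t = PopulationTable()
    t.set(2003, "M", AgeBand(25, 35), 123.0)
    t.set(2003, "F", AgeBand(75, None), 456.0)  # open band ↔ empty age_upper
    path = tmp_path / "pop.csv"
    t.to_csv(path)
    back = PopulationTable.from_csv(path)
    assert back.entries == t.entries
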