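import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmproj.bands import CORE_BANDS, AgeBand
from dmproj.demography import PopulationTable
from dmproj.rates import (
    RelativeRisks,
    attributable_deaths,
    estimate_incidence_from_prevalence,
    excess_mortality,
    forward_prevalence,
    partition_mortality,
)


class TestMortalityPartition:
    def test_closed_form_example(self):
        m0, m1, attr = partition_mortality(0.01, 0.1, 2.0)
        assert m0 == pytest.approx(0.01 / 1.1)
        assert m1 == pytest.approx(0.02 / 1.1)
        assert attr == pytest.approx(0.001 / 1.1)

    def test_null_relative_risk(self):
        m0, m1, attr = partition_mortality(0.02, 0.3, 1.0)
        assert m0 == m1 == 0.02
        assert attr == 0.0

    def test_zero_prevalence(self):
        m0, _, attr = partition_mortality(0.02, 0.0, 3.0)
        assert m0 == 0.02
        assert attr == 0.0

    @given(
        m=st.floats(0.0, 0.5),
        p=st.floats(0.0, 1.0),
        rr=st.floats(0.2, 10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_prevalence_weighted_mean_conserved(self, m, p, rr):
        """(1−p)·m0 + p·m1 must reassemble the all-cause rate exactly."""
        m0, m1, _ = partition_mortality(m, p, rr)
        assert (1 - p) * m0 + p * m1 == pytest.approx(m, rel=1e-12, abs=1e-15)

    def test_m0_strictly_decreasing_in_rr(self):
        vals = [partition_mortality(0.01, 0.2, rr)[0] for rr in (1.0, 1.5, 2.0, 4.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("bad", [dict(rr=0.0), dict(rr=-1.0), dict(p=-0.1), dict(p=1.5)])
    def test_invalid_inputs_rejected(self, bad):
        kwargs = dict(m=0.01, p=0.1, rr=2.0) | bad
        with pytest.raises(ValueError):
            partition_mortality(kwargs["m"], kwargs["p"], kwargs["rr"])

    def test_excess_is_m0_scaled(self):
        e = excess_mortality(0.01, 0.1, 2.0)
        m0 = partition_mortality(0.01, 0.1, 2.0)[0]
        assert e == pytest.approx(m0)


class TestIncidenceBackCalculation:
    def test_constant_prevalence_without_excess_needs_no_new_cases(self):
        """Flat prevalence with e=0 and no remission → zero incidence above the first band."""
        i = estimate_incidence_from_prevalence([0.1] * 5, [0.01] * 5, [0.0] * 5)
        assert i[0] > 0  # the first band must build prevalence from zero
        assert np.all(i[1:] == 0.0)

    def test_recovers_generating_hazard(self):
        """Forward-simulate a known constant hazard, recover it to <1% relative."""
        i_true, m0, e = 0.015, 0.008, 0.004
        curve = forward_prevalence([i_true] * 6, [m0] * 6, [e] * 6)
        i_hat = estimate_incidence_from_prevalence(curve, [m0] * 6, [e] * 6)
        assert np.abs(i_hat - i_true).max() / i_true < 0.01

    def test_round_trip_prevalence(self):
        """Estimated hazards reproduce the input curve at band midpoints (<0.5% absolute)."""
        rng_curve = np.array([0.01, 0.05, 0.15, 0.28, 0.35, 0.40])
        m0 = np.full(6, 0.01)
        e = np.full(6, 0.01)
        i_hat = estimate_incidence_from_prevalence(rng_curve, m0, e)
        back = forward_prevalence(i_hat, m0, e)
        assert np.abs(back - rng_curve).max() < 0.005

    @given(
        i=st.lists(st.floats(0.0, 0.05), min_size=4, max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_prevalence_nondecreasing_without_excess(self, i):
        """With zero excess mortality and zero remission, prevalence cannot fall with age."""
        curve = forward_prevalence(i, [0.01] * 4, [0.0] * 4)
        assert np.all(np.diff(curve) >= -1e-12)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="align"):
            estimate_incidence_from_prevalence([0.1, 0.2], [0.01], [0.0, 0.0])

    def test_prevalence_bounds_enforced(self):
        with pytest.raises(ValueError):
            estimate_incidence_from_prevalence([0.1, 1.2], [0.01] * 2, [0.0] * 2)


class TestAttributableDeaths:
    def _pop(self, n=100_000.0):
        t = PopulationTable()
        t.set(2011, "M", AgeBand(25, 35), n)
        return t

    def test_null_relative_risk_means_no_attributable_deaths(self):
        rr = RelativeRisks(rr_mort_dm=1.0)
        out = attributable_deaths(
            self._pop(), {("M", "25-34"): 0.1}, {("M", "25-34"): 0.01}, rr, 2011
        )
        assert out == 0.0

    def test_single_stratum_arithmetic(self):
        rr = RelativeRisks(rr_mort_dm=2.0)
        out = attributable_deaths(
            self._pop(), {("M", "25-34"): 0.1}, {("M", "25-34"): 0.01}, rr, 2011
        )
        assert out == pytest.approx(100.0)

    def test_stratum_misalignment_rejected(self):
        rr = RelativeRisks()
        with pytest.raises(ValueError, match="missing"):
            attributable_deaths(self._pop(), {}, {}, rr, 2011)
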