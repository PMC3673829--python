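import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmproj import run_projection, syria
from dmproj.bands import CORE_BANDS, SEXES, AgeBand, AgeGrid
from dmproj.markov import (
    DM,
    EXPOSURE,
    LIVING,
    RiskFactorSpec,
    StateVector,
    TransitionSet,
    apply_risk_trend,
    exposure_specific_incidence,
    independence_split,
    initialize_states,
    step_one_cycle,
)
from dmproj.rates import RelativeRisks
from dmproj.synthetic import SyntheticCountrySpec, generate_country

ONE_BAND = (AgeBand(25, None),)


def _one_band_state(n=1000.0, p_dm=0.0, q_o=0.3, q_s=0.2):
    grid = AgeGrid.from_bands(ONE_BAND)
    risk = RiskFactorSpec.uniform(ONE_BAND, obesity={"M": q_o, "F": q_o}, smoking={"M": q_s, "F": q_s})
    pop = {(s, "25+"): n for s in SEXES}
    dm = {(s, "25+"): p_dm for s in SEXES}
    return initialize_states(pop, dm, risk, grid, 2000), risk


def _zero_transitions(grid):
    z = np.zeros((2, grid.n_cells))
    return TransitionSet(np.zeros((2, grid.n_cells, 4)), z.copy(), z.copy(), z.copy())


class TestInitialization:
    def test_independence_arithmetic(self):
        state, _ = _one_band_state(n=1000.0, p_dm=0.0, q_o=0.4, q_s=0.5)
        assert np.allclose(state.occ[0, 0, :4], [300.0, 200.0, 300.0, 200.0])

    def test_no_exposure_means_everyone_healthy(self):
        state, _ = _one_band_state(n=500.0, p_dm=0.0, q_o=0.0, q_s=0.0)
        assert state.occ[0, 0, 0] == 500.0
        assert state.occ[0, 0, 1:4].sum() == 0.0

    def test_marginals_reproduce_survey_prevalences(self):
        """Diabetes, obesity and smoking marginals of the initial state match the inputs."""
        state, _ = _one_band_state(n=10_000.0, p_dm=0.147, q_o=0.401, q_s=0.188)
        occ = state.occ[1, 0]
        living = occ[LIVING].sum()
        non_dm = occ[EXPOSURE].sum()
        assert occ[DM] / living == pytest.approx(0.147)
        assert (occ[1] + occ[3]) / non_dm == pytest.approx(0.401)
        assert (occ[2] + occ[3]) / non_dm == pytest.approx(0.188)

    def test_negative_occupancy_is_named(self):
        grid = AgeGrid.from_bands(ONE_BAND)
        occ = np.zeros((2, 1, 7))
        occ[0, 0, 4] = -5.0
        with pytest.raises(ValueError, match="diabetes"):
            StateVector(occ, grid, 2000)


class TestExposureSpecificIncidence:
    def test_unit_relative_risks_spread_uniformly(self):
        out = exposure_specific_incidence(0.02, [0.25, 0.25, 0.25, 0.25], 1.0, 1.0)
        assert np.allclose(out, 0.02)

    def test_reference_hazard_normalization(self):
        out = exposure_specific_incidence(0.014, [0.5, 0.3, 0.2, 0.0], 2.0, 1.5)
        assert out[0] == pytest.approx(0.014 / 1.4)  # 0.5 + 0.6 + 0.3 = 1.4
        assert out[1] == pytest.approx(2.0 * 0.014 / 1.4)

    @given(
        i=st.floats(0.0, 0.02),
        q_o=st.floats(0.0, 0.9),
        q_s=st.floats(0.0, 0.9),
        rr_o=st.floats(1.0, 10.0),
        rr_s=st.floats(1.0, 3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_share_weighted_mean_conserved(self, i, q_o, q_s, rr_o, rr_s):
        shares = independence_split(q_o, q_s)
        out = exposure_specific_incidence(i, shares, rr_o, rr_s)
        assert float(shares @ out) == pytest.approx(i, rel=1e-10, abs=1e-15)

    def test_expected_new_cases_conserved_through_one_cycle(self):
        """Feeding the compartment hazards through a cycle yields N_nonDM·q(i_pop)-level inflow."""
        state, risk = _one_band_state(n=1000.0, q_o=0.4, q_s=0.5)
        grid = state.grid
        i_comp = exposure_specific_incidence(0.05, independence_split(0.4, 0.5), 2.0, 1.5)
        # direct probabilities, no deaths: inflow = Σ share·i·N
        q = np.tile(i_comp, (2, grid.n_cells, 1))
        ts = TransitionSet(q, np.zeros((2, 1)), np.zeros((2, 1)), np.zeros((2, 1)))
        new, _ = step_one_cycle(state, ts, risk.at(0.0))
        assert new.occ[0, 0, DM] == pytest.approx(1000.0 * 0.05)

    def test_impossible_probability_rejected(self):
        with pytest.raises(ValueError, match="cycle length"):
            exposure_specific_incidence(0.5, [1.0, 0.0, 0.0, 0.0], 9.0, 9.0)


class TestRiskTrend:
    def _risk(self, base=0.29, trend=0.01, cap=0.80):
        return RiskFactorSpec.uniform(
            ONE_BAND, obesity={"M": base, "F": base}, smoking={"M": 0.5, "F": 0.5},
            obesity_trend=trend, obesity_cap=cap,
        )

    def test_linear_percentage_point_rise(self):
        q = apply_risk_trend(self._risk(0.29, 0.01), 3.0)
        assert q[("M", "25+")][0] == pytest.approx(0.32)

    def test_cap_saturates(self):
        q = apply_risk_trend(self._risk(0.795, 0.01), 5.0)
        assert q[("M", "25+")][0] == pytest.approx(0.80)

    def test_zero_trend_is_inert(self):
        q = apply_risk_trend(self._risk(0.4, 0.0), 50.0)
        assert q[("M", "25+")] == (0.4, 0.5)

    @given(years=st.floats(0.0, 100.0), base=st.floats(0.0, 1.0), trend=st.floats(-0.05, 0.05))
    @settings(max_examples=100, deadline=None)
    def test_never_outside_bounds(self, years, base, trend):
        q = self._risk(base, trend).at(years)
        q_o, q_s = q[("M", "25+")]
        assert 0.0 <= q_o <= 0.80 + 1e-12
        assert 0.0 <= q_s <= 1.0


class TestCycle:
    def test_inert_cycle_preserves_state(self):
        state, risk = _one_band_state(n=1000.0, p_dm=0.1)
        new, acct = step_one_cycle(state, _zero_transitions(state.grid), risk.at(0.0))
        assert np.allclose(new.occ, state.occ, rtol=1e-12, atol=1e-9)
        assert acct.deaths_dm.sum() == 0.0

    def test_band_aging_moves_one_wth_per_cycle(self):
        bands = (AgeBand(25, 35), AgeBand(35, None))
        grid = AgeGrid.from_bands(bands)
        risk = RiskFactorSpec.uniform(bands, obesity={"M": 0, "F": 0}, smoking={"M": 0, "F": 0})
        pop = {(s, b.label): 1000.0 if b.lower == 25 else 0.0 for s in SEXES for b in bands}
        dm = {(s, b.label): 0.0 for s in SEXES for b in bands}
        state = initialize_states(pop, dm, risk, grid, 2000)
        new, _ = step_one_cycle(state, _zero_transitions(grid), risk.at(0.0))
        assert new.occ[0, 0, 0] == pytest.approx(900.0)  # 1/10 advanced
        assert new.occ[0, 1, 0] == pytest.approx(100.0)

    def test_pure_incidence_flow(self):
        state, risk = _one_band_state(n=1000.0, p_dm=0.0)
        grid = state.grid
        q = np.full((2, grid.n_cells, 4), 0.1)
        ts = TransitionSet(q, np.zeros((2, 1)), np.zeros((2, 1)), np.zeros((2, 1)))
        new, _ = step_one_cycle(state, ts, risk.at(0.0))
        assert new.occ[0, 0, DM] == pytest.approx(100.0)
        assert new.occ[0, 0, :4].sum() == pytest.approx(900.0)

    def test_entrants_join_diabetes_free(self):
        state, risk = _one_band_state(n=1000.0, p_dm=0.5)
        new, acct = step_one_cycle(
            state, _zero_transitions(state.grid), risk.at(0.0), entrants={"M": 200.0, "F": 0.0}
        )
        assert acct.entrants[0] == 200.0
        assert new.occ[0, 0, DM] == pytest.approx(500.0)      # untouched
        assert new.occ[0, 0, :4].sum() == pytest.approx(700.0)

    def test_no_remission_diabetes_decays_only_by_death(self):
        """With zero incidence the diabetes pool shrinks exactly by its death probabilities."""
        state, risk = _one_band_state(n=1000.0, p_dm=0.4)
        grid = state.grid
        ts = TransitionSet(
            np.zeros((2, 1, 4)),
            np.full((2, 1), 0.02),
            np.full((2, 1), 0.02),
            np.full((2, 1), 0.03),
        )
        cur = state
        for t in range(5):
            cur, _ = step_one_cycle(cur, ts, risk.at(0.0))
        expected = 400.0 * (1 - 0.05) ** 5
        assert cur.occ[0, 0, DM] == pytest.approx(expected, rel=1e-12)


class TestProjectionInvariants:
    @given(
        i=st.floats(0.0, 0.05),
        m0=st.floats(1e-6, 0.05),
        e=st.floats(0.0, 0.05),
        p0=st.floats(0.0, 0.5),
    )
    @settings(max_examples=25, deadline=None)
    def test_person_conservation_closed(self, i, m0, e, p0):
        """living(t+1) + cumulative deaths(t+1) == living(t) + cumulative deaths(t) + entrants."""
        spec = SyntheticCountrySpec(
            incidence=i, mortality_background=m0, excess_mortality=e, dm_prev0=p0,
            growth=0.0, start_year=2000, end_year=2008,
        )
        res = run_projection(generate_country(spec).config(demography_mode="closed"))
        for t, acct in enumerate(res.accounting):
            before = res.states[t].occ[:, :, LIVING].sum()
            after = res.states[t + 1].occ[:, :, LIVING].sum()
            deaths = acct.deaths_other.sum() + acct.deaths_dm.sum()
            assert after + deaths == pytest.approx(before, rel=1e-12, abs=1e-6)

    def test_conservation_with_migration_term_under_rescale(self, syria_baseline):
        res = syria_baseline
        for t, acct in enumerate(res.accounting):
            before = res.states[t].occ[:, :, LIVING].sum(axis=(1, 2))
            after = res.states[t + 1].occ[:, :, LIVING].sum(axis=(1, 2))
            deaths = acct.deaths_other + acct.deaths_dm
            assert np.allclose(after + deaths, before + acct.entrants + acct.migration, rtol=1e-9)

    def test_death_compartments_monotone(self, syria_baseline):
        dead = np.array([s.occ[:, :, 5:7].sum() for s in syria_baseline.states])
        assert np.all(np.diff(dead) > 0)

    def test_obesity_never_exceeds_cap(self, syria_baseline):
        for state in syria_baseline.states:
            arr = state.band_array()
            non_dm = arr[:, :, :4].sum(axis=2)
            obese = arr[:, :, 1] + arr[:, :, 3]
            with np.errstate(invalid="ignore"):
                share = np.where(non_dm > 0, obese / np.where(non_dm > 0, non_dm, 1.0), 0.0)
            assert np.all(share <= 0.80 + 1e-12)

    def test_monotone_in_obesity_relative_risk(self):
        """A larger obesity incidence RR can never lower projected prevalence."""
        runs = {}
        for rr_o in (7.19, 12.41):
            rr = RelativeRisks(rr_mort_dm={"M": 1.5, "F": 2.5}, rr_dm_obese=rr_o, rr_dm_smoker=1.44)
            runs[rr_o] = run_projection(syria.projection_config(relative_risks=rr))
        for y in runs[7.19].years:
            assert runs[12.41].prevalence(y) >= runs[7.19].prevalence(y) - 1e-12

    def test_deterministic_bit_identical(self, syria_baseline):
        again = run_projection(syria.projection_config())
        assert all(
            (a.occ == b.occ).all() for a, b in zip(again.states, syria_baseline.states)
        )

    def test_zero_incidence_prevalence_declines(self):
        """With no inflow, diabetes counts never rise and prevalence erodes."""
        from dmproj.markov import IncidenceSpec

        cfg = syria.projection_config(
            incidence=IncidenceSpec(per_100k={"M": 0.0, "F": 0.0}, denominator="total")
        )
        res = run_projection(cfg)
        counts = np.array([res.diabetes_count(y) for y in res.years])
        assert np.all(np.diff(counts) <= 1e-6)
        assert res.prevalence(2022) < res.prevalence(2003)

    def test_closed_form_oracle(self, oracle_bundle):
        """Constant-hazard single-stratum run matches the analytic solution each cycle."""
        res = run_projection(oracle_bundle.config(demography_mode="closed"))
        truth = oracle_bundle.truth["prevalence_trajectory"]["M"]
        model = np.array([res.prevalence(y, "M") for y in res.years])
        assert np.abs(model / truth - 1.0).max() < 1e-3

    def test_incomplete_config_lists_all_missing_fields(self):
        from dmproj.markov import ConfigError, ProjectionConfig

        cfg = ProjectionConfig(start_year=2000, end_year=2010)
        with pytest.raises(ConfigError) as err:
            cfg.validate()
        for field in ("population", "dm_prevalence", "mortality", "incidence"):
            assert field in str(err.value)
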