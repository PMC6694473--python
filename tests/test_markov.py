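"""Markov engine: matrix construction, cohort propagation, outcome
accumulation, and agreement with a brute-force path-enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pahcea.markov import (
    CohortTrace,
    InvalidRowError,
    TransitionMatrix,
    accumulate_outcomes,
    build_transition_matrix,
    choose_horizon,
    run_cohort,
    state_cost_vector,
)
from pahcea.moments import MomentSpec
from pahcea.parameters import BaselineTransitions, DeathProbabilities, TreatmentEffect
from pahcea.states import N_STATES, FunctionalClass

FC = FunctionalClass


def _fixed(x):
    return MomentSpec(mean=x, family="fixed")


def _baseline(w1, i2, w2, i3, w3, i4):
    return BaselineTransitions(
        fc1_to_fc2=_fixed(w1), fc2_to_fc1=_fixed(i2), fc2_to_fc3=_fixed(w2),
        fc3_to_fc2=_fixed(i3), fc3_to_fc4=_fixed(w3), fc4_to_fc3=_fixed(i4),
    )


def _deaths(d1, d2, d3, d4):
    return DeathProbabilities(fc1=_fixed(d1), fc2=_fixed(d2), fc3=_fixed(d3), fc4=_fixed(d4))


class TestBuildTransitionMatrix:
    def test_sildenafil_fc2_row(self, params):
        """Hand-multiplied RR-on-baseline arithmetic for the FC II row."""
        m = build_transition_matrix(
            params.transitions, params.deaths, params.effects["sildenafil"]
        ).probs
        row = m[int(FC.FC2)]
        assert row[int(FC.FC1)] == pytest.approx(0.125 * 4.23)      # improve 0.52875
        assert row[int(FC.FC3)] == pytest.approx(0.127 * 0.43)      # worsen 0.05461
        assert row[int(FC.DEATH)] == pytest.approx(0.013)
        assert row[int(FC.FC2)] == pytest.approx(0.40364)
        assert row[int(FC.FC4)] == 0.0

    def test_beraprost_fc3_row(self, params):
        m = build_transition_matrix(
            params.transitions, params.deaths, params.effects["beraprost"]
        ).probs
        row = m[int(FC.FC3)]
        assert row[int(FC.FC2)] == pytest.approx(0.11625)
        assert row[int(FC.FC4)] == pytest.approx(0.0094)
        assert row[int(FC.DEATH)] == pytest.approx(0.016)
        assert row[int(FC.FC3)] == pytest.approx(0.85835)

    def test_neutral_effect_equals_standard_care(self, params):
        neutral = TreatmentEffect(rr_worsening=_fixed(1.0), rr_improvement=_fixed(1.0))
        treated = build_transition_matrix(params.transitions, params.deaths, neutral)
        standard = build_transition_matrix(params.transitions, params.deaths, None)
        np.testing.assert_allclose(treated.probs, standard.probs, atol=0)

    def test_rows_stochastic_and_structure(self, params):
        for drug in ("sildenafil", "beraprost"):
            m = build_transition_matrix(
                params.transitions, params.deaths, params.effects[drug]
            ).probs
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= 0).all()
            # death row absorbing; only adjacent-FC moves allowed
            np.testing.assert_array_equal(m[4], [0, 0, 0, 0, 1])
            assert m[0, 2] == m[0, 3] == m[1, 3] == m[3, 1] == m[2, 0] == m[3, 0] == 0.0

    def test_capping_rescales_moves_keeps_death(self):
        baseline = _baseline(0.0, 0.6, 0.5, 0.0, 0.0, 0.0)
        deaths = _deaths(0.0, 0.2, 0.0, 0.5)
        with pytest.warns(RuntimeWarning, match="capped"):
            m = build_transition_matrix(baseline, deaths, None)
        row = m.probs[int(FC.FC2)]
        assert m.capped_rows == 1
        assert row[int(FC.DEATH)] == pytest.approx(0.2)
        assert row[int(FC.FC1)] + row[int(FC.FC3)] == pytest.approx(0.8)
        # proportional: improvement/worsening ratio preserved
        assert row[int(FC.FC1)] / row[int(FC.FC3)] == pytest.approx(0.6 / 0.5)
        assert row[int(FC.FC2)] == pytest.approx(0.0, abs=1e-12)

    def test_capping_disabled_raises(self):
        baseline = _baseline(0.0, 0.6, 0.5, 0.0, 0.0, 0.0)
        deaths = _deaths(0.0, 0.2, 0.0, 0.5)
        with pytest.raises(InvalidRowError):
            build_transition_matrix(baseline, deaths, None, cap=False)


class TestRunCohort:
    def test_identity_matrix_constant(self):
        tm = TransitionMatrix(probs=np.eye(5))
        trace = run_cohort(tm, FC.FC3, 10)
        assert (trace.occupancy[:, int(FC.FC3)] == 1.0).all()

    def test_immediate_death(self):
        p = np.eye(5)
        p[int(FC.FC2)] = [0, 0, 0, 0, 1]
        trace = run_cohort(TransitionMatrix(probs=p), FC.FC2, 3)
        assert trace.occupancy[1, int(FC.DEATH)] == 1.0
        assert trace.living[1:].sum() == 0.0

    def test_one_step_equals_matrix_row(self, params):
        tm = build_transition_matrix(params.transitions, params.deaths,
                                     params.effects["sildenafil"])
        trace = run_cohort(tm, FC.FC2, 1)
        np.testing.assert_allclose(trace.occupancy[1], tm.probs[int(FC.FC2)], atol=0)

    def test_mass_conservation_and_death_monotone(self, params):
        tm = build_transition_matrix(params.transitions, params.deaths,
                                     params.effects["beraprost"])
        trace = run_cohort(tm, FC.FC3, 200)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        dead = trace.occupancy[:, int(FC.DEATH)]
        assert (np.diff(dead) >= -1e-12).all()
        assert (np.diff(trace.living) <= 1e-12).all()

    def test_bad_arguments(self, params):
        tm = build_transition_matrix(params.transitions, params.deaths, None)
        with pytest.raises(ValueError):
            run_cohort(tm, FC.FC2, 0)
        with pytest.raises(ValueError):
            run_cohort(tm, FC.DEATH, 5)


class TestAccumulateOutcomes:
    def test_fixed_fc2_hand_sum(self, params_copy):
        """One patient held in FC II for a year, undiscounted, societal arm."""
        p = params_copy
        # components chosen to make the FC II direct medical cost exactly 368
        p.costs.admissions_per_cycle.fc2 = _fixed(0.0)
        p.costs.visits_per_cycle.fc2 = _fixed(4.0)
        p.costs.cost_per_visit = _fixed(92.0)
        p.settings.annual_discount_rate = 0.0
        occ = np.zeros((5, N_STATES))
        occ[:, int(FC.FC2)] = 1.0
        trace = CohortTrace(occupancy=occ, start_state=FC.FC2, horizon_cycles=4)
        out = accumulate_outcomes(trace, p.utilities, p.costs, "sildenafil", p.settings)
        assert out.total_cost_discounted == pytest.approx(4 * (368 + 110 + 92))
        assert out.life_years_undiscounted == pytest.approx(1.0)
        assert out.qalys_undiscounted == pytest.approx(0.71)

    def test_unit_utilities_zero_discount_qalys_equal_life_years(self, params_copy):
        p = params_copy
        for k in ("fc1", "fc2", "fc3", "fc4"):
            setattr(p.utilities, k, MomentSpec(mean=1.0, se=0.0, family="beta"))
        p.settings.annual_discount_rate = 0.0
        tm = build_transition_matrix(p.transitions, p.deaths, p.effects["sildenafil"])
        trace = run_cohort(tm, FC.FC2, 80)
        out = accumulate_outcomes(trace, p.utilities, p.costs, "sildenafil", p.settings)
        assert out.qalys_undiscounted == pytest.approx(out.life_years_undiscounted, rel=1e-14)
        assert out.qalys_discounted == pytest.approx(out.life_years_discounted, rel=1e-14)

    def test_discounting_strictly_reduces(self, params):
        tm = build_transition_matrix(params.transitions, params.deaths,
                                     params.effects["beraprost"])
        trace = run_cohort(tm, FC.FC3, 40)
        out = accumulate_outcomes(trace, params.utilities, params.costs,
                                  "beraprost", params.settings)
        assert out.life_years_discounted < out.life_years_undiscounted
        assert out.qalys_discounted < out.qalys_undiscounted
        assert out.total_cost_discounted < out.total_cost_undiscounted
        assert out.qalys_discounted <= out.life_years_discounted

    def test_annual_discount_factor_definition(self, params):
        # cycle 4 = one year: (1.03)^-1
        r, dt = params.settings.annual_discount_rate, params.settings.cycle_length_years
        assert (1 + r) ** (-4 * dt) == pytest.approx(1 / 1.03)

    def test_government_perspective_drops_nonmedical(self, params_copy):
        p = params_copy
        tm = build_transition_matrix(p.transitions, p.deaths, p.effects["beraprost"])
        trace = run_cohort(tm, FC.FC2, 20)
        societal = accumulate_outcomes(trace, p.utilities, p.costs, "beraprost", p.settings)
        p.settings.perspective = "government"
        gov = accumulate_outcomes(trace, p.utilities, p.costs, "beraprost", p.settings)
        assert gov.total_cost_discounted < societal.total_cost_discounted
        assert gov.qalys_discounted == societal.qalys_discounted


def _enumerate_paths_oracle(probs, start, horizon, u, cvec, dt, rate):
    """Independent oracle: exhaustive enumeration of state paths.

    Sums LY/QALY/cost over every possible state sequence weighted by its
    path probability; accrual at the start of each of the ``horizon``
    cycles, discounted by (1+rate)^(-k*dt).
    """
    totals = {"ly": 0.0, "qaly": 0.0, "cost": 0.0}

    def recurse(state, k, prob, ly, qaly, cost):
        if prob == 0.0:
            return
        if k == horizon:
            totals["ly"] += prob * ly
            totals["qaly"] += prob * qaly
            totals["cost"] += prob * cost
            return
        disc = (1.0 + rate) ** (-k * dt)
        living = state != 4
        ly_k = ly + (dt if living else 0.0) * disc
        qaly_k = qaly + u[state] * dt * disc
        cost_k = cost + cvec[state] * disc
        for nxt in range(5):
            recurse(nxt, k + 1, prob * probs[state, nxt], ly_k, qaly_k, cost_k)

    recurse(int(start), 0, 1.0, 0.0, 0.0, 0.0)
    return totals


@pytest.mark.parametrize("drug,start", [("sildenafil", FC.FC2), ("beraprost", FC.FC3)])
def test_brute_force_path_enumeration_oracle(params, drug, start):
    """Engine outcomes equal exhaustive path enumeration at a short horizon."""
    h = 6
    tm = build_transition_matrix(params.transitions, params.deaths, params.effects[drug])
    trace = run_cohort(tm, start, h)
    out = accumulate_outcomes(trace, params.utilities, params.costs, drug, params.settings)
    u = np.array([params.utilities[fc].mean for fc in FC if fc.is_living] + [0.0])
    cvec = state_cost_vector(params.costs, drug, params.settings.perspective)
    oracle = _enumerate_paths_oracle(
        tm.probs, start, h, u, cvec,
        params.settings.cycle_length_years, params.settings.annual_discount_rate,
    )
    assert out.life_years_discounted == pytest.approx(oracle["ly"], abs=1e-9)
    assert out.qalys_discounted == pytest.approx(oracle["qaly"], abs=1e-9)
    assert out.total_cost_discounted == pytest.approx(oracle["cost"], abs=1e-9)


class TestChooseHorizon:
    def test_fixed(self):
        assert choose_horizon(None, None, "fixed:120") == 120

    def test_extinction_immediate_death(self):
        p = np.eye(5)
        p[int(FC.FC2)] = [0, 0, 0, 0, 1]
        tm = TransitionMatrix(probs=p)
        assert choose_horizon(tm, FC.FC2, "extinction:1e-4") == 1

    def test_extinction_bad_epsilon(self, params):
        tm = build_transition_matrix(params.transitions, params.deaths, None)
        with pytest.raises(ValueError):
            choose_horizon(tm, FC.FC2, "extinction:0")

    def test_extinction_exceeds_calibrated_horizon(self, params):
        """Without background mortality the chain takes far longer than the
        calibrated lifetime to die out (undiscounted LY ~73 years at
        near-extinction vs the published ~28) — the evidence that the
        published 'lifetime' is a finite horizon, which the calibrated
        140-cycle default supplies."""
        tm = build_transition_matrix(params.transitions, params.deaths,
                                     params.effects["sildenafil"])
        h = choose_horizon(tm, FC.FC2, "extinction:1e-3")
        assert h > params.settings.horizon_cycles
        from pahcea.markov import accumulate_outcomes
        out = accumulate_outcomes(run_cohort(tm, FC.FC2, h), params.utilities,
                                  params.costs, "sildenafil", params.settings)
        assert out.life_years_undiscounted > 50.0

    def test_calibrated_reads_settings(self, params):
        assert choose_horizon(None, None, "calibrated", params.settings) == \
            params.settings.horizon_cycles


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    probs=st.lists(st.floats(0.0, 0.6), min_size=6, max_size=6),
    deaths=st.lists(st.floats(0.0, 0.9), min_size=4, max_size=4),
    rr_w=st.floats(0.01, 6.0),
    rr_i=st.floats(0.01, 6.0),
)
def test_matrix_valid_for_arbitrary_inputs_after_capping(probs, deaths, rr_w, rr_i):
    """Capping keeps every row a probability vector for any admissible draw."""
    baseline = _baseline(*probs)
    dp = _deaths(*deaths)
    eff = TreatmentEffect(rr_worsening=_fixed(rr_w), rr_improvement=_fixed(rr_i))
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = build_transition_matrix(baseline, dp, eff).probs
    assert (m >= -1e-12).all() and (m <= 1 + 1e-12).all()
    np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
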