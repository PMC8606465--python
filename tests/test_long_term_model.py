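"""Markov engine: mortality combination, recurrence, matrix structure,
trace propagation and agreement with an individual-level oracle."""

import copy

import numpy as np
import pytest

from evtvalue.model_types import (
    LIVING_STATES,
    MRSDistribution,
    MRSState,
)
from evtvalue.long_term_model import (
    annual_death_prob,
    build_transition_matrix,
    recurrence_redistribution,
    run_cohort,
)
from conftest import make_quiet_params
from oracles import brute_force_redistribution, microsimulate


class TestAnnualDeathProb:
    def test_identity_hazard_returns_background(self, params):
        q_mix = 0.5 * params.life_table.q(70, "M") + 0.5 * params.life_table.q(70, "F")
        quiet = make_quiet_params(flat_q=q_mix, hr=1.0)
        p = annual_death_prob(
            70, 0.5, MRSState.MRS2, 1, quiet.life_table, quiet.hazards
        )
        assert p == pytest.approx(q_mix, rel=1e-12)

    def test_zero_background_gives_zero(self):
        quiet = make_quiet_params(flat_q=0.0, hr=7.3)
        assert annual_death_prob(69, 0.5, MRSState.MRS5, 3, quiet.life_table, quiet.hazards) == 0.0

    def test_rate_multiplication_formula(self):
        # q = 0.1, hr = 2 -> 1 - 0.9^2 = 0.19
        quiet = make_quiet_params(flat_q=0.1, hr=2.0)
        p = annual_death_prob(69, 0.5, MRSState.MRS3, 1, quiet.life_table, quiet.hazards)
        assert p == pytest.approx(0.19, rel=1e-12)

    def test_certain_background_death(self):
        quiet = make_quiet_params(flat_q=1.0, hr=2.5)
        assert annual_death_prob(69, 0.5, MRSState.MRS2, 1, quiet.life_table, quiet.hazards) == 1.0

    def test_nonpositive_hazard_rejected(self):
        quiet = make_quiet_params(flat_q=0.1, hr=1.0)
        quiet.hazards.table[:, :] = -1.0
        with pytest.raises(ValueError):
            annual_death_prob(69, 0.5, MRSState.MRS2, 1, quiet.life_table, quiet.hazards)

    def test_dead_state_rejected(self, params):
        with pytest.raises(ValueError):
            annual_death_prob(69, 0.5, MRSState.DEAD, 1, params.life_table, params.hazards)


class TestRecurrenceRedistribution:
    def test_worst_living_state_keeps_all_mass(self, params):
        out = recurrence_redistribution(MRSState.MRS5, params.recurrence.base_dist)
        assert out[int(MRSState.MRS5)] == pytest.approx(1.0)
        assert out[int(MRSState.DEAD)] == 0.0

    def test_best_state_reproduces_base_distribution(self, params):
        out = recurrence_redistribution(MRSState.MRS0_1, params.recurrence.base_dist)
        np.testing.assert_allclose(out[:5], params.recurrence.base_dist)

    def test_hand_computed_truncation(self):
        base = np.array([0.3, 0.2, 0.2, 0.2, 0.1])
        out = recurrence_redistribution(MRSState.MRS3, base)
        np.testing.assert_allclose(out, [0, 0, 0.4, 0.4, 0.2, 0.0])

    def test_matches_brute_force_on_random_bases(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            base = rng.dirichlet(np.ones(5))
            for s in LIVING_STATES:
                np.testing.assert_allclose(
                    recurrence_redistribution(s, base),
                    brute_force_redistribution(int(s), base),
                    atol=1e-13,
                )

    def test_zero_mass_above_current_is_an_error(self):
        base = np.array([0.6, 0.4, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="MRS4"):
            recurrence_redistribution(MRSState.MRS4, base)


class TestTransitionMatrix:
    def test_identity_without_death_or_recurrence(self):
        quiet = make_quiet_params(flat_q=0.0, p_rec=0.0)
        np.testing.assert_allclose(build_transition_matrix(1, quiet), np.eye(6))

    def test_no_recurrence_populates_diagonal_and_dead_only(self, params):
        p = copy.deepcopy(params)
        p.recurrence.p_rec[:] = 0.0
        mat = build_transition_matrix(2, p)
        off = mat.copy()
        np.fill_diagonal(off, 0.0)
        off[:, int(MRSState.DEAD)] = 0.0
        assert np.all(off == 0.0)

    def test_no_spontaneous_improvement(self, params):
        """No entry below the diagonal among living states at any cycle."""
        for t in range(1, 6):
            mat = build_transition_matrix(t, params)
            for s in LIVING_STATES:
                assert np.all(mat[int(s), : int(s)] == 0.0)

    def test_rows_stochastic(self, params):
        for t in range(1, 6):
            mat = build_transition_matrix(t, params)
            np.testing.assert_allclose(mat.sum(axis=1), np.ones(6), atol=1e-12)
            assert np.all(mat >= 0)

    def test_dead_row_absorbing(self, params):
        mat = build_transition_matrix(1, params)
        expected = np.zeros(6)
        expected[int(MRSState.DEAD)] = 1.0
        np.testing.assert_array_equal(mat[int(MRSState.DEAD)], expected)


class TestRunCohort:
    def test_constant_occupancy_without_events(self):
        quiet = make_quiet_params(flat_q=0.0, p_rec=0.0)
        trace = run_cohort(quiet.short_term[1], quiet)
        for t in range(6):
            np.testing.assert_allclose(trace.at(t), quiet.short_term[1].probs)

    def test_all_dead_stays_dead(self, params):
        start = np.zeros(6)
        start[int(MRSState.DEAD)] = 1.0
        trace = run_cohort(MRSDistribution(start), params)
        for t in range(trace.n_cycles + 1):
            np.testing.assert_allclose(trace.at(t), start)

    def test_mass_conserved_each_cycle(self, params):
        for h in params.short_term:
            trace = run_cohort(params.short_term[h], params)
            np.testing.assert_allclose(
                trace.occupancy.sum(axis=1), np.ones(trace.n_cycles + 1), atol=1e-10
            )

    def test_dead_mass_monotone(self, params):
        for h in params.short_term:
            trace = run_cohort(params.short_term[h], params)
            dead = trace.occupancy[:, int(MRSState.DEAD)]
            assert np.all(np.diff(dead) >= -1e-15)

    def test_worse_start_never_more_survivors(self, params):
        """Shifting start mass toward severer states cannot add survivors."""
        better = params.short_term[1].probs
        worse = params.short_term[6].probs
        t_better = run_cohort(MRSDistribution(better), params)
        t_worse = run_cohort(MRSDistribution(worse), params)
        for t in range(6):
            alive_better = 1.0 - t_better.at(t)[int(MRSState.DEAD)]
            alive_worse = 1.0 - t_worse.at(t)[int(MRSState.DEAD)]
            assert alive_worse <= alive_better + 1e-12

    def test_matches_microsimulation(self, params):
        """Matrix propagation equals the individual-level oracle within 3 SE."""
        start = params.short_term[3].probs
        trace = run_cohort(MRSDistribution(start), params)
        n = 20_000
        micro = microsimulate(start, params, n_individuals=n, seed=99)
        se = np.sqrt(np.maximum(trace.occupancy * (1 - trace.occupancy), 1e-12) / n)
        assert np.all(np.abs(micro - trace.occupancy) <= 3 * se + 1e-9)

    def test_invalid_start_rejected(self, params):
        with pytest.raises(ValueError):
            run_cohort(np.array([0.5, 0, 0, 0, 0, 0]), params)
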