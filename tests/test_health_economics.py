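"""Discounting, cost anchoring, accrual, NMV/NMB identities and the
per-hour -> per-10-minute -> per-minute and QALY -> day conversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evtvalue.model_types import MRSState
from evtvalue.long_term_model import CohortTrace, run_cohort
from evtvalue.health_economics import (
    StratumOutcome,
    accrue,
    convert_time_unit,
    cost_for_cycle,
    discount_factor,
    nmb_between_strata,
    nmv,
    per_hour_median,
    qalys_to_disability_free_days,
    round_euro,
    summarize,
)
from conftest import make_quiet_params


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "rate, t, expected",
        [(0.04, 0, 1.0), (0.04, 1, 1 / 1.04), (0.015, 5, 1.015 ** -5), (0.0, 3, 1.0)],
    )
    def test_closed_form(self, rate, t, expected):
        assert discount_factor(rate, t) == pytest.approx(expected, rel=1e-12)


class TestCostForCycle:
    def test_dead_costs_nothing(self, params):
        for t in range(1, 6):
            assert cost_for_cycle(MRSState.DEAD, t, params.econ) == 0.0

    def test_year3_anchor_exact_without_adjustments(self, quiet_params):
        econ = quiet_params.econ  # inflation 0, price factor 1
        assert cost_for_cycle(MRSState.MRS3, 3, econ) == econ.cost_year3plus[MRSState.MRS3]
        assert cost_for_cycle(MRSState.MRS3, 5, econ) == econ.cost_year3plus[MRSState.MRS3]

    def test_zero_rehab_state_only_differs_by_inflation(self, params):
        """If year-3+ equals year-2 cost, t=2 vs t=3 differ by one inflation step."""
        econ = params.econ
        s = MRSState.MRS2
        econ_eq = type(econ)(
            utility=econ.utility,
            cost_year1=econ.cost_year1,
            cost_year2=econ.cost_year2,
            cost_year3plus=econ.cost_year2.copy(),  # no rehabilitation component
            wtp=econ.wtp,
            discount_qaly=econ.discount_qaly,
            discount_cost=econ.discount_cost,
            inflation=econ.inflation,
            price_year_factor=econ.price_year_factor,
        )
        ratio = cost_for_cycle(s, 3, econ_eq) / cost_for_cycle(s, 2, econ_eq)
        assert ratio == pytest.approx(1.0 + econ.inflation, rel=1e-12)

    def test_year1_includes_price_and_inflation_factors(self, params):
        econ = params.econ
        s = MRSState.MRS4
        expected = econ.cost_year1[s] * econ.price_year_factor * (1 + econ.inflation)
        assert cost_for_cycle(s, 1, econ) == pytest.approx(expected, rel=1e-12)


class TestAccrue:
    def test_all_dead_accrues_nothing(self, params):
        occ = np.zeros((6, 6))
        occ[:, int(MRSState.DEAD)] = 1.0
        q, c = accrue(CohortTrace(occ), params.econ)
        assert q == 0.0 and c == 0.0

    def test_undiscounted_single_state_closed_form(self):
        quiet = make_quiet_params(start=(0, 0, 1.0, 0, 0, 0))
        trace = run_cohort(quiet.short_term[1], quiet)
        q, c = accrue(trace, quiet.econ)
        u = quiet.econ.utility[MRSState.MRS3]
        assert q == pytest.approx(5 * u, rel=1e-12)
        expected_cost = (
            quiet.econ.cost_year1[MRSState.MRS3]
            + quiet.econ.cost_year2[MRSState.MRS3]
            + 3 * quiet.econ.cost_year3plus[MRSState.MRS3]
        )
        assert c == pytest.approx(expected_cost, rel=1e-12)

    def test_optional_cycle0_accrual_adds_quarter_year_utility(self):
        quiet = make_quiet_params(start=(0, 0, 1.0, 0, 0, 0))
        trace = run_cohort(quiet.short_term[1], quiet)
        q_off, c_off = accrue(trace, quiet.econ)
        q_on, c_on = accrue(trace, quiet.econ, include_cycle0=True)
        u = quiet.econ.utility[MRSState.MRS3]
        assert q_on - q_off == pytest.approx(90.0 / 365.0 * u, rel=1e-12)
        assert c_on == c_off

    def test_constant_occupancy_geometric_series(self, quiet_params):
        """Discounted accrual equals the geometric closed form."""
        quiet = quiet_params
        quiet.econ.discount_qaly = 0.015
        quiet.econ.discount_cost = 0.04
        quiet.econ.inflation = 0.017
        quiet.econ.price_year_factor = 1.1
        trace = run_cohort(quiet.short_term[1], quiet)  # no events: constant rows
        q, c = accrue(trace, quiet.econ)
        occ = quiet.short_term[1].probs
        u_bar = float(occ @ quiet.econ.utility)
        expected_q = u_bar * sum(1.015 ** -t for t in range(1, 6))
        assert q == pytest.approx(expected_q, abs=1e-9)
        expected_c = 0.0
        for t in range(1, 6):
            cat = quiet.econ.cost_year1 if t == 1 else (
                quiet.econ.cost_year2 if t == 2 else quiet.econ.cost_year3plus
            )
            nominal = float(occ @ cat) * 1.1 * 1.017 ** t
            expected_c += nominal * 1.04 ** -t
        assert c == pytest.approx(expected_c, abs=1e-9)


class TestNMV:
    @pytest.mark.parametrize(
        "q, c, wtp, expected",
        [(1.0, 0.0, 80_000, 80_000), (0.0, 100.0, 80_000, -100.0), (0.5, 10_000, 80_000, 30_000)],
    )
    def test_arithmetic_identity(self, q, c, wtp, expected):
        assert nmv(q, c, wtp) == pytest.approx(expected)

    def test_identity_holds_for_every_stratum(self, params):
        summary = summarize(params)
        for s in summary.strata:
            assert abs(s.nmv - (s.qalys * params.econ.wtp - s.costs)) < 1e-6


class TestNMB:
    def test_identical_strata_give_zero(self):
        a = StratumOutcome(1, 1.5, 1000.0, 119_000.0)
        b = StratumOutcome(2, 1.5, 1000.0, 119_000.0)
        assert nmb_between_strata(a, b, 80_000) == (0.0, 0.0, 0.0)

    def test_arithmetic(self):
        a = StratumOutcome(1, 1.724, 1000.0, 0.0)
        b = StratumOutcome(2, 1.5, 3433.0, 0.0)
        d_qaly, d_cost, benefit = nmb_between_strata(a, b, 80_000)
        assert d_qaly == pytest.approx(0.224)
        assert d_cost == pytest.approx(-2433.0)
        assert benefit == pytest.approx(20_353.0, abs=0.1)

    def test_sign_follows_qaly_when_costs_equal(self):
        a = StratumOutcome(1, 1.9, 500.0, 0.0)
        b = StratumOutcome(2, 1.8, 500.0, 0.0)
        assert nmb_between_strata(a, b, 80_000)[2] > 0

    def test_invariant_to_common_nmv_shift(self, params):
        summary = summarize(params)
        a, b = summary.strata[0], summary.strata[1]
        _, _, benefit = nmb_between_strata(a, b, params.econ.wtp)
        shifted_a = StratumOutcome(a.hour, a.qalys + 1.0, a.costs + 80_000.0, a.nmv)
        shifted_b = StratumOutcome(b.hour, b.qalys + 1.0, b.costs + 80_000.0, b.nmv)
        _, _, shifted = nmb_between_strata(shifted_a, shifted_b, params.econ.wtp)
        assert shifted == pytest.approx(benefit, abs=1e-6)


class TestPerHourMedian:
    def test_middle_order_statistic(self):
        assert per_hour_median([1, 2, 3, 4, 5]) == 3
        assert per_hour_median([23799, 14052, 30143, 13125, 10560]) == 14052
        assert per_hour_median([7.0] * 5) == 7.0

    @pytest.mark.parametrize("values", [[1, 2, 3], [1, 2, 3, 4, 5, 6], []])
    def test_requires_exactly_five(self, values):
        with pytest.raises(ValueError):
            per_hour_median(values)


class TestTimeUnitConversion:
    @pytest.mark.parametrize(
        "per_hour, minutes, expected",
        [(18_513, 1, 309), (14_519, 1, 242), (-2_433, 1, -41), (0, 1, 0), (18_513, 10, 3_086)],
    )
    def test_euro_rounding_half_away_from_zero(self, per_hour, minutes, expected):
        assert convert_time_unit(per_hour, minutes, euro=True) == expected

    def test_plain_conversion_is_exact_division(self):
        assert convert_time_unit(120.0, 10) == pytest.approx(20.0)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(-1e6, 1e6, allow_nan=False),
        b=st.floats(-1e6, 1e6, allow_nan=False),
        minutes=st.sampled_from([1, 10]),
    )
    def test_linearity_before_rounding(self, a, b, minutes):
        assert convert_time_unit(a + b, minutes) == pytest.approx(
            convert_time_unit(a, minutes) + convert_time_unit(b, minutes), abs=1e-6
        )

    def test_rejects_other_units(self):
        with pytest.raises(ValueError):
            convert_time_unit(100.0, 30)

    def test_round_euro_half_away_from_zero(self):
        assert round_euro(0.5) == 1.0
        assert round_euro(-0.5) == -1.0
        assert round_euro(241.98) == 242.0


class TestDisabilityFreeDays:
    @pytest.mark.parametrize(
        "per_hour_qalys, expected", [(0.224, 1.4), (0.22, 1.3), (0.0, 0.0)]
    )
    def test_per_minute_day_value(self, per_hour_qalys, expected):
        assert qalys_to_disability_free_days(per_hour_qalys) == expected

    def test_per_10_minutes(self):
        assert qalys_to_disability_free_days(0.224, minutes=10) == pytest.approx(13.6)


class TestSummarize:
    def test_nmv_decreases_with_delay(self, params):
        summary = summarize(params)
        nmvs = [s.nmv for s in summary.strata]
        assert np.all(np.diff(nmvs) < 0)

    def test_pair_and_converted_tables_consistent(self, params):
        summary = summarize(params)
        assert len(summary.pairs) == 5
        per_min = summary.converted.set_index("unit").loc["per_minute"]
        assert per_min["nmb_eur"] == convert_time_unit(
            summary.per_hour["nmb_eur"], 1, euro=True
        )
        assert per_min["d_qaly"] == pytest.approx(summary.per_hour["d_qaly"] / 60.0)
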