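"""Discounted QALYs, costs, Net Monetary Value / Benefit and unit conversions.

Per delay stratum the cohort trace is converted into cumulative discounted
QALYs (effects discounted at 1.5%/year) and cumulative discounted,
inflation-adjusted costs (discounted at 4%/year). Net Monetary Value is
NMV = QALYs * WTP - costs at a willingness to pay of EUR 80,000 per QALY;
Net Monetary Benefit is the NMV difference between adjacent delay hours.
A per-hour headline value is the median of the five adjacent-hour
differences; per-10-minute and per-minute values are linear rescalings
(assuming constant differences between hours), with euro amounts rounded
half away from zero to whole euros and day-valued outputs to one decimal.
A QALY is expressed as 365 disability-free life days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_types import (
    COST_CATEGORIES,
    HOURS,
    EconomicInputs,
    MRSState,
    ParameterSet,
)
from .long_term_model import CohortTrace, run_cohort

__all__ = [
    "discount_factor",
    "cost_for_cycle",
    "accrue",
    "nmv",
    "nmb_between_strata",
    "per_hour_median",
    "convert_time_unit",
    "round_euro",
    "qalys_to_disability_free_days",
    "StratumOutcome",
    "OutcomeSummary",
    "simulate_strata",
    "summarize",
]


def discount_factor(rate: float, t: int) -> float:
    """Present-value multiplier ``(1 + rate)**(-t)`` for year ``t``."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + rate) ** (-t)


def cost_for_cycle(state: MRSState, t: int, econ: EconomicInputs) -> float:
    """Nominal (pre-discount) annual cost of ``state`` during year ``t``.

    Year 1 uses the first-year cost anchor (90-day mRS reference), year 2
    the second-year anchor (18-month mRS reference), and years 3+ the
    second-year costs with rehabilitation removed. Source-year prices are
    translated to the simulation start year with ``price_year_factor`` and
    projected forward with ``(1 + inflation)**t``. DEAD costs nothing.
    """
    if state is MRSState.DEAD:
        return 0.0
    if t < 1:
        raise ValueError("cost accrual starts in year 1")
    if t == 1:
        base = econ.cost_year1[state]
    elif t == 2:
        base = econ.cost_year2[state]
    else:
        base = econ.cost_year3plus[state]
    return float(base * econ.price_year_factor * (1.0 + econ.inflation) ** t)


def accrue(
    trace: CohortTrace, econ: EconomicInputs, include_cycle0: bool = False
) -> tuple[float, float]:
    """Cumulative discounted (QALYs, costs) over years 1..horizon.

    By default the 90-day cycle 0 accrues nothing: acute-phase treatment
    costs enter through the first-year cost anchor, and year-1 accrual
    uses the cycle-1 occupancy. With ``include_cycle0`` the initial
    90-day period additionally accrues utility (no cost: the year-1
    anchor already carries the acute admission) for 90/365 of a year,
    undiscounted.
    """
    qalys = 0.0
    costs = 0.0
    if include_cycle0:
        qalys += (90.0 / 365.0) * float(trace.at(0) @ econ.utility)
    for t in range(1, trace.n_cycles + 1):
        occ = trace.at(t)
        qalys += discount_factor(econ.discount_qaly, t) * float(occ @ econ.utility)
        nominal = sum(occ[s] * cost_for_cycle(s, t, econ) for s in MRSState)
        costs += discount_factor(econ.discount_cost, t) * nominal
    return qalys, costs


def nmv(qalys: float, costs: float, wtp: float) -> float:
    """Net Monetary Value: ``qalys * wtp - costs`` (EUR)."""
    if not wtp > 0:
        raise ValueError("willingness to pay must be > 0")
    return qalys * wtp - costs


@dataclass
class StratumOutcome:
    """Cumulative discounted outcomes for one delay-hour stratum."""

    hour: int
    qalys: float
    costs: float
    nmv: float


def nmb_between_strata(
    earlier: StratumOutcome, later: StratumOutcome, wtp: float
) -> tuple[float, float, float]:
    """(dQALY, dCost, NMB) gained by treating in the earlier hour.

    Each difference is earlier-hour value minus later-hour value, so a
    positive NMB means faster treatment is worth money at the given WTP.
    """
    d_qaly = earlier.qalys - later.qalys
    d_cost = earlier.costs - later.costs
    return d_qaly, d_cost, d_qaly * wtp - d_cost


def per_hour_median(differences) -> float:
    """Median of the five adjacent-hour differences (the per-hour headline)."""
    vals = [float(v) for v in differences]
    if len(vals) != 5:
        raise ValueError(f"expected the 5 adjacent-hour differences, got {len(vals)}")
    return float(np.median(vals))


def round_euro(value: float) -> float:
    """Round to the nearest whole euro, halves away from zero."""
    return float(math.floor(abs(value) + 0.5) * (1 if value >= 0 else -1))


def convert_time_unit(per_hour_value: float, minutes: int, euro: bool = False) -> float:
    """Rescale a per-hour value to per ``minutes`` (1 or 10) of faster EVT.

    Assumes constant differences between hours (linear interpolation within
    the hour). Euro amounts are additionally rounded to whole euros.
    """
    if minutes not in (1, 10):
        raise ValueError("minutes must be 1 or 10")
    value = per_hour_value * minutes / 60.0
    return round_euro(value) if euro else value


def qalys_to_disability_free_days(per_hour_qalys: float, minutes: int = 1) -> float:
    """Disability-free life days gained per ``minutes`` of faster EVT.

    One QALY equals 365 days in perfect health; the per-hour QALY gain is
    rescaled to the requested time unit and reported at one decimal.
    """
    if minutes not in (1, 10):
        raise ValueError("minutes must be 1 or 10")
    return round(per_hour_qalys * 365.0 * minutes / 60.0, 1)


@dataclass
class OutcomeSummary:
    """Baseline per-stratum, per-pair and per-time-unit outcomes."""

    strata: list[StratumOutcome]
    pairs: pd.DataFrame  # rows = adjacent hour pairs: d_qaly, d_cost, nmb
    per_hour: dict[str, float]  # median-of-five d_qaly, d_cost, nmb
    converted: pd.DataFrame  # rows = per_hour / per_10min / per_minute
    wtp: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hour": [s.hour for s in self.strata],
                "qalys_discounted": [s.qalys for s in self.strata],
                "costs_discounted_eur": [s.costs for s in self.strata],
                "nmv_eur": [s.nmv for s in self.strata],
            }
        )


def simulate_strata(params: ParameterSet, age_offset: int = 0) -> list[StratumOutcome]:
    """Run the long-term model and economic accrual for every delay hour."""
    out = []
    for h in HOURS:
        trace = run_cohort(params.short_term[h], params, age_offset=age_offset)
        q, c = accrue(trace, params.econ)
        out.append(StratumOutcome(hour=h, qalys=q, costs=c, nmv=nmv(q, c, params.econ.wtp)))
    return out


def summarize(params: ParameterSet, age_offset: int = 0) -> OutcomeSummary:
    """Full baseline outcome table for one parameter set.

    Computes per-stratum cumulative discounted QALYs, costs and NMV, the
    five adjacent-hour differences, their medians (the per-hour values),
    and the per-10-minute / per-minute conversions.
    """
    strata = simulate_strata(params, age_offset=age_offset)
    wtp = params.econ.wtp
    rows = []
    for earlier, later in zip(strata[:-1], strata[1:]):
        d_qaly, d_cost, benefit = nmb_between_strata(earlier, later, wtp)
        rows.append(
            {
                "pair": f"hour{earlier.hour}-hour{later.hour}",
                "d_qaly": d_qaly,
                "d_cost_eur": d_cost,
                "nmb_eur": benefit,
            }
        )
    pairs = pd.DataFrame(rows)
    per_hour = {
        "d_qaly": per_hour_median(pairs["d_qaly"]),
        "d_cost_eur": per_hour_median(pairs["d_cost_eur"]),
        "nmb_eur": per_hour_median(pairs["nmb_eur"]),
    }
    conv_rows = [
        {
            "unit": "per_hour",
            "d_cost_eur": round_euro(per_hour["d_cost_eur"]),
            "d_qaly": per_hour["d_qaly"],
            "disability_free_days": round(per_hour["d_qaly"] * 365.0, 1),
            "nmb_eur": round_euro(per_hour["nmb_eur"]),
        }
    ]
    for minutes, label in ((10, "per_10min"), (1, "per_minute")):
        conv_rows.append(
            {
                "unit": label,
                "d_cost_eur": convert_time_unit(per_hour["d_cost_eur"], minutes, euro=True),
                "d_qaly": per_hour["d_qaly"] * minutes / 60.0,
                "disability_free_days": qalys_to_disability_free_days(
                    per_hour["d_qaly"], minutes
                ),
                "nmb_eur": convert_time_unit(per_hour["nmb_eur"], minutes, euro=True),
            }
        )
    converted = pd.DataFrame(conv_rows)
    return OutcomeSummary(
        strata=strata, pairs=pairs, per_hour=per_hour, converted=converted, wtp=wtp
    )
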