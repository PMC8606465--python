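"""Annual-cycle Markov engine for the 5-year follow-up after stroke.

Cycle 0 holds the 90-day post-treatment mRS distribution produced by the
short-term model; no long-term transition happens within the first 90 days.
Each subsequent annual cycle t = 1..horizon applies, per living state:

1. all-cause mortality: the sex-mixed background annual death probability
   q_mix at the cohort's attained age, combined with the state- and
   year-specific excess-mortality hazard ratio on the cumulative-hazard
   scale, p_die = 1 - (1 - q_mix)**hr;
2. stroke recurrence among survivors: with probability p_rec(t) the patient
   has a recurrent stroke and moves to a state drawn from the control-arm
   90-day distribution truncated to states at least as severe as the
   current one and renormalized (death after recurrence is excluded; the
   hazard ratios already carry stroke-related mortality).

mRS can therefore only stay equal or deteriorate: there is no spontaneous
improvement, and DEAD is absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_types import (
    LIVING_STATES,
    N_STATES,
    LifeTable,
    MortalityHazardRatios,
    MRSDistribution,
    MRSState,
    ParameterSet,
)

__all__ = [
    "CohortTrace",
    "annual_death_prob",
    "recurrence_redistribution",
    "build_transition_matrix",
    "run_cohort",
]


@dataclass
class CohortTrace:
    """State occupancy per cycle: ``occupancy[t, s]`` for t = 0..horizon.

    Row 0 is the 90-day post-treatment distribution; each row sums to 1 and
    the DEAD column is non-decreasing in t.
    """

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.occupancy, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != N_STATES:
            raise ValueError(f"occupancy must be (cycles+1, {N_STATES}), got {arr.shape}")
        self.occupancy = arr

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def at(self, cycle: int) -> np.ndarray:
        return self.occupancy[cycle]


def mixed_background_q(age: int, sex_mix: float, life_table: LifeTable) -> float:
    """Sex-mixed annual background death probability at ``age``."""
    return sex_mix * life_table.q(age, "M") + (1.0 - sex_mix) * life_table.q(age, "F")


def annual_death_prob(
    age: int,
    sex_mix: float,
    state: MRSState,
    year_since_stroke: int,
    life_table: LifeTable,
    hazards: MortalityHazardRatios,
) -> float:
    """All-cause annual death probability for a living state.

    The background probability is converted to a cumulative hazard,
    multiplied by the hazard ratio and converted back:
    ``p = 1 - (1 - q_mix)**hr``, clamped to [0, 1]. For q_mix = 1 the
    result is 1 for any finite positive hazard ratio.
    """
    if state is MRSState.DEAD:
        raise ValueError("annual_death_prob is defined for living states only")
    hr = hazards.hr(state, year_since_stroke)
    if hr <= 0:
        raise ValueError(f"hazard ratio must be > 0, got {hr}")
    q_mix = mixed_background_q(age, sex_mix, life_table)
    if q_mix >= 1.0:
        return 1.0
    p = 1.0 - (1.0 - q_mix) ** hr
    return float(min(max(p, 0.0), 1.0))


def recurrence_redistribution(current: MRSState, base_dist: np.ndarray) -> np.ndarray:
    """Post-recurrence state distribution over the six states.

    ``base_dist`` is the control-arm non-fatal 90-day distribution over the
    five living states. Mass at states less severe than ``current`` is
    dropped (a recurrent stroke cannot improve disability) and the rest is
    renormalized; DEAD receives no mass.
    """
    if current is MRSState.DEAD:
        raise ValueError("no recurrence from the DEAD state")
    base = np.asarray(base_dist, dtype=float)
    if base.shape != (len(LIVING_STATES),):
        raise ValueError(f"base_dist must cover the {len(LIVING_STATES)} living states")
    trunc = base.copy()
    trunc[: int(current)] = 0.0
    total = trunc.sum()
    if total <= 0:
        raise ValueError(
            f"base_dist has zero mass at or above {current.name}; no valid recurrence outcome"
        )
    out = np.zeros(N_STATES)
    out[: len(LIVING_STATES)] = trunc / total
    return out


def build_transition_matrix(
    t: int, params: ParameterSet, age_offset: int = 0
) -> np.ndarray:
    """Row-stochastic 6x6 transition matrix for year ``t`` (1..horizon).

    Death is resolved first; recurrence applies to survivors only, so the
    two channels never double-count stroke mortality. ``age_offset`` shifts
    the cohort age (used by the one-way sensitivity analysis, which varies
    age in the long-term model only).
    """
    if not 1 <= t <= params.cohort.horizon_years:
        raise ValueError(f"cycle {t} outside 1..{params.cohort.horizon_years}")
    age = params.cohort.start_age + age_offset + (t - 1)
    hr_year = min(t, 5)  # hazard-ratio table covers 5 years since stroke
    p_rec = float(params.recurrence.p_rec[min(t, 5) - 1])
    mat = np.zeros((N_STATES, N_STATES))
    for s in LIVING_STATES:
        p_die = annual_death_prob(
            age, params.cohort.sex_mix, s, hr_year, params.life_table, params.hazards
        )
        survive = 1.0 - p_die
        row = np.zeros(N_STATES)
        row[s] += survive * (1.0 - p_rec)
        if p_rec > 0:
            row += survive * p_rec * recurrence_redistribution(s, params.recurrence.base_dist)
        row[MRSState.DEAD] = p_die
        mat[s] = row
    mat[MRSState.DEAD, MRSState.DEAD] = 1.0
    return mat


def run_cohort(
    start: MRSDistribution | np.ndarray, params: ParameterSet, age_offset: int = 0
) -> CohortTrace:
    """Propagate the 90-day distribution through the annual Markov model."""
    vec = start.probs if isinstance(start, MRSDistribution) else np.asarray(start, dtype=float)
    if abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError(f"start distribution sums to {vec.sum():.12g}, not 1")
    horizon = params.cohort.horizon_years
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0] = vec
    for t in range(1, horizon + 1):
        occ[t] = occ[t - 1] @ build_transition_matrix(t, params, age_offset=age_offset)
    return CohortTrace(occ)
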