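"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the microsimulation
samples individual event sequences from the component probabilities
(death, recurrence, post-recurrence redistribution) instead of building
or multiplying transition matrices, and the truncation oracle recomputes
the post-recurrence distribution by brute force.
"""

import numpy as np

from evtvalue.model_types import LIVING_STATES, N_STATES, MRSState, ParameterSet
from evtvalue.long_term_model import annual_death_prob

DEAD = int(MRSState.DEAD)


def brute_force_redistribution(current: int, base_dist: np.ndarray) -> np.ndarray:
    """Truncate-and-normalize by explicit enumeration over target states."""
    masses = []
    for target in range(len(LIVING_STATES)):
        masses.append(base_dist[target] if target >= current else 0.0)
    total = sum(masses)
    out = np.zeros(N_STATES)
    for target, m in enumerate(masses):
        out[target] = m / total
    return out


def microsimulate(
    start: np.ndarray, params: ParameterSet, n_individuals: int, seed: int
) -> np.ndarray:
    """Individual-level simulation of the same transition law.

    Each simulated patient starts in a state drawn from ``start`` and per
    year first faces the state/age-specific death probability, then (if
    alive) the recurrence probability with the truncated post-recurrence
    redistribution. Returns occupancy fractions with shape
    (horizon+1, 6).
    """
    rng = np.random.default_rng(seed)
    horizon = params.cohort.horizon_years
    states = rng.choice(N_STATES, size=n_individuals, p=np.asarray(start, dtype=float))
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0] = np.bincount(states, minlength=N_STATES) / n_individuals
    for t in range(1, horizon + 1):
        age = params.cohort.start_age + (t - 1)
        p_rec = params.recurrence.p_rec[min(t, 5) - 1]
        for s in LIVING_STATES:
            idx = np.flatnonzero(states == int(s))
            if idx.size == 0:
                continue
            p_die = annual_death_prob(
                age, params.cohort.sex_mix, s, min(t, 5), params.life_table, params.hazards
            )
            dies = rng.random(idx.size) < p_die
            states[idx[dies]] = DEAD
            alive = idx[~dies]
            recurs = alive[rng.random(alive.size) < p_rec]
            if recurs.size:
                redist = brute_force_redistribution(int(s), params.recurrence.base_dist)
                states[recurs] = rng.choice(N_STATES, size=recurs.size, p=redist)
        occ[t] = np.bincount(states, minlength=N_STATES) / n_individuals
    return occ
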