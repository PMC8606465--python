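import numpy as np
import pytest

from evtvalue.model_types import (
    CohortSpec,
    EconomicInputs,
    LifeTable,
    MortalityHazardRatios,
    MRSDistribution,
    ParameterSet,
    RecurrenceModel,
)
from evtvalue.synthetic_data import SyntheticConfig, gen_parameter_set


@pytest.fixture(scope="session")
def config() -> SyntheticConfig:
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def params(config) -> ParameterSet:
    return gen_parameter_set(config)


def make_quiet_params(
    utility=(0.85, 0.71, 0.52, 0.28, -0.05, 0.0),
    p_rec=0.0,
    flat_q=0.0,
    hr=1.0,
    start=(0.3, 0.2, 0.2, 0.15, 0.15, 0.0),
) -> ParameterSet:
    """Hand-built parameter set with controllable mortality/recurrence.

    ``flat_q`` is an age-independent background death probability and
    ``hr`` a single hazard ratio for every state and year; with both at
    their defaults the cohort never moves, which gives closed-form
    accruals.
    """
    ages = 121
    lt = LifeTable(
        qx={"M": np.full(ages, flat_q), "F": np.full(ages, flat_q)},
        min_age=0,
    )
    start_dist = MRSDistribution(np.asarray(start, dtype=float))
    return ParameterSet(
        short_term={h: start_dist for h in range(1, 7)},
        life_table=lt,
        hazards=MortalityHazardRatios(np.full((5, 5), hr)),
        recurrence=RecurrenceModel(
            p_rec=np.full(5, p_rec),
            base_dist=np.array([0.15, 0.18, 0.32, 0.28, 0.07]),
        ),
        econ=EconomicInputs(
            utility=np.asarray(utility, dtype=float),
            cost_year1=np.array([9000.0, 16000.0, 28000.0, 45000.0, 60000.0, 0.0]),
            cost_year2=np.array([2500.0, 5500.0, 13000.0, 28000.0, 42000.0, 0.0]),
            cost_year3plus=np.array([2000.0, 4500.0, 11000.0, 25000.0, 38000.0, 0.0]),
            wtp=80_000.0,
            discount_qaly=0.0,
            discount_cost=0.0,
            inflation=0.0,
            price_year_factor=1.0,
        ),
        cohort=CohortSpec(start_age=69, sex_mix=0.5, horizon_years=5),
    )


@pytest.fixture()
def quiet_params() -> ParameterSet:
    return make_quiet_params()
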