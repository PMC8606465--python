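"""Domain types and the full model parameterization.

The model tracks a stroke cohort over six health states defined by the
modified Rankin Scale (mRS): mRS 0 and 1 are merged into a single state
(sample sizes at the favourable end are otherwise too small to estimate
reliably), mRS 2-5 are individual states, and death (mRS 6) is absorbing.
Severity is ordinal: MRS0_1 < MRS2 < ... < MRS5 < DEAD.

A :class:`ParameterSet` bundles everything a simulation needs:

* per treatment-delay-hour 90-day mRS distributions (the short-term model
  output, optionally with the multinomial count vectors behind them),
* a background life table (annual death probability by age and sex),
* excess-mortality hazard ratios by mRS state and year since stroke,
* an annual stroke-recurrence model with the post-recurrence mRS
  distribution,
* economic inputs (annual utilities, annual costs by year-category,
  willingness to pay, discount / inflation rates),
* the cohort definition (start age, sex mix, horizon), and
* per-parameter uncertainty annotations used by the probabilistic
  sensitivity analysis.

Parameter sets serialize to JSON (canonical) and YAML (convenience) and
round-trip exactly.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "MRSState",
    "LIVING_STATES",
    "N_STATES",
    "HOURS",
    "MRSDistribution",
    "LifeTable",
    "MortalityHazardRatios",
    "RecurrenceModel",
    "EconomicInputs",
    "CohortSpec",
    "PSAAnnotations",
    "ParameterSet",
    "RegistryRecord",
    "validate_parameter_set",
]


class MRSState(enum.IntEnum):
    """Markov state on the merged modified Rankin Scale.

    The integer value doubles as the index into every 6-vector and into
    transition-matrix rows/columns; the order is the ordinal severity order.
    """

    MRS0_1 = 0
    MRS2 = 1
    MRS3 = 2
    MRS4 = 3
    MRS5 = 4
    DEAD = 5


#: The five non-absorbing (alive) states in severity order.
LIVING_STATES: tuple[MRSState, ...] = tuple(s for s in MRSState if s is not MRSState.DEAD)

N_STATES: int = len(MRSState)

#: Onset-to-groin-puncture delay strata: hour h covers minutes (60*(h-1), 60*h].
HOURS: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

SEXES: tuple[str, str] = ("M", "F")

_SUM_TOL = 1e-12


def _as_vector(values, n: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
    return arr


@dataclass(frozen=True)
class MRSDistribution:
    """Probability vector over the six Markov states.

    ``probs[MRSState.MRS0_1] ... probs[MRSState.DEAD]``; must be
    non-negative and sum to 1 (within 1e-12) to be valid.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", _as_vector(self.probs, N_STATES, "probs"))

    @classmethod
    def from_mapping(cls, mapping: Mapping[MRSState | str, float]) -> "MRSDistribution":
        vec = np.zeros(N_STATES)
        for key, p in mapping.items():
            state = MRSState[key] if isinstance(key, str) else MRSState(key)
            vec[state] = float(p)
        return cls(vec)

    def as_mapping(self) -> dict[str, float]:
        return {s.name: float(self.probs[s]) for s in MRSState}

    def __getitem__(self, state: MRSState) -> float:
        return float(self.probs[MRSState(state)])

    def is_valid(self, tol: float = _SUM_TOL) -> bool:
        return bool(np.all(self.probs >= 0) and abs(self.probs.sum() - 1.0) <= tol)

    def violations(self, context: str, tol: float = _SUM_TOL) -> list[str]:
        out = []
        if np.any(self.probs < 0):
            neg = [s.name for s in MRSState if self.probs[s] < 0]
            out.append(f"{context}: negative probability for {', '.join(neg)}")
        if abs(self.probs.sum() - 1.0) > tol:
            out.append(f"{context}: probabilities sum to {self.probs.sum():.12g}, not 1")
        return out


@dataclass
class LifeTable:
    """Annual death probability by integer age and sex.

    ``qx[sex]`` is indexed by age starting at ``min_age``;
    ``start_calendar_year`` records the first projection year of the table
    (metadata only; mortality is looked up by attained age).
    """

    qx: dict[str, np.ndarray]
    min_age: int = 0
    start_calendar_year: int = 2021

    def __post_init__(self) -> None:
        self.qx = {sex: np.asarray(v, dtype=float) for sex, v in self.qx.items()}
        lengths = {len(v) for v in self.qx.values()}
        if set(self.qx) != set(SEXES):
            raise ValueError(f"life table must cover sexes {SEXES}, got {sorted(self.qx)}")
        if len(lengths) != 1:
            raise ValueError("life-table columns must have equal length")

    @property
    def max_age(self) -> int:
        return self.min_age + len(self.qx["M"]) - 1

    def q(self, age: int, sex: str) -> float:
        """Annual probability of death at integer ``age`` for ``sex``."""
        idx = int(age) - self.min_age
        if not 0 <= idx < len(self.qx[sex]):
            raise ValueError(f"age {age} outside life-table range [{self.min_age}, {self.max_age}]")
        return float(self.qx[sex][idx])

    def violations(self) -> list[str]:
        out = []
        for sex, col in self.qx.items():
            if np.any(col < 0) or np.any(col > 1):
                out.append(f"life_table[{sex}]: q outside [0, 1]")
        return out


@dataclass
class MortalityHazardRatios:
    """Excess all-cause mortality hazard ratios.

    ``table`` has shape (5 living states, 5 years since stroke); entry
    ``table[state, t-1]`` multiplies the background cumulative hazard in
    year ``t`` for a patient in ``state``.
    """

    table: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.table, dtype=float)
        if arr.shape != (len(LIVING_STATES), 5):
            raise ValueError(f"hazard-ratio table must be 5x5, got {arr.shape}")
        self.table = arr

    def hr(self, state: MRSState, year_since_stroke: int) -> float:
        if state is MRSState.DEAD:
            raise ValueError("no hazard ratio for the absorbing DEAD state")
        if not 1 <= year_since_stroke <= 5:
            raise ValueError(f"year_since_stroke must be in 1..5, got {year_since_stroke}")
        return float(self.table[MRSState(state), year_since_stroke - 1])

    def violations(self) -> list[str]:
        out = []
        if np.any(self.table <= 0):
            out.append("hazards: hazard ratio must be > 0")
        return out


@dataclass
class RecurrenceModel:
    """Annual stroke-recurrence probabilities and the post-recurrence
    mRS distribution.

    ``p_rec[t-1]`` is the probability of a recurrent stroke in year ``t``
    (1..5) for a survivor. ``base_dist`` is the 90-day mRS distribution of
    an untreated (control) population *excluding death*, over the five
    living states; after a recurrence in state ``s`` it is truncated to
    states >= s and renormalized (death after recurrence is excluded to
    avoid double-counting stroke mortality, which the hazard ratios carry).
    ``base_counts``, when present, are the observation counts behind
    ``base_dist`` and drive its Dirichlet resampling in the PSA.
    """

    p_rec: np.ndarray
    base_dist: np.ndarray
    base_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p_rec = _as_vector(self.p_rec, 5, "p_rec")
        self.base_dist = _as_vector(self.base_dist, 5, "base_dist")
        if self.base_counts is not None:
            self.base_counts = _as_vector(self.base_counts, 5, "base_counts")

    def violations(self) -> list[str]:
        out = []
        if np.any(self.p_rec < 0) or np.any(self.p_rec > 1):
            out.append("recurrence.p_rec: probabilities must lie in [0, 1]")
        if np.any(self.base_dist < 0):
            out.append("recurrence.base_dist: negative probability")
        if abs(self.base_dist.sum() - 1.0) > _SUM_TOL:
            out.append(
                f"recurrence.base_dist: sums to {self.base_dist.sum():.12g} over living states, not 1"
            )
        return out


#: Cost year-categories: first year is anchored on 90-day mRS, the second on
#: 18-month mRS, and years three onward equal the second year without
#: rehabilitation costs.
COST_CATEGORIES: tuple[str, ...] = ("year1", "year2", "year3plus")


@dataclass
class EconomicInputs:
    """Utilities, costs and economic constants.

    * ``utility`` - annual QALY weight per state (DEAD must be 0); values
      below zero are allowed, for states perceived as worse than death.
    * ``cost_year1`` / ``cost_year2`` / ``cost_year3plus`` - annual
      healthcare cost (EUR, price-year of the source data) per state; DEAD
      must be 0, and year-3+ costs cannot exceed year-2 costs (they are the
      year-2 costs with rehabilitation removed).
    * ``wtp`` - willingness to pay per QALY (EUR).
    * ``discount_qaly`` / ``discount_cost`` - compounded annual discount
      rates (Dutch guideline: 1.5% effects, 4% costs).
    * ``inflation`` - annual rate used to project future costs.
    * ``price_year_factor`` - historical inflation multiplier translating
      source-data prices to the simulation start year.
    """

    utility: np.ndarray
    cost_year1: np.ndarray
    cost_year2: np.ndarray
    cost_year3plus: np.ndarray
    wtp: float = 80_000.0
    discount_qaly: float = 0.015
    discount_cost: float = 0.04
    inflation: float = 0.017
    price_year_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("utility", "cost_year1", "cost_year2", "cost_year3plus"):
            setattr(self, name, _as_vector(getattr(self, name), N_STATES, name))

    def cost_vector(self, category: str) -> np.ndarray:
        if category not in COST_CATEGORIES:
            raise ValueError(f"unknown cost category {category!r}")
        return getattr(self, f"cost_{category}")

    def violations(self) -> list[str]:
        out = []
        if not self.wtp > 0:
            out.append("econ.wtp: must be > 0")
        for name in ("discount_qaly", "discount_cost", "inflation"):
            rate = getattr(self, name)
            if not 0 <= rate < 1:
                out.append(f"econ.{name}: rate {rate} outside [0, 1)")
        if self.utility[MRSState.DEAD] != 0:
            out.append("econ.utility: DEAD state must have utility 0")
        for cat in COST_CATEGORIES:
            if self.cost_vector(cat)[MRSState.DEAD] != 0:
                out.append(f"econ.cost_{cat}: DEAD state must have cost 0")
            if np.any(self.cost_vector(cat)[:-1] < 0):
                out.append(f"econ.cost_{cat}: negative cost")
        if np.any(self.cost_year3plus > self.cost_year2 + 1e-9):
            bad = [s.name for s in LIVING_STATES if self.cost_year3plus[s] > self.cost_year2[s] + 1e-9]
            out.append(
                "econ.cost_year3plus: exceeds cost_year2 for " + ", ".join(bad)
                + " (year-3+ costs are year-2 costs minus rehabilitation)"
            )
        return out


@dataclass
class CohortSpec:
    """Simulated cohort: start age, sex mix and Markov horizon."""

    start_age: int = 69
    sex_mix: float = 0.5  # fraction male
    horizon_years: int = 5
    cycle_length_years: int = 1

    def violations(self) -> list[str]:
        out = []
        if not 0 <= self.sex_mix <= 1:
            out.append(f"cohort.sex_mix: {self.sex_mix} outside [0, 1]")
        if self.horizon_years < 1:
            out.append("cohort.horizon_years: must be >= 1")
        if self.cycle_length_years != 1:
            out.append("cohort.cycle_length_years: engine assumes annual cycles")
        return out


@dataclass
class PSAAnnotations:
    """Second-order uncertainty annotations per stochastic parameter.

    Families follow standard cost-effectiveness conventions:

    * mRS distributions (short-term per-hour and the recurrence base
      distribution) - Dirichlet on their count vectors; zero-count cells
      stay structurally zero,
    * utilities - Normal(mean, se), untruncated (negative draws allowed),
    * costs - Gamma, moment-matched to (mean, se),
    * hazard ratios - LogNormal(log mean, log-se),
    * recurrence probabilities - Beta, moment-matched to (mean, se).

    A standard error of 0 makes the parameter degenerate (always the
    baseline value).
    """

    utility_se: np.ndarray = field(default_factory=lambda: np.zeros(N_STATES))
    cost_se: dict[str, np.ndarray] = field(
        default_factory=lambda: {cat: np.zeros(N_STATES) for cat in COST_CATEGORIES}
    )
    hr_log_se: np.ndarray = field(default_factory=lambda: np.zeros((len(LIVING_STATES), 5)))
    recurrence_se: np.ndarray = field(default_factory=lambda: np.zeros(5))

    def __post_init__(self) -> None:
        self.utility_se = _as_vector(self.utility_se, N_STATES, "utility_se")
        self.cost_se = {
            cat: _as_vector(self.cost_se.get(cat, np.zeros(N_STATES)), N_STATES, f"cost_se[{cat}]")
            for cat in COST_CATEGORIES
        }
        self.hr_log_se = np.asarray(self.hr_log_se, dtype=float)
        self.recurrence_se = _as_vector(self.recurrence_se, 5, "recurrence_se")

    def violations(self) -> list[str]:
        out = []
        if np.any(self.utility_se < 0):
            out.append("psa.utility_se: negative standard error")
        for cat, se in self.cost_se.items():
            if np.any(se < 0):
                out.append(f"psa.cost_se[{cat}]: negative standard error")
        if np.any(self.hr_log_se < 0):
            out.append("psa.hr_log_se: negative log standard error")
        if np.any(self.recurrence_se < 0):
            out.append("psa.recurrence_se: negative standard error")
        return out


@dataclass
class ParameterSet:
    """Every input of the two-stage model.

    ``short_term`` maps delay hour (1..6) to the 90-day mRS distribution;
    ``short_term_counts`` optionally carries the multinomial counts those
    distributions were estimated from (needed for Dirichlet resampling in
    the PSA). ``prevalence`` holds the relative frequency of each delay
    hour in the source population, used for population-level weighting.
    """

    short_term: dict[int, MRSDistribution]
    life_table: LifeTable
    hazards: MortalityHazardRatios
    recurrence: RecurrenceModel
    econ: EconomicInputs
    cohort: CohortSpec
    psa: PSAAnnotations = field(default_factory=PSAAnnotations)
    short_term_counts: dict[int, np.ndarray] | None = None
    prevalence: np.ndarray | None = None  # one weight per delay hour

    def __post_init__(self) -> None:
        self.short_term = {int(h): d for h, d in self.short_term.items()}
        if self.short_term_counts is not None:
            self.short_term_counts = {
                int(h): _as_vector(v, N_STATES, f"short_term_counts[{h}]")
                for h, v in self.short_term_counts.items()
            }
        if self.prevalence is not None:
            self.prevalence = _as_vector(self.prevalence, len(HOURS), "prevalence")

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "short_term": {str(h): dist.as_mapping() for h, dist in sorted(self.short_term.items())},
            "life_table": {
                "min_age": self.life_table.min_age,
                "start_calendar_year": self.life_table.start_calendar_year,
                "qx": {sex: list(map(float, col)) for sex, col in self.life_table.qx.items()},
            },
            "hazards": {
                s.name: list(map(float, self.hazards.table[s])) for s in LIVING_STATES
            },
            "recurrence": {
                "p_rec": list(map(float, self.recurrence.p_rec)),
                "base_dist": {s.name: float(self.recurrence.base_dist[s]) for s in LIVING_STATES},
            },
            "econ": {
                "utility": {s.name: float(self.econ.utility[s]) for s in MRSState},
                "cost_year1": {s.name: float(self.econ.cost_year1[s]) for s in MRSState},
                "cost_year2": {s.name: float(self.econ.cost_year2[s]) for s in MRSState},
                "cost_year3plus": {s.name: float(self.econ.cost_year3plus[s]) for s in MRSState},
                "wtp": self.econ.wtp,
                "discount_qaly": self.econ.discount_qaly,
                "discount_cost": self.econ.discount_cost,
                "inflation": self.econ.inflation,
                "price_year_factor": self.econ.price_year_factor,
            },
            "cohort": {
                "start_age": self.cohort.start_age,
                "sex_mix": self.cohort.sex_mix,
                "horizon_years": self.cohort.horizon_years,
                "cycle_length_years": self.cohort.cycle_length_years,
            },
            "psa": {
                "utility_se": {s.name: float(self.psa.utility_se[s]) for s in MRSState},
                "cost_se": {
                    cat: {s.name: float(se[s]) for s in MRSState}
                    for cat, se in self.psa.cost_se.items()
                },
                "hr_log_se": {s.name: list(map(float, self.psa.hr_log_se[s])) for s in LIVING_STATES},
                "recurrence_se": list(map(float, self.psa.recurrence_se)),
            },
        }
        if self.recurrence.base_counts is not None:
            d["recurrence"]["base_counts"] = {
                s.name: float(self.recurrence.base_counts[s]) for s in LIVING_STATES
            }
        if self.short_term_counts is not None:
            d["short_term_counts"] = {
                str(h): {s.name: float(v[s]) for s in MRSState}
                for h, v in sorted(self.short_term_counts.items())
            }
        if self.prevalence is not None:
            d["prevalence"] = list(map(float, self.prevalence))
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        lt = d["life_table"]
        rec = d["recurrence"]
        econ = d["econ"]

        def state_vec(mapping: Mapping[str, float], states=MRSState) -> np.ndarray:
            return np.array([float(mapping[s.name]) for s in states])

        return cls(
            short_term={
                int(h): MRSDistribution.from_mapping(m) for h, m in d["short_term"].items()
            },
            life_table=LifeTable(
                qx={sex: np.array(col, dtype=float) for sex, col in lt["qx"].items()},
                min_age=int(lt["min_age"]),
                start_calendar_year=int(lt["start_calendar_year"]),
            ),
            hazards=MortalityHazardRatios(
                np.array([d["hazards"][s.name] for s in LIVING_STATES], dtype=float)
            ),
            recurrence=RecurrenceModel(
                p_rec=np.array(rec["p_rec"], dtype=float),
                base_dist=state_vec(rec["base_dist"], LIVING_STATES),
                base_counts=(
                    state_vec(rec["base_counts"], LIVING_STATES)
                    if "base_counts" in rec
                    else None
                ),
            ),
            econ=EconomicInputs(
                utility=state_vec(econ["utility"]),
                cost_year1=state_vec(econ["cost_year1"]),
                cost_year2=state_vec(econ["cost_year2"]),
                cost_year3plus=state_vec(econ["cost_year3plus"]),
                wtp=float(econ["wtp"]),
                discount_qaly=float(econ["discount_qaly"]),
                discount_cost=float(econ["discount_cost"]),
                inflation=float(econ["inflation"]),
                price_year_factor=float(econ["price_year_factor"]),
            ),
            cohort=CohortSpec(
                start_age=int(d["cohort"]["start_age"]),
                sex_mix=float(d["cohort"]["sex_mix"]),
                horizon_years=int(d["cohort"]["horizon_years"]),
                cycle_length_years=int(d["cohort"]["cycle_length_years"]),
            ),
            psa=PSAAnnotations(
                utility_se=state_vec(d["psa"]["utility_se"]),
                cost_se={
                    cat: state_vec(d["psa"]["cost_se"][cat]) for cat in COST_CATEGORIES
                },
                hr_log_se=np.array(
                    [d["psa"]["hr_log_se"][s.name] for s in LIVING_STATES], dtype=float
                ),
                recurrence_se=np.array(d["psa"]["recurrence_se"], dtype=float),
            ),
            short_term_counts=(
                {
                    int(h): state_vec(m)
                    for h, m in d["short_term_counts"].items()
                }
                if "short_term_counts" in d
                else None
            ),
            prevalence=(
                np.array(d["prevalence"], dtype=float) if "prevalence" in d else None
            ),
        )

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_file(cls, path) -> "ParameterSet":
        """Load from JSON (canonical) or YAML (accepted dialect)."""
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass
class RegistryRecord:
    """One patient-level registry row used to fit the short-term model.

    ``None`` encodes a missing value (empty CSV field).
    """

    onset_to_groin_minutes: float | None
    mrs90: int | None
    occlusion_location: str | None = None  # ICA, M1, proxM2, other
    age: float | None = None
    treated_in_trial_center: bool | None = None

    CSV_COLUMNS = (
        "onset_to_groin_minutes",
        "mrs90",
        "occlusion_location",
        "age",
        "treated_in_trial_center",
    )


def validate_parameter_set(params: ParameterSet) -> list[str]:
    """Report every invariant violation in ``params``.

    Total: returns a (possibly empty) list of human-readable violation
    strings and never raises, whatever numeric garbage the set contains.
    An empty list means the set is valid.
    """
    out: list[str] = []
    try:
        hours = sorted(params.short_term)
        if hours != list(HOURS):
            out.append(f"short_term: expected hours {list(HOURS)}, got {hours}")
        for h, dist in sorted(params.short_term.items()):
            out.extend(dist.violations(f"short_term[hour {h}]"))
        if params.short_term_counts is not None:
            for h, counts in sorted(params.short_term_counts.items()):
                if np.any(counts < 0):
                    out.append(f"short_term_counts[hour {h}]: negative count")
                if counts.sum() < 1:
                    out.append(f"short_term_counts[hour {h}]: stratum total < 1")
        out.extend(params.life_table.violations())
        if not params.life_table.min_age <= params.cohort.start_age <= params.life_table.max_age:
            out.append(
                f"life_table: cohort start age {params.cohort.start_age} outside table range"
            )
        elif params.cohort.start_age + params.cohort.horizon_years > params.life_table.max_age:
            out.append("life_table: table too short for cohort age + horizon")
        out.extend(params.hazards.violations())
        out.extend(params.recurrence.violations())
        out.extend(params.econ.violations())
        out.extend(params.cohort.violations())
        out.extend(params.psa.violations())
        if params.prevalence is not None:
            if np.any(params.prevalence < 0) or params.prevalence.sum() <= 0:
                out.append("prevalence: weights must be non-negative with positive sum")
    except Exception as exc:  # malformed beyond field checks: still report, never raise
        out.append(f"parameter set malformed: {exc!r}")
    return out
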