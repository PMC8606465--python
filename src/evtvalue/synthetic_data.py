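"""Synthetic stand-ins for the registry, trial follow-up and public inputs.

The real model inputs (a national EVT registry, two-year trial follow-up,
actuarial life-table forecasts, published excess-mortality hazard ratios
and recurrence rates) are not redistributable, so this module fabricates
statistically analogous inputs for every pipeline stage:

* a patient-level registry in which the 90-day mRS degrades with
  onset-to-groin time through a proportional-odds (cumulative-logit) model,
* per-patient utility / cost observations at 3, 6, 12, 18 and 24 months
  scattering around per-state anchors,
* a Gompertz life table with female mortality below male,
* severity-ordered excess-mortality hazard ratios, annual recurrence
  probabilities with a non-fatal post-recurrence distribution, and per-state
  utilities / annual costs, assembled into a complete, valid
  :class:`~evtvalue.model_types.ParameterSet` with PSA annotations.

All generators are pure functions of their configuration (which includes
the seed): identical configurations yield byte-identical outputs. None of
the default values claims to equal the confidential source data; they are
chosen to be clinically plausible and to reproduce the qualitative shape of
the published inputs (ordinal time-to-treatment damage, worse-than-death
severe states, roughly delay-invariant cumulative costs).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .model_types import (
    COST_CATEGORIES,
    HOURS,
    LIVING_STATES,
    N_STATES,
    CohortSpec,
    EconomicInputs,
    LifeTable,
    MortalityHazardRatios,
    MRSDistribution,
    MRSState,
    ParameterSet,
    PSAAnnotations,
    RecurrenceModel,
    RegistryRecord,
)

__all__ = [
    "SyntheticConfig",
    "gen_registry",
    "gen_followup_econ",
    "gen_life_table",
    "gen_parameter_set",
    "true_mrs_distribution",
    "write_registry_csv",
    "read_registry_csv",
]

FOLLOWUP_MONTHS: tuple[int, ...] = (3, 6, 12, 18, 24)

# 90-day mRS 0..6 probabilities of a (hypothetical) zero-delay EVT cohort;
# the anchor of the proportional-odds time effect.
_BASELINE_MRS7 = np.array([0.10, 0.14, 0.17, 0.16, 0.14, 0.07, 0.22])

_OCCLUSION_LOCATIONS = ("ICA", "M1", "proxM2")
_OCCLUSION_PROBS = (0.27, 0.58, 0.15)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of every synthetic generator.

    * ``n_per_hour`` - registry records per delay-hour stratum.
    * ``ordinal_slope`` - log-odds shift of the 90-day mRS per hour of
      onset-to-groin delay (positive = worse outcomes with delay).
    * ``gompertz_a`` / ``gompertz_b`` - life-table baseline hazard and age
      slope; defaults put the annual death probability of a 69-year-old
      man near 1.5%.
    * ``female_factor`` - multiplier (< 1) on the female hazard.
    * ``utility_anchor`` / ``cost_anchor`` - per-state mean annual utility
      and first-year cost used by the follow-up generator.
    * ``followup_noise_sd`` - dispersion of repeated observations: absolute
      SD for utilities, coefficient of variation for costs.
    * ``n_followup`` - patients in the synthetic trial follow-up.
    * ``seed`` - RNG seed; fixed seed means byte-identical outputs.
    """

    n_per_hour: int = 480
    ordinal_slope: float = 0.12
    gompertz_a: float = 3.0e-5
    gompertz_b: float = 0.09
    female_factor: float = 0.6
    utility_anchor: tuple[float, ...] = (0.85, 0.71, 0.52, 0.28, -0.05, 0.0)
    cost_anchor: tuple[float, ...] = (9_000.0, 16_000.0, 28_000.0, 45_000.0, 60_000.0, 0.0)
    followup_noise_sd: float = 0.08
    n_followup: int = 400
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_hour < 1:
            raise ValueError("n_per_hour must be >= 1")
        if self.followup_noise_sd < 0:
            raise ValueError("followup_noise_sd must be >= 0")
        if self.gompertz_a <= 0 or self.gompertz_b <= 0:
            raise ValueError("Gompertz parameters must be > 0")
        if not 0 < self.female_factor <= 1:
            raise ValueError("female_factor must be in (0, 1]")


def _cumulative_logit_thresholds() -> np.ndarray:
    # thresholds theta_k with P(mRS <= k | delay h) = expit(theta_k - slope*h)
    return logit(np.cumsum(_BASELINE_MRS7)[:-1])


def _mrs7_probs(hour: float, slope: float) -> np.ndarray:
    """7-level 90-day mRS distribution under the proportional-odds model."""
    cum = expit(_cumulative_logit_thresholds() - slope * hour)
    probs = np.diff(np.concatenate(([0.0], cum, [1.0])))
    return probs


def true_mrs_distribution(config: SyntheticConfig, hour: int) -> MRSDistribution:
    """Generator-truth merged 6-state distribution for a delay hour."""
    p7 = _mrs7_probs(hour, config.ordinal_slope)
    merged = np.concatenate(([p7[0] + p7[1]], p7[2:]))
    return MRSDistribution(merged)


def gen_registry(config: SyntheticConfig) -> list[RegistryRecord]:
    """Patient-level registry records with an ordinal time effect.

    For each delay hour 1..6, ``n_per_hour`` records are drawn: the 90-day
    mRS from the proportional-odds model evaluated at that hour, the
    onset-to-groin time uniformly within the hour bin (minutes in
    (60*(h-1), 60*h]), occlusion site and age from fixed plausible
    marginals. All records satisfy the registry inclusion criteria by
    construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[RegistryRecord] = []
    for h in HOURS:
        p7 = _mrs7_probs(h, config.ordinal_slope)
        mrs = rng.choice(7, size=config.n_per_hour, p=p7)
        # uniform over (60*(h-1), 60*h]: sample [0, 60) and subtract from the top
        minutes = 60.0 * h - rng.uniform(0.0, 60.0, size=config.n_per_hour)
        locs = rng.choice(_OCCLUSION_LOCATIONS, size=config.n_per_hour, p=_OCCLUSION_PROBS)
        ages = np.clip(np.round(rng.normal(69.0, 11.0, size=config.n_per_hour)), 18, 99)
        for m, mn, loc, age in zip(mrs, minutes, locs, ages):
            records.append(
                RegistryRecord(
                    onset_to_groin_minutes=float(mn),
                    mrs90=int(m),
                    occlusion_location=str(loc),
                    age=float(age),
                    treated_in_trial_center=True,
                )
            )
    return records


def gen_followup_econ(config: SyntheticConfig) -> pd.DataFrame:
    """Repeated utility / cost observations at 3-24 months post-stroke.

    Each synthetic patient keeps one merged mRS state across visits;
    utilities scatter around the state's anchor with SD
    ``followup_noise_sd`` and annual costs with coefficient of variation
    ``followup_noise_sd`` (floored at zero). Columns: patient_id, month,
    mrs_state, utility, annual_cost_eur.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    util_anchor = np.asarray(config.utility_anchor, dtype=float)
    cost_anchor = np.asarray(config.cost_anchor, dtype=float)
    # patient states: living-state mix of a mid-delay cohort, death excluded
    mid = true_mrs_distribution(config, hour=3).probs[: len(LIVING_STATES)]
    state_probs = mid / mid.sum()
    states = rng.choice(len(LIVING_STATES), size=config.n_followup, p=state_probs)
    rows = []
    for pid, s in enumerate(states):
        for month in FOLLOWUP_MONTHS:
            utility = util_anchor[s] + (
                rng.normal(0.0, config.followup_noise_sd) if config.followup_noise_sd else 0.0
            )
            cost = cost_anchor[s] * (
                1.0 + (rng.normal(0.0, config.followup_noise_sd) if config.followup_noise_sd else 0.0)
            )
            rows.append(
                {
                    "patient_id": pid,
                    "month": month,
                    "mrs_state": MRSState(s).name,
                    "utility": utility,
                    "annual_cost_eur": max(cost, 0.0),
                }
            )
    return pd.DataFrame(rows)


def gen_life_table(config: SyntheticConfig, max_age: int = 110) -> LifeTable:
    """Gompertz life table q(age, sex) = 1 - exp(-a * e^(b*age) * f_sex).

    Male sex factor is 1, female ``female_factor`` < 1, so female mortality
    is lower at every age. Probabilities are capped at 1 (with a warning if
    the cap binds before ``max_age``).
    """
    config.validate()
    ages = np.arange(0, max_age + 1)
    hazard = config.gompertz_a * np.exp(config.gompertz_b * ages)
    qx = {}
    for sex, factor in (("M", 1.0), ("F", config.female_factor)):
        q = 1.0 - np.exp(-hazard * factor)
        if np.any(q[:-1] >= 1.0):
            warnings.warn(
                f"Gompertz parameters reach q=1 before age {max_age} for sex {sex}; capping",
                stacklevel=2,
            )
        qx[sex] = np.minimum(q, 1.0)
    return LifeTable(qx=qx, min_age=0, start_calendar_year=2021)


# Severity-ordered excess-mortality hazard ratios (living state x year
# since stroke); year 1 carries the acute excess, later years attenuate.
_HR_YEAR1 = np.array([1.5, 2.2, 3.0, 4.2, 6.0])
_HR_LATER = np.array([1.2, 1.6, 2.1, 2.8, 3.8])

# Annual recurrence probability by year since index stroke (~13% over 5 y).
_P_REC = np.array([0.042, 0.030, 0.025, 0.022, 0.020])

# Non-fatal 90-day mRS mix of an untreated control population (living
# states only, renormalized after removing death); skewed toward
# moderate-severe disability. Pseudo-counts mimic a trial control arm.
_REC_BASE = np.array([0.15, 0.18, 0.32, 0.28, 0.07])
_REC_N = 267

# Annual costs per state (EUR, source price-year): the first year carries
# the acute admission and rehabilitation, later years the chronic-care
# gradient. Levels are set so that higher per-year costs of severe states
# are largely offset by their shorter survival, keeping cumulative 5-year
# costs roughly flat across delay strata (the qualitative pattern of the
# source population).
_COST_YEAR2 = np.array([2_500.0, 5_500.0, 13_000.0, 28_000.0, 42_000.0, 0.0])
_COST_YEAR3 = np.array([2_000.0, 4_500.0, 11_000.0, 25_000.0, 38_000.0, 0.0])


def gen_parameter_set(config: SyntheticConfig) -> ParameterSet:
    """Assemble a complete, valid parameter set from the generators.

    Short-term distributions are the analytic proportional-odds
    distributions per hour (generator truth) with Dirichlet pseudo-counts
    of ``n_per_hour`` observations each; utilities and costs come from the
    config anchors; hazard ratios, recurrence and PSA standard errors use
    fixed severity-ordered defaults.
    """
    config.validate()
    short_term = {h: true_mrs_distribution(config, h) for h in HOURS}
    counts = {h: short_term[h].probs * config.n_per_hour for h in HOURS}

    hr_table = np.column_stack([_HR_YEAR1] + [_HR_LATER] * 4)
    utility = np.asarray(config.utility_anchor, dtype=float)
    cost1 = np.asarray(config.cost_anchor, dtype=float)

    econ = EconomicInputs(
        utility=utility,
        cost_year1=cost1,
        cost_year2=_COST_YEAR2.copy(),
        cost_year3plus=_COST_YEAR3.copy(),
        wtp=80_000.0,
        discount_qaly=0.015,
        discount_cost=0.04,
        inflation=0.017,
        price_year_factor=1.10,  # source price-year 2015 -> simulation start 2021
    )
    psa = PSAAnnotations(
        utility_se=np.array([0.02, 0.025, 0.03, 0.035, 0.05, 0.0]),
        cost_se={
            "year1": 0.15 * cost1,
            "year2": 0.15 * _COST_YEAR2,
            "year3plus": 0.15 * _COST_YEAR3,
        },
        hr_log_se=np.full((len(LIVING_STATES), 5), 0.10),
        recurrence_se=0.25 * _P_REC,
    )
    return ParameterSet(
        short_term=short_term,
        short_term_counts=counts,
        life_table=gen_life_table(config),
        hazards=MortalityHazardRatios(hr_table),
        recurrence=RecurrenceModel(
            p_rec=_P_REC.copy(),
            base_dist=_REC_BASE.copy(),
            base_counts=_REC_BASE * _REC_N,
        ),
        econ=econ,
        cohort=CohortSpec(start_age=69, sex_mix=0.5, horizon_years=5),
        psa=psa,
        # delay-hour prevalence of a typical EVT population (most patients
        # reach the angiosuite in hours 2-4)
        prevalence=np.array([0.05, 0.17, 0.30, 0.27, 0.14, 0.07]),
    )


# -- CSV round-trip for registry records --------------------------------


def write_registry_csv(records: list[RegistryRecord], path) -> None:
    """UTF-8 CSV with a header row; missing values as empty fields."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RegistryRecord.CSV_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    "" if rec.onset_to_groin_minutes is None else repr(rec.onset_to_groin_minutes),
                    "" if rec.mrs90 is None else rec.mrs90,
                    rec.occlusion_location or "",
                    "" if rec.age is None else repr(rec.age),
                    ""
                    if rec.treated_in_trial_center is None
                    else int(rec.treated_in_trial_center),
                ]
            )


def read_registry_csv(path) -> list[RegistryRecord]:
    records = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                RegistryRecord(
                    onset_to_groin_minutes=(
                        float(row["onset_to_groin_minutes"])
                        if row["onset_to_groin_minutes"]
                        else None
                    ),
                    mrs90=int(row["mrs90"]) if row["mrs90"] else None,
                    occlusion_location=row["occlusion_location"] or None,
                    age=float(row["age"]) if row["age"] else None,
                    treated_in_trial_center=(
                        bool(int(row["treated_in_trial_center"]))
                        if row["treated_in_trial_center"]
                        else None
                    ),
                )
            )
    return records
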