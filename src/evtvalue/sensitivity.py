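"""One-way and probabilistic sensitivity analyses.

The one-way analysis (OWSA) perturbs one input at a time by +/-10% (the
cohort start age by +/-4 years, affecting the long-term model only) and
records the resulting per-hour Net Monetary Benefit, yielding a tornado
table. Components of an mRS probability vector are perturbed individually
with the complement renormalized so the vector stays a distribution.

The probabilistic analysis (PSA) is second-order Monte Carlo: each draw
resamples every annotated parameter from its uncertainty distribution
(Dirichlet for mRS distributions, Normal for utilities, Gamma for costs,
LogNormal for hazard ratios, Beta for recurrence probabilities), reruns
the whole short-term + long-term + economics pipeline, takes the per-draw
median of the five adjacent-hour differences and converts it to per-hour /
per-10-minute / per-minute values. Summaries are empirical medians with
interquartile ranges (linear interpolation between order statistics).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_types import (
    COST_CATEGORIES,
    HOURS,
    LIVING_STATES,
    MRSDistribution,
    MRSState,
    ParameterSet,
    validate_parameter_set,
)
from .health_economics import (
    convert_time_unit,
    per_hour_median,
    qalys_to_disability_free_days,
    round_euro,
    simulate_strata,
    nmb_between_strata,
)
from .short_term_model import sample_short_term

__all__ = [
    "PSAConfig",
    "PSAResult",
    "run_owsa",
    "draw_parameter_set",
    "run_psa",
    "per_hour_nmb",
]

PAIR_LABELS: tuple[str, ...] = tuple(f"hour{h}-hour{h + 1}" for h in HOURS[:-1])


def per_hour_nmb(params: ParameterSet, age_offset: int = 0) -> float:
    """Baseline per-hour NMB: median of the five adjacent-hour NMBs."""
    strata = simulate_strata(params, age_offset=age_offset)
    nmbs = [
        nmb_between_strata(a, b, params.econ.wtp)[2]
        for a, b in zip(strata[:-1], strata[1:])
    ]
    return per_hour_median(nmbs)


# -- one-way sensitivity analysis ---------------------------------------


def _perturb_component(probs: np.ndarray, idx: int, factor: float) -> np.ndarray:
    """Scale one component of a probability vector, renormalize the rest."""
    p = float(probs[idx])
    new_p = min(max(p * factor, 0.0), 1.0)
    out = probs.copy()
    if p >= 1.0:  # degenerate vector: nothing to renormalize against
        return out
    out[idx] = new_p
    rest = np.delete(np.arange(len(probs)), idx)
    rest_sum = probs[rest].sum()
    if rest_sum > 0:
        out[rest] = probs[rest] * (1.0 - new_p) / rest_sum
    return out


def _owsa_variants(params: ParameterSet):
    """Yield (name, builder) where builder(factor) returns a varied set."""

    def vary(apply):
        def build(factor: float) -> ParameterSet:
            p = copy.deepcopy(params)
            apply(p, factor)
            return p

        return build

    for s in LIVING_STATES:
        yield f"utility[{s.name}]", vary(
            lambda p, f, s=s: p.econ.utility.__setitem__(s, params.econ.utility[s] * f)
        )
    for cat in COST_CATEGORIES:
        base = params.econ.cost_vector(cat)
        for s in LIVING_STATES:
            yield f"cost_{cat}[{s.name}]", vary(
                lambda p, f, cat=cat, s=s, base=base: p.econ.cost_vector(cat).__setitem__(
                    s, base[s] * f
                )
            )
    for s in LIVING_STATES:
        yield f"hr[{s.name}]", vary(
            lambda p, f, s=s: p.hazards.table.__setitem__(s, params.hazards.table[s] * f)
        )
    for t in range(1, 6):
        yield f"p_rec[year{t}]", vary(
            lambda p, f, t=t: p.recurrence.p_rec.__setitem__(
                t - 1, min(max(params.recurrence.p_rec[t - 1] * f, 0.0), 1.0)
            )
        )
    for h in HOURS:
        for s in MRSState:
            yield f"short_term[hour{h}][{s.name}]", vary(
                lambda p, f, h=h, s=s: p.short_term.__setitem__(
                    h,
                    MRSDistribution(
                        _perturb_component(params.short_term[h].probs, int(s), f)
                    ),
                )
            )


def run_owsa(
    params: ParameterSet, rel_change: float = 0.10, age_change: int = 4
) -> pd.DataFrame:
    """Tornado table of the per-hour NMB under one-at-a-time perturbations.

    Every scalar input is varied by ``-rel_change`` / ``+rel_change``
    (probabilities clamped to [0, 1], distribution components complement-
    renormalized); the cohort start age is varied by ``+/-age_change``
    years in the long-term model only. Rows are sorted by tornado span
    |high - low|, widest first. A variation that breaks a parameter-set
    invariant is flagged in the ``flagged`` column but still evaluated.
    """
    baseline = per_hour_nmb(params)
    rows = []
    for name, build in _owsa_variants(params):
        row = {"parameter": name, "baseline": baseline, "flagged": ""}
        for label, factor in (("low", 1.0 - rel_change), ("high", 1.0 + rel_change)):
            varied = build(factor)
            violations = validate_parameter_set(varied)
            if violations:
                row["flagged"] = "; ".join(sorted(set(violations)))
            row[label] = per_hour_nmb(varied)
        rows.append(row)
    age_row = {"parameter": "start_age", "baseline": baseline, "flagged": ""}
    age_row["low"] = per_hour_nmb(params, age_offset=-age_change)
    age_row["high"] = per_hour_nmb(params, age_offset=+age_change)
    rows.append(age_row)
    df = pd.DataFrame(rows)
    df["span"] = (df["high"] - df["low"]).abs()
    df = df.sort_values("span", ascending=False, kind="mergesort").reset_index(drop=True)
    return df[["parameter", "low", "high", "span", "baseline", "flagged"]]


# -- probabilistic sensitivity analysis ---------------------------------


def _gamma_draw(mean: float, se: float, rng: np.random.Generator, name: str) -> float:
    if se == 0 or mean == 0:
        return mean
    if mean < 0 or se < 0:
        raise ValueError(f"{name}: gamma requires non-negative mean and se")
    shape = (mean / se) ** 2
    scale = se**2 / mean
    return float(rng.gamma(shape, scale))


def _beta_draw(mean: float, se: float, rng: np.random.Generator, name: str) -> float:
    if se == 0:
        return mean
    if not 0 < mean < 1:
        raise ValueError(f"{name}: beta mean must be in (0, 1)")
    var = se**2
    if var >= mean * (1 - mean):
        raise ValueError(f"{name}: se too large for a beta distribution")
    nu = mean * (1 - mean) / var - 1.0
    return float(rng.beta(mean * nu, (1 - mean) * nu))


def draw_parameter_set(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One second-order Monte Carlo draw of the full parameter set.

    Families per parameter class: short-term and recurrence-base mRS
    distributions ~ Dirichlet(count vector) when counts are available
    (zero-count cells stay zero); utilities ~ Normal(mean, se), not
    truncated (a severe state may draw below zero); costs ~ Gamma moment-
    matched to (mean, se); hazard ratios ~ LogNormal(log mean, log-se);
    annual recurrence probabilities ~ Beta moment-matched to (mean, se).
    The drawn year-3+ cost is capped at the drawn year-2 cost so the
    "year 2 minus rehabilitation" structure survives resampling. A zero
    standard error leaves the parameter at its baseline value.
    """
    draw = copy.deepcopy(params)
    if params.short_term_counts is not None:
        draw.short_term = sample_short_term(params.short_term_counts, rng)
    if params.recurrence.base_counts is not None:
        alpha = params.recurrence.base_counts
        g = rng.gamma(shape=alpha, scale=1.0)
        if g.sum() <= 0:
            raise ValueError("recurrence.base_counts: all-zero count vector")
        draw.recurrence.base_dist = g / g.sum()

    for s in MRSState:
        se = params.psa.utility_se[s]
        if se > 0:
            draw.econ.utility[s] = rng.normal(params.econ.utility[s], se)
    for cat in COST_CATEGORIES:
        base = params.econ.cost_vector(cat)
        ses = params.psa.cost_se[cat]
        target = draw.econ.cost_vector(cat)
        for s in LIVING_STATES:
            target[s] = _gamma_draw(base[s], ses[s], rng, f"cost_{cat}[{s.name}]")
    # keep the year-3+ <= year-2 structure under independent draws
    np.minimum(
        draw.econ.cost_year3plus, draw.econ.cost_year2, out=draw.econ.cost_year3plus
    )

    log_se = params.psa.hr_log_se
    if np.any(log_se > 0):
        draw.hazards.table = np.exp(
            rng.normal(np.log(params.hazards.table), log_se)
        )
    for t in range(5):
        draw.recurrence.p_rec[t] = _beta_draw(
            params.recurrence.p_rec[t],
            params.psa.recurrence_se[t],
            rng,
            f"p_rec[year{t + 1}]",
        )
    return draw


@dataclass
class PSAConfig:
    """Monte Carlo settings: number of draws and RNG seed."""

    n_draws: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass
class PSAResult:
    """Raw per-draw outcomes plus summary helpers.

    ``draws`` holds one row per accepted draw: per-stratum QALYs/costs/NMV,
    per-pair differences, and the per-draw per-hour medians. ``n_failed``
    counts draws rejected by parameter validation.
    """

    draws: pd.DataFrame
    n_failed: int
    wtp: float

    def quantiles(self, column: str) -> tuple[float, float, float]:
        """(median, q25, q75) of one draw column, linear interpolation."""
        v = self.draws[column].to_numpy()
        q25, med, q75 = np.percentile(v, [25, 50, 75])
        return float(med), float(q25), float(q75)

    def summary_table(self) -> pd.DataFrame:
        """Published-style table: pairs, then per-hour/10-min/minute rows.

        Cost and NMB cells are whole euros; the per-10-min and per-minute
        QALY cells are expressed as disability-free life days (one QALY =
        365 days), at one decimal.
        """
        rows = []
        for i, label in enumerate(PAIR_LABELS):
            row = {"row": label}
            for prefix, col in (
                ("cost", f"d_cost_pair{i + 1}"),
                ("qaly", f"d_qaly_pair{i + 1}"),
                ("nmb", f"nmb_pair{i + 1}"),
            ):
                med, q25, q75 = self.quantiles(col)
                if prefix in ("cost", "nmb"):
                    med, q25, q75 = map(round_euro, (med, q25, q75))
                row.update({f"{prefix}_median": med, f"{prefix}_q25": q25, f"{prefix}_q75": q75})
            rows.append(row)
        for unit, minutes in (("per_hour", 60), ("per_10min", 10), ("per_minute", 1)):
            row = {"row": unit}
            for prefix, col, is_euro in (
                ("cost", "per_hour_d_cost", True),
                ("qaly", "per_hour_d_qaly", False),
                ("nmb", "per_hour_nmb", True),
            ):
                med, q25, q75 = self.quantiles(col)
                vals = [v * minutes / 60.0 for v in (med, q25, q75)]
                if is_euro:
                    vals = [round_euro(v) for v in vals]
                elif unit != "per_hour":  # QALYs as disability-free days
                    vals = [round(v * 365.0, 1) for v in vals]
                row.update(
                    {
                        f"{prefix}_median": vals[0],
                        f"{prefix}_q25": vals[1],
                        f"{prefix}_q75": vals[2],
                    }
                )
            rows.append(row)
        return pd.DataFrame(rows)


def run_psa(params: ParameterSet, psa_config: PSAConfig) -> PSAResult:
    """Second-order Monte Carlo over the full pipeline.

    Each draw resamples the parameter set, recomputes per-stratum
    discounted QALYs/costs/NMV, the five adjacent-hour differences and
    their per-draw medians. Draws failing parameter validation are
    counted, excluded and reported; they contribute nothing to summaries.
    Reproducible: the same config yields the identical result table.
    """
    rng = np.random.default_rng(psa_config.seed)
    records = []
    n_failed = 0
    for _ in range(psa_config.n_draws):
        draw = draw_parameter_set(params, rng)
        if validate_parameter_set(draw):
            n_failed += 1
            continue
        strata = simulate_strata(draw)
        rec: dict[str, float] = {}
        for s in strata:
            rec[f"qalys_hour{s.hour}"] = s.qalys
            rec[f"costs_hour{s.hour}"] = s.costs
            rec[f"nmv_hour{s.hour}"] = s.nmv
        d_qalys, d_costs, nmbs = [], [], []
        for i, (a, b) in enumerate(zip(strata[:-1], strata[1:])):
            d_qaly, d_cost, benefit = nmb_between_strata(a, b, draw.econ.wtp)
            rec[f"d_qaly_pair{i + 1}"] = d_qaly
            rec[f"d_cost_pair{i + 1}"] = d_cost
            rec[f"nmb_pair{i + 1}"] = benefit
            d_qalys.append(d_qaly)
            d_costs.append(d_cost)
            nmbs.append(benefit)
        rec["per_hour_d_qaly"] = per_hour_median(d_qalys)
        rec["per_hour_d_cost"] = per_hour_median(d_costs)
        rec["per_hour_nmb"] = per_hour_median(nmbs)
        records.append(rec)
    if not records:
        raise ValueError("every PSA draw failed parameter validation")
    return PSAResult(draws=pd.DataFrame(records), n_failed=n_failed, wtp=params.econ.wtp)
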