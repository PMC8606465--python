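"""Short-term model: 90-day mRS distribution per onset-to-groin hour.

Patient-level registry records are filtered against the study inclusion
criteria, binned into delay-hour strata (hour h covers minutes in
(60*(h-1), 60*h], so 360 minutes is the closed upper edge of hour 6), and
the empirical relative frequencies of the six merged mRS states form the
per-hour 90-day distributions. The raw multinomial count vectors are kept:
the probabilistic sensitivity analysis resamples each stratum as
Dirichlet(counts) with a zero prior, so cells never observed stay
structurally zero rather than being invented.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
import pandas as pd

from .model_types import (
    HOURS,
    N_STATES,
    MRSDistribution,
    MRSState,
    RegistryRecord,
)

__all__ = [
    "INCLUSION_CRITERIA",
    "filter_registry",
    "hour_stratum",
    "merge_mrs90",
    "estimate_mrs_by_hour",
    "sample_short_term",
    "hour_prevalence",
    "mrs_table",
]

_ANTERIOR_LVO = {"ICA", "M1", "proxM2"}

#: Inclusion criteria in evaluation order; an excluded record is attributed
#: to its first failing criterion.
INCLUSION_CRITERIA: tuple[str, ...] = (
    "anterior_lvo",
    "trial_center",
    "age_ge_18",
    "mrs90_available",
    "time_available",
    "time_le_360",
)


def _passes(criterion: str, rec: RegistryRecord) -> bool:
    if criterion == "anterior_lvo":
        return rec.occlusion_location in _ANTERIOR_LVO
    if criterion == "trial_center":
        return bool(rec.treated_in_trial_center)
    if criterion == "age_ge_18":
        return rec.age is not None and rec.age >= 18
    if criterion == "mrs90_available":
        return rec.mrs90 is not None
    if criterion == "time_available":
        return rec.onset_to_groin_minutes is not None
    if criterion == "time_le_360":
        return rec.onset_to_groin_minutes <= 360.0
    raise ValueError(f"unknown criterion {criterion!r}")


def filter_registry(
    records: list[RegistryRecord],
) -> tuple[list[RegistryRecord], "OrderedDict[str, int]"]:
    """Apply the six inclusion criteria.

    Returns the retained records and per-criterion exclusion counts; each
    dropped record counts against the first criterion it fails, in the
    order of :data:`INCLUSION_CRITERIA`. Idempotent: filtering the
    retained records again drops nothing.
    """
    counts: OrderedDict[str, int] = OrderedDict((c, 0) for c in INCLUSION_CRITERIA)
    included = []
    for rec in records:
        for criterion in INCLUSION_CRITERIA:
            if not _passes(criterion, rec):
                counts[criterion] += 1
                break
        else:
            included.append(rec)
    return included, counts


def hour_stratum(minutes: float) -> int:
    """Delay-hour stratum of an onset-to-groin time.

    Hour h covers minutes in (60*(h-1), 60*h]; 360 min falls in hour 6.
    """
    if not 0 < minutes <= 360:
        raise ValueError(f"onset-to-groin time {minutes} min outside (0, 360]")
    return int(np.ceil(minutes / 60.0))


def merge_mrs90(mrs90: int) -> MRSState:
    """Map a raw 0..6 score to the merged six-state scale (0 and 1 merge)."""
    if not 0 <= mrs90 <= 6:
        raise ValueError(f"mrs90 must be in 0..6, got {mrs90}")
    return MRSState(max(mrs90 - 1, 0))


def estimate_mrs_by_hour(
    records: list[RegistryRecord],
) -> dict[int, tuple[MRSDistribution, np.ndarray]]:
    """Empirical 90-day mRS distribution and count vector per delay hour.

    Records must already be filtered (every field present and in range).
    Raises if any hour stratum is empty: an empty stratum cannot anchor a
    cycle-0 distribution.
    """
    counts = {h: np.zeros(N_STATES) for h in HOURS}
    for rec in records:
        h = hour_stratum(rec.onset_to_groin_minutes)
        counts[h][merge_mrs90(rec.mrs90)] += 1
    out: dict[int, tuple[MRSDistribution, np.ndarray]] = {}
    for h in HOURS:
        total = counts[h].sum()
        if total < 1:
            raise ValueError(f"no records in delay-hour stratum {h}; cannot estimate")
        out[h] = (MRSDistribution(counts[h] / total), counts[h])
    return out


def sample_short_term(
    counts: dict[int, np.ndarray], rng: np.random.Generator
) -> dict[int, MRSDistribution]:
    """One Dirichlet(counts) draw per stratum (zero prior).

    Cells with zero observed count have Dirichlet weight 0 and are
    structurally zero in every draw: no smoothing mass is invented. The
    draw is realized through independent Gamma(count) variables normalized
    to sum 1, which handles zero shapes exactly.
    """
    out: dict[int, MRSDistribution] = {}
    for h in sorted(counts):
        alpha = np.asarray(counts[h], dtype=float)
        if np.any(alpha < 0):
            raise ValueError(f"negative count in stratum {h}")
        if alpha.sum() <= 0:
            raise ValueError(f"all-zero count vector in stratum {h}")
        draw = rng.gamma(shape=alpha, scale=1.0)
        out[h] = MRSDistribution(draw / draw.sum())
    return out


def hour_prevalence(records: list[RegistryRecord]) -> np.ndarray:
    """Relative frequency of each delay hour among (filtered) records."""
    counts = np.zeros(len(HOURS))
    for rec in records:
        counts[hour_stratum(rec.onset_to_groin_minutes) - 1] += 1
    if counts.sum() == 0:
        raise ValueError("no records to compute hour prevalence from")
    return counts / counts.sum()


def mrs_table(estimates: dict[int, tuple[MRSDistribution, np.ndarray]]) -> pd.DataFrame:
    """Stratum x state table of probabilities and counts for export."""
    rows = []
    for h, (dist, counts) in sorted(estimates.items()):
        row: dict[str, float] = {"hour": h}
        for s in MRSState:
            row[f"p_{s.name}"] = dist[s]
        for s in MRSState:
            row[f"n_{s.name}"] = counts[s]
        rows.append(row)
    return pd.DataFrame(rows)
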