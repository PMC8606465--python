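# Methods

## Model structure

`evtvalue` implements a two-stage Markov cohort model of large-vessel-occlusion
(LVO) stroke treated with endovascular thrombectomy (EVT), quantifying what one
hour (and, by linear rescaling, ten minutes or one minute) of faster treatment
is worth in health and healthcare costs over a five-year horizon.

**States.** Six states on the modified Rankin Scale (mRS): `MRS0_1` (mRS 0 and
1 merged — at the favourable end single-score sample sizes are too small to
estimate reliably), `MRS2` … `MRS5`, and `DEAD` (absorbing). Severity is
ordinal; the engine never allows spontaneous improvement — disability can only
stay equal or worsen, through recurrence or death.

**Short-term stage.** The 90-day post-treatment mRS distribution is estimated
per onset-to-groin-puncture delay stratum. Hour *h* covers minutes in
(60·(h−1), 60·h]; the study's 360-minute eligibility bound is thus the closed
upper edge of hour 6. Records pass six inclusion criteria (anterior-circulation
LVO, treatment in a trial center, age ≥ 18, 90-day mRS available,
onset-to-groin time available and ≤ 360 min), each exclusion attributed to the
first failing criterion. Within a stratum the distribution is the empirical
relative frequency over the six merged states, with the raw multinomial count
vector retained for resampling.

**Long-term stage.** Annual cycles over 5 years; cycle 0 *is* the 90-day
distribution and carries no transition. Per cycle and living state:

1. *Mortality.* Background annual death probability `q_mix` is the sex-mixed
   life-table value at the attained age (cohort default: age 69 at baseline,
   50% male, ageing one year per cycle). The state- and year-specific excess
   hazard ratio is applied on the cumulative-hazard scale,
   `p_die = 1 − (1 − q_mix)^hr`, the standard actuarial composition that keeps
   probabilities in [0, 1].
2. *Recurrence.* Survivors suffer a recurrent stroke with the year-specific
   probability `p_rec(t)` and land in a state drawn from a control-population
   90-day distribution **excluding death**, truncated to states at least as
   severe as the current one and renormalized. Death after recurrence is
   structurally excluded because stroke-related mortality already lives inside
   the all-cause hazard ratios; allowing it would double-count.

Death is resolved before recurrence within a cycle, so the two channels are
disjoint. No half-cycle correction is applied; transitions and accruals are
whole-cycle. The post-recurrence state takes effect at the next cycle boundary
(the cycle of recurrence accrues the pre-recurrence state's utility and cost).

## Economics

Per cycle *t* = 1…5 the cohort accrues
`occupancy(t) · utility` QALYs, discounted at 1.5%/year, and
`occupancy(t) · cost(t)` euros, discounted at 4%/year (Dutch guideline rates;
effects and costs are deliberately discounted at different rates). Costs are
anchored per state and year-category: year 1 (anchored on 90-day mRS, includes
the acute admission and rehabilitation), year 2 (anchored on 18-month mRS),
years 3+ (year-2 costs with rehabilitation removed — hence never larger).
Nominal costs are translated from the source price-year with a fixed historical
multiplier and projected forward at 1.7%/year inflation before discounting.
Utilities are annual QALY weights and may be negative (states perceived worse
than death); they are never clamped. Cycle 0 accrues nothing by default; the
`include_cycle0` switch of `accrue()` adds 90/365 of a year of utility
(undiscounted, no cost) for sensitivity checks.

Outcome algebra, per delay stratum and between adjacent strata:

- `NMV = QALYs · WTP − costs` at WTP = €80,000/QALY;
- `NMB(h) = NMV(h) − NMV(h+1)`, likewise ΔQALY and Δcost;
- the *per-hour* headline is the **median of the five adjacent-hour
  differences** (per PSA draw, then summarized across draws);
- per-10-minute and per-minute values divide the per-hour value by 6 and 60
  (assuming constant differences within the hour); euro outputs are rounded
  half-away-from-zero to whole euros, day-valued outputs to one decimal;
- one QALY is expressed as 365 disability-free life days.

## Sensitivity analyses

**One-way (OWSA).** Every scalar input is varied ±10%; components of an mRS
probability vector are varied individually with the complement renormalized so
the vector remains a distribution; the cohort start age is varied ±4 years,
affecting the long-term model only (the 90-day distributions stay fixed). Rows
are sorted by tornado span. A variation that breaks a cross-parameter
invariant (e.g. −10% on a year-2 cost undercutting the year-3+ cost) is
flagged, not silently dropped.

**Probabilistic (PSA).** Second-order Monte Carlo, default 10,000 draws.
Families follow standard cost-effectiveness conventions:

| parameter | family | notes |
|---|---|---|
| per-hour mRS distributions | Dirichlet(counts) | zero prior; zero-count cells stay structurally zero |
| post-recurrence base distribution | Dirichlet(counts) | same rule |
| utilities | Normal(mean, se) | untruncated; severe states may draw < 0 |
| annual costs | Gamma | moment-matched to (mean, se); drawn year-3+ capped at drawn year-2 |
| hazard ratios | LogNormal(log mean, log-se) | positivity guaranteed |
| recurrence probabilities | Beta | moment-matched to (mean, se) |

A zero standard error collapses the family to its mean. Each draw reruns the
whole pipeline; draws failing validation are counted, excluded and reported.
Summaries are medians with interquartile ranges; quantiles use linear
interpolation between order statistics (numpy default), stated here so IQRs
are reproducible to the bit.

**Population extrapolation.** Per draw, the five pair differences are averaged
with weights proportional to the prevalence of the *later* hour of each pair
(those are the patients who would realize that gain if treated an hour
earlier; hour-1 patients cannot gain a full hour), then scaled by the yearly
EVT volume. The yearly count is an explicit input defaulting to the reported
887/year; the package also computes the annualization formula
(total·12/months) and warns when the two disagree, as they do for the source
figures (3279 patients / 43 months ≈ 915/year).

**External validation.** Simulated traces are banded into mRS ≤ 2 / mRS 3–5 /
dead and compared with user-supplied reference proportions (year, band,
proportion CSV); the output is a table of absolute differences, with no test
statistic attached.

## Synthetic data

Real inputs (national registry, trial follow-up, actuarial forecasts) are not
redistributable, so `synthetic_data` fabricates statistically analogous
stand-ins; none of its defaults claims to equal the confidential values.

- *Registry*: per delay hour, 90-day mRS is drawn from a proportional-odds
  (cumulative-logit) model — the standard ordinal regression — with a
  log-odds shift of 0.12 per hour of delay against a fixed zero-delay anchor
  distribution; onset-to-groin minutes are uniform within the hour bin.
  Default 480 records/hour (≈ 2,900 patients, the scale of a national
  registry). The analytic per-hour distributions are exposed as generator
  truth for parameter-recovery tests.
- *Follow-up economics*: per-patient utility/cost observations at months
  3–24 scattering around per-state anchors (utility SD absolute, cost SD
  relative). Anchors: utility 0.85 (mRS 0–1) down to −0.05 (mRS 5, worse than
  death); first-year costs €9,000 → €60,000 across severity.
- *Life table*: Gompertz, `q = 1 − exp(−a·e^{b·age}·f_sex)` with a = 3·10⁻⁵,
  b = 0.09 (annual death probability ≈ 1.5% for a 69-year-old man), female
  factor 0.6.
- *Hazard ratios*: severity-ordered, 1.5–6.0 in year 1 attenuating to
  1.2–3.8 in later years. *Recurrence*: 4.2% in year 1 declining to 2.0%
  (≈ 13% cumulative over 5 years); post-recurrence base distribution skewed
  to moderate-severe disability with control-arm-scale pseudo-counts (n=267).
- Cost levels were chosen so that the higher per-year costs of severe states
  are largely offset by their shorter survival, reproducing the qualitative
  pattern the model is known for: cumulative five-year costs nearly invariant
  to treatment delay, so faster treatment buys health at roughly zero net
  cost.

What the generator does **not** emulate: covariate structure (age/severity
confounding with delay), within-patient mRS transitions during follow-up,
inter-parameter correlation in the PSA, calendar-time life-table improvement.
Passing tests therefore demonstrate the correctness and statistical behaviour
of the machinery under the declared generative law, not the magnitude of any
real-world estimate: headline euro values computed on synthetic inputs are
internally valid, not external claims.

## Numerical choices

- Mass conservation asserted at 1e-12 per transition row, 1e-10 per trace row.
- Dirichlet draws realized as normalized per-cell Gamma(shape=count)
  variables, which handles zero counts exactly.
- Beta/Gamma moment matching rejects infeasible hyperparameters (e.g.
  se² ≥ m(1−m)) with the parameter's name in the error.
- Hazard-ratio and recurrence tables cover 5 years; horizons beyond 5 reuse
  the year-5 values.
- Euro rounding is half-away-from-zero (so 241.98 → 242 and −40.55 → −41);
  Python's bankers' rounding is deliberately not used.
- All randomness flows through `numpy.random.default_rng` seeds; the pipeline
  manifest records every seed plus a hash of the parameter set, making any
  output bit-reproducible.
- Default problem sizes (480 records/hour for the generator; 2,000 draws in
  the acceptance script's PSA versus the 10,000-draw analysis default) keep
  a full run in the seconds-to-minutes range on one core while leaving Monte
  Carlo error well below the decision-relevant scale.

## Known limitations

- Five-year horizon only; no lifetime extrapolation (by design: error
  accumulation dominates long horizons).
- Healthcare-payer perspective; societal costs out of scope.
- The 90-day distribution is conditioned on delay hour only — no covariate
  adjustment (age affects the long-term stage exclusively).
- No EVPI/CEAC computation and no correlation between PSA parameters.
- The per-minute conversion assumes a constant effect within each hour; the
  per-draw median-of-five makes the headline robust to one irregular pair
  but is not a trend estimate.
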