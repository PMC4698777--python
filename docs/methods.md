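# Methods

## Model structure

The model is a deterministic Markov cohort simulation over annual cycles.
The four clinical states — normal glucose tolerance (NGT), impaired glucose
tolerance (IGT), type 2 diabetes (T2DM), death — are expanded internally to
six by splitting NGT and IGT into *retained* and *dropped* strata. The
split encodes participation in the two-year SMS programme: only retained
mass receives the relative-risk reduction on IGT→T2DM onset and incurs the
programme cost. The control cohort, drop-outs, and everyone after cycle 2
occupy the dropped strata, which follow control-arm natural history. T2DM
is absorbing except for death (converters stop receiving the programme and
are managed identically in both arms); death is absorbing. There is no
direct NGT→T2DM transition and no modelling of diabetic complications.

Assumptions worth making explicit:

* **Constant hazards within a cycle.** Rates convert to probabilities by
  p = 1 − exp(−rt), t = 1 year, and back by r = −ln(1 − p).
* **Intervention relative risk on the probability scale.** RR × p, capped
  at 1. Applied this way, 0.60 × 10.417% reproduces the published 6.25%
  year-2 SMS onset probability exactly; rate-scale application would give
  6.39%.
* **Mortality relative risk on the rate scale.** q_adj = 1 − (1 − q)^RR.
  The two conventions differ by under 0.1 percentage point at the relevant
  magnitudes, and the rate convention keeps probabilities in [0, 1) for
  any RR, which matters at the upper sensitivity corners.
* **Mortality-first composition.** Each cycle the state-specific death
  probability is applied and the inter-state probabilities act on the
  surviving mass (scaled by 1 − q). This keeps every transition-matrix row
  exactly stochastic at all corners of the sensitivity ranges (e.g. IGT→NGT
  25% plus IGT→T2DM 11.57% plus old-age mortality) without truncation.
* **Drop-out at cycle start.** 38.89% of retained mass drops at the start
  of cycle 1 and 30.30% of the remainder at the start of cycle 2, before
  any transition. Year-1 onset in the SMS arm is therefore a drop-out-
  weighted mixture of the treated and control probabilities, and at 100%
  year-1 drop-out the two arms coincide exactly from the first transition —
  the incremental cost is exactly $0.00 regardless of the life table.
* **Retention labels persist through NGT↔IGT moves** during the window: a
  retained subject who regresses to NGT and relapses still receives the
  year-2 relative risk, because messages were delivered for two years
  regardless of interim glycaemic state.
* **No half-cycle correction.** Occupancy is evaluated at cycle end, which
  is also where costs, life years and QALYs accrue.

## Economics

Discounted at 3%/year with end-of-cycle weights (1 + r)^(−t), first cycle
discounted. The annual T2DM cost is charged on end-of-cycle diabetic
occupancy, so the onset year carries a full year's cost. The programme cost
is charged on retained, alive, non-diabetic mass at cycle start after
drop-out (configurable to IGT-only via `intervention_cost_states`); this is
the convention under which the incremental cost vanishes identically as
year-1 drop-out reaches 100%. The dead state carries zero cost and zero
utility. Cumulative T2DM onset is a clinical event count and is reported
undiscounted. Dominance ("cheaper and more effective") is evaluated per
effect measure; an ICER is reported only when the cost and effect deltas
share a sign, and is undefined at a zero effect delta.

## Parameters

All inputs live in `src/igtcea/data/basecase.yaml` and are validated on
load (probabilities in [0, 1], costs ≥ 0, relative risks > 0, utilities in
[0, 1]). Units: rates per person-year, costs in 2011 US$ (HKD pegged at
7.8), utilities per year. The two SMS unit costs are sums of delivery and
staff components (4.15 + 30.23 = 34.38 in year 1; 0.92 + 6.72 = 7.64 in
year 2); component values are authoritative and the two-year total is
therefore $42.02. The year-1 SMS onset probability is derived as
0.34 × 10.417% = 3.542%; a direct probability override
(`p_igt_to_t2dm_sms_y1: 0.0353`) is available for users who want the
published rounded 3.53% literally — the unrounded trial RR was evidently
slightly below 0.34.

The cohort starting age defaults to 55 (the trial population's age
structure is not an input shipped with the model; results reported by the
acceptance script are independent of this choice) and the long horizon to
50 years.

## Synthetic life table

The original analysis used a national all-cause life table that is not
bundled here. `generate_life_table` synthesises a single-year, sex-averaged
table from the Gompertz–Makeham hazard rate(x) = A + B·e^(cx) with defaults
A = 0.001, B = 0.0001, c = 0.085, giving adult mortality of the order of
national tables for an industrialised population (≈0.3% at age 40, 0.8% at
50, 2% in the early 60s). What the synthetic table does *not* emulate:
infant/young-adult mortality structure, sex differences, and secular trend.
Consequently the 2-year results (driven almost entirely by the printed
transition probabilities) reproduce the published figures closely, while
50-year absolute costs, life years and thresholds depend on the mortality
tail and are expected to agree in sign, structure and order of magnitude
but not digit-for-digit. Any real table can be supplied as CSV
(`age,mortality_rate`, contiguous integer ages); the loader validates
contiguity and non-negativity.

## Sensitivity and threshold analysis

One-way sweeps re-run the full 50-year pipeline at both endpoints of each
declared range, holding everything else at base case; results are reported
as endpoint incremental costs with a dominance status, mirroring the usual
tabular presentation. Threshold analysis bisects the map parameter →
incremental discounted cost (monotone in each supported parameter) to a
residual below $0.01, at most 64 iterations, and reports the bracket and
residual. With the synthetic table and start age 55 the four break-even
values are: year-1 programme cost ≈ $1,218, year-2 cost ≈ $1,853, year-1
SMS onset probability ≈ 12.1%, year-2 ≈ 22.7% (recomputed at run time by
`igtcea threshold`; the probability thresholds are nearly insensitive to
the life table, the cost thresholds scale with the discounted mortality
tail). No probabilistic sensitivity analysis is implemented.

## Microsimulation oracle

`microsimulate` pushes n individual subjects through the *same* per-cycle
probabilities with per-subject Bernoulli draws (drop-out at cycle start,
then a categorical transition draw from the subject's matrix row), accruing
per-subject discounted economics under identical conventions. Because it
shares only the per-cycle probabilities — not the expectation propagation —
agreement of empirical state frequencies with the cohort trace within
binomial sampling error (3 SE at n = 200,000, every cycle, both strategies)
is a genuine cross-check of the engine's bookkeeping: drop-out timing,
retention-label handling, mortality-first composition and onset counting
would each break it independently. `generate_trial_cohort` additionally
emulates the two-arm trial structure behind the relative risks (mortality
ignored over the two-year window) so that parameter-recovery tests can
confirm an empirical completer RR re-estimates the input RR within
binomial error — and that at the original pilot's scale (~52 per arm) the
RR is very uncertain.

All randomness flows through one seeded `numpy.random.Generator` per run;
identical (seed, n) gives bit-identical output.

## Numerical choices and degenerate inputs

Transition rows are asserted to sum to 1 within 1e-9 at assembly (they hold
to ~1e-16); occupancy mass is conserved to 1e-10 over 50 cycles. The
rate↔probability round trip holds to 1e-12 over p ∈ [0, 0.999] (expm1/log1p
forms). RR-scaled probabilities are capped at 1 with a logged warning.
Competing IGT exits (onset + regression) are validated to sum ≤ 1 before
survivor scaling. A horizon extending past the life table raises an error
instructing the user to extend the table rather than extrapolating
silently. Monetary values are rounded to cents only when tables are
written.

## Problem sizes

The deterministic pipeline is a 50-step iteration of 6×6 matrices and runs
in milliseconds, so sweeps and bisections use the full 50-year model. The
validation suites use n = 200,000 subjects for the oracle comparison,
n = 50,000 per arm × 500 replicates for RR-recovery calibration, and a
1,001-point grid scan per parameter for threshold uniqueness.

## Known limitations

* No diabetic-complication sub-states; a single average T2DM cost and
  utility regardless of duration, sex, or treatment.
* No probabilistic sensitivity analysis, CEACs or EVPI.
* The synthetic life table is a stand-in: absolute 50-year quantities
  depend on it (see above).
* Costs are health-service-provider perspective only; no societal costs.
* Whether the original implementation applied drop-out before or after the
  first transition, or let retention labels persist through regression, is
  not externally documented; this package's choices are stated above and
  the cost-exposure convention is configurable.
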