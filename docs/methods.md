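# Methods

`rheumcea` implements a cohort state-transition (Markov) model comparing six
sequential, treat-to-target DMARD strategies for established rheumatoid
arthritis in a low-resource setting (Zanzibar), from a healthcare-provider
perspective restricted to outpatient care.

## Model structure

**Health states.** Four live disease-activity states defined by CDAI bands —
remission (CDAI ≤ 2.8), low (≤ 10), moderate (≤ 22) and high (> 22) disease
activity — plus absorbing death. Remission and LDA together form the
*treatment target*. The cohort starts with moderate disease activity, on
methotrexate.

**Strategies.** Every strategy starts with methotrexate; patients who miss
the target escalate through the strategy's remaining lines (triple therapy =
methotrexate + sulfasalazine + hydroxychloroquine; one or two
biologic/targeted-synthetic DMARDs) and end on *rescue therapy*
(methotrexate + low-dose prednisolone with calcium/vitamin D). The six
sequences are: (1) MTX only; (2) MTX→TT; (3) MTX→b/tsDMARD1;
(4) MTX→TT→b/tsDMARD1; (5) MTX→TT→b/tsDMARD1→b/tsDMARD2;
(6) MTX→b/tsDMARD1→b/tsDMARD2.

**Cycle dynamics.** Cycles are 6 months, horizon 3 years (6 cycles).
The cohort is tracked on an expanded space: health state × treatment
position (just started line *k* / at target on line *k* / rescue states).
Within a cycle, death is applied first (background annual mortality 0.004,
converted to a per-cycle probability under a constant hazard, times
disease-activity multipliers 1.0 / 1.29 / 1.42 / 1.42 for
remission/LDA/MDA/HDA). Survivors who just started a line land on the line's
6-month transition profile; remission/LDA landers stay on that line and
remain at target with probability 0.8 per cycle (re-split remission:LDA
1:2), relapsers (split MDA:HDA 2:1) start the next line. A line's *early*
profile applies when it follows methotrexate failure alone and its *late*
profile after both methotrexate and triple-therapy failure; for the second
b/tsDMARD in strategy 6 this means the early profile, since no triple
therapy precedes it.

**Rescue categorization.** After the last line fails, patients spend one
cycle on rescue therapy and reach the target with probability 0.43, split
1:2 remission:LDA; those who do not are categorized off-target (2:1
MDA:HDA) for the remaining cycles. Both categories are absorbing apart from
death. This one-shot reading of the rescue stage is the package default
(`rules.rescue_mode: one_shot`): it is the only variant, among the four we
examined, under which effectiveness increases monotonically from strategy 1
through strategy 6 — longer sequences give more chances of durable target
attainment — which matches the published ordering. A literal per-cycle
rescue response (`rescue_mode: per_cycle`, optionally with
`rescue_at_relapse: true`) is available; under it the rescue state (43% per
cycle indefinitely) slightly outperforms a trial cycle on the second
b/tsDMARD (42% once), so adding that drug can *reduce* effectiveness.

## Costs and accrual

Unit costs (USD, December-2021 prices) per 6 months: methotrexate 45,
sulfasalazine 127, hydroxychloroquine 111, 1st b/tsDMARD 94, 2nd b/tsDMARD
5,456, prednisolone rescue bundle 20, bridging steroids 6 (once, cycle 1),
diagnosis work-up 125 (once), csDMARD first-cycle investigation panel 57
(once), csDMARD continuation investigations 25/cycle, b/tsDMARD start-up
panel 157 (once per biologic line started), b/tsDMARD continuation 7/cycle,
clinic visits 4/visit — four visits in the first cycle, then one per cycle
at target and two off target. The b/tsDMARD continuation figure follows the
±50% range printed for that item (3.5–10.5, i.e. a 7 USD point value); the
separately printed point of 56 contradicts its own range by a factor of
eight and the three-year strategy totals, so we treat it as a misprint.

Costs are billed on start-of-cycle occupancy — the people occupying a
treatment position during the cycle pay its drug, investigation and visit
costs; one-off charges are billed when triggered. QALYs accrue on the
half-cycle-corrected occupancy (trapezoid average of adjacent cycle starts)
at the band utilities 0.87 / 0.72 / 0.57 / 0.21 (a pooled two-level
0.77 / 0.45 alternative is available via
`utilities.use_pooled_target_utilities`). Both flows are discounted at 3%
per year, evaluated at cycle midpoints.

## Cost-effectiveness analysis

Strategies are compared by discounted totals: absolute dominance (weakly
costlier and less effective than some alternative), extended dominance
(incremental ICER above the next more effective strategy's), frontier ICERs,
and net monetary benefit NMB = QALYs × WTP − cost with WTP thresholds 282
(base), 1,136 and 2,272 USD/QALY. The cheapest strategy carries no ICER.

## Sensitivity analyses

*One-way (tornado)*: each parameter in turn at its low/high bound (±50% for
costs, ±25% for probabilities and utilities, or the printed range where one
exists), re-evaluating a strategy pair's ICER.

*Probabilistic*: 10,000 Monte-Carlo iterations drawing all parameters
jointly and independently — costs from gamma, probabilities from beta,
utilities from normal distributions, each matched by method of moments to
mean = point estimate and SD = (high − low)/(2·1.96). Transition-profile
rows are drawn per state from betas and renormalized to sum to one (a
Dirichlet option exists). Utility draws are truncated to [0, 1]; the
truncation slightly lowers the realized remission-utility mean because the
printed upper bound (1.0875) exceeds full health. All six strategies are
evaluated per draw (common random numbers), giving CEAC curves and pairwise
incremental scatters.

*Price thresholds*: bisection on one drug line's per-cycle price until the
pairwise ICER against methotrexate monotherapy equals the WTP (tolerance
0.5 USD/QALY), with an explicit no-solution result when even a free drug
leaves the ICER above the threshold. The triple-therapy threshold is
expressed as the price of the whole three-drug combination.

*Scenarios*: the India and Scandinavia parameter sets replace component drug
prices only (plus the +18 USD calcium/vitamin D supplement in the rescue
arm); investigation, visit and overhead costs stay at Zanzibar values.

## Synthetic data

The patient-level EQ-5D-5L data behind the band utilities are not publicly
deposited, so the package generates a synthetic stand-in. Baseline CDAI is
truncated-normal (mean 19.8, SD 12.8, support [0, 76]; truncation raises the
realized mean to ≈ 21.7). Follow-up visits decay multiplicatively
(factor 0.68 per visit, Gaussian noise SD 5), emulating treat-to-target
improvement; the decay is calibrated once so the pooled visit-level mean
utility sits near the cohort's published 0.62. EQ-5D levels are drawn per
dimension as 1 + Binomial(4, 1 − u_band) under the bundled toy value set
(0.05 per level step per dimension), which makes band-mean utilities equal
the published targets (0.87/0.72/0.57/0.21) in expectation — a construction
chosen for exact recoverability, not realism. The toy value set is a
synthetic stand-in for a country tariff (e.g. the Ugandan value set) and the
generator reproduces published summary moments only: no real demographic
structure, visit-schedule irregularity, item-level response patterns or
within-patient correlation beyond the CDAI trajectory. Passing recovery
tests therefore validates the pipeline's arithmetic, not its behavior on
real questionnaires. A Gompertz-shaped synthetic female life table
(anchored at 0.004 annual mortality at age 45, slope 0.09/year) stands in
for a national life table; the cohort's age is held at 45 over the 3-year
horizon.

## Numerical choices and known limitations

* Occupancy is conserved to 1e-9 every cycle; transition rows are built
  exactly, not renormalized.
* Ties in the NMB argmax go to the lower cost, then the lower strategy id;
  in PSA share computations ties go to the cheaper base-case strategy.
* Bisection uses ≤ 200 iterations with bracket expansion above the base
  price; the result is verified in tests against a dense grid scan.
* The published three-year QALY totals (2.079–2.209) are not reproducible
  from the published utilities and transition inputs: with a maximum
  at-target utility of 0.77, 2.079 QALYs for methotrexate monotherapy would
  require ≈ 86% of discounted time at target, far above what a 43%
  first-line response with any rescue dynamic we examined can deliver
  (≈ 55–68%). The model reports ≈ 1.74–1.83 QALYs; between-strategy cost
  differences, orderings and dominance of strategy 2 match the published
  table, while the small QALY gaps leave strategy 5 on the frontier and
  raise the top frontier ICER well above the published value.
* Deterministic problem size: 6 strategies × 6 cycles on ≤ 21 expanded
  states; PSA uses 10,000 iterations; bootstrap CIs use 1,000 resamples.
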