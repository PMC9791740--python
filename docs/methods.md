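# Methods

## Model structure

The evaluation compares two strategies for pediatric Ph+ ALL in China —
chemotherapy plus imatinib (300 mg/m²/day) versus chemotherapy plus dasatinib
(70 mg/m²/day) — from the health-system perspective, for a reference
7-year-old patient with 0.8 m² body surface area.  It is a two-stage model:

1. **Decision tree** over the induction phase (imatinib 0.0795 yr, dasatinib
   0.0849 yr) and intensive chemotherapy (0.8164 / 0.6822 yr).  End states:
   CR, non-CR, death.  No induction/intensive mortality is parameterized, so
   tree death probability is 0.  Imatinib reaches no induction CR and 50% CR
   after intensive chemotherapy.  Dasatinib reaches 16.7% induction CR;
   composing the two tree rows (0.167·1 + 0.833·0.875) gives 89.6% end-CR,
   while the group-level rate is 87.5% — which of the two entered the original
   model is unknown, so both are implemented (`group_level_cr` toggle).
2. **Markov cohort model**, 10 annual cycles.  States: maintenance CR, non-CR,
   relapse, post-transplant CR (a 5-year tunnel, then a "late" state), post-
   transplant failure, death (absorbing, zero reward).  Non-CR and relapse
   share costs and utilities and both can receive HSCT.  Within a cycle the
   competing events from non-CR/relapse are treated as mutually exclusive:
   transplant 0.1 (split 0.4 success / 0.6 failure, one-off cost CNY 250,000
   charged at entry), death 0.6, stay 0.3.  The post-transplant utility clock
   (0.80 first five years, 0.86 after) counts from transplant entry, not model
   time, because the source utilities are transplant-anchored.

Annual maintenance probabilities come from 4-year trial rates through the
constant-hazard transform `p = 1 − (1 − P)^(1/T)` (implemented with
`log1p`/`expm1`; the inverse round-trips to ~1e-12 on the well-conditioned
region, and the transform reproduces the trial's printed 4-year deltas of
14.6% recurrence and 19.2% OS from the annual values in the parameter table).

## Parameters

All quantities live in `src/tkicea/data/parameters.yaml`: transition
probabilities, annual costs (2019 CNY), the one-off transplant cost, phase
durations, utilities, and the settings (horizon 10 cycles, discount 5%/yr
compound `(1+r)^-t`, WTP 70,892 CNY/QALY).  Where the source reports no
range, one-way bounds default to ±10% (probabilities) / ±20% (costs,
utilities), clipped to the support; the discount rate is varied 3–8% one-way
only and never sampled.  Durations are fixed.

For the PSA, ranges map to standard deviations by `SD = range/3.92` (range
read as a central 95% interval, the default) or `SD = range/4`; the source
never states its rule, so both are exposed (`sd_rule`).  Costs are fitted
Gamma and probabilities/utilities Beta by method of moments with mean equal
to the base value; a Beta whose implied variance is infeasible falls back to
half the maximal SD with a logged warning, and a boundary mean (0 or 1)
degenerates to a point mass.  Parameters are sampled independently (no
correlation information exists); each draw is shared by both arms, so
arm-shared quantities cancel correctly in the increments.

## Structural toggles and calibration

Seven binary choices are genuinely open given the published description:
dasatinib end-of-intensive CR composition vs group rate; TKI cost included in
CR-maintenance costs; TKI tree cost prorated by phase duration vs full-year;
half-cycle correction; start- vs end-of-cycle reward timing; tree accruals
discounted from time zero vs undiscounted; phase "other costs" as lump sums
vs prorated per year.  `calibrate_structure` evaluates all 128 combinations
and ranks them by the maximum relative deviation from the four published
base-case totals (both arms' cost and QALYs — all four matter equally).  The
winner — group-level CR, TKI in maintenance, prorated tree drug cost, tree
accruals discounted — deviates at most 1.3% on any total and is cached as the
package default.

## Agreement with the published results, and known differences

With the calibrated structure the model reproduces the published totals
within 2% (imatinib 1,012,988.90 vs 1,020,995.35 CNY and 2.556 vs 2.59
QALYs; dasatinib 1,048,832.10 vs 1,035,788.50 CNY and 4.870 vs 4.84 QALYs).
The *increments*, however, do not match: this model gives ΔC ≈ CNY 35,843 and
ΔE ≈ 2.31 (ICER ≈ 15,487 CNY/QALY) against the published ΔC = 14,793.15 and
ΔE = 2.25 (ICER 6,575.78).  No toggle combination fits the totals and the
increments simultaneously — the increments are small differences of ~CNY 1M
totals, so they are far more sensitive to structure than the totals are, and
the original TreeAge implementation is not published.  Downstream quantities
inherit this: the generic-price scenario ICER is 65,402 vs the published
58,888 CNY/QALY, the threshold dasatinib price 18,960 vs 21,928 CNY/yr, and
the 1000-draw PSA acceptability at the threshold ≈ 0.876 (range/3.92 rule;
0.890 under range/4) vs the published 0.967.  The PSA gap follows directly
from the wide published cost ranges: the four phase "other cost" ranges alone
put the iNMB standard deviation near CNY 125k, which caps the acceptability
near 0.87–0.90 even at the published iNMB of 144.7k; reproducing 96.7% would
require a substantially tighter (unpublished) range-to-variance rule.  None
of these values is adjusted toward the published ones; the acceptance tests
assert the published values and the incremental ones fail honestly.

The conclusion the model supports is directionally identical to the published
one: dasatinib is cost-effective at the CNY 70,892/QALY threshold by a wide
margin in the base case and in most PSA draws.

One published derived figure (a "cost-saving" comparison of CNY 51,100 vs
CNY 86,074.59) has no stated derivation and is not reproduced here.

## Synthetic cohort

`tkicea.cohort.simulate_patients` draws patient-level trajectories through
the identical tree and Markov dynamics (same matrix, rewards, discounting,
and toggles as the cohort engine), with the study's arm sizes (14 imatinib /
18 dasatinib) as defaults.  It emulates trajectory structure only — no ages,
sexes, or billing records, since the economic model uses none.  Its two jobs:

- **oracle equivalence**: at n = 200,000 the empirical per-cycle occupancy
  and the mean discounted cost/QALYs agree with the cohort engine within 3
  binomial/standard errors (tested per state-cycle cell and for the totals,
  for the calibrated and for alternative toggle sets);
- **parameter recovery**: transition probabilities re-estimated from the
  trajectories (events / at-risk, pooling the tunnel years, with exact
  Clopper–Pearson intervals) converge to the generating values, and at the
  study size the 95% intervals cover the truth at ≥ 93% (exact intervals are
  conservative).

Passing these tests shows the two engines implement the same stochastic
process; it does not validate the model against real patients, whose
trajectories include features (treatment interruption, re-transplantation,
background mortality, covariate heterogeneity) the model deliberately omits.

## Numerical choices

- Transition rows must sum to 1 within 1e-9 at construction; cohort occupancy
  is checked for conservation (1e-8) every cycle; negative remainders from
  pathological inputs raise instead of being clipped.
- Threshold-price inversion uses Brent root-finding to 0.01 CNY; the ICER is
  affine in any drug cost, so a bracketing sign change certifies monotonicity.
  An unbracketed target reports the achievable ICER range.
- Dominance (ΔC<0, ΔE>0 or ΔC>0, ΔE<0) is reported as a label, never as a
  negative ICER; ΔE = 0 leaves the ICER undefined and reports iNMB only.
- Tornado ties break on parameter id, making the ranking independent of
  evaluation order.
- PSA draws are generated once up front in sorted-parameter order from a
  single `numpy` generator, so the stream is a pure function of the seed.

## Problem sizes

Default analyses: 10 Markov cycles, 1000 PSA draws, 128-point calibration
search.  The microsimulation cross-checks use 200,000 patients in the
acceptance suite and 40,000–50,000 in unit tests; interval-coverage
experiments use 200–500 replicates.  All together the suite runs in well
under a minute on one CPU.

## Limitations

- The structural calibration selects among plausible conventions; it cannot
  recover details the publication never stated (see the increments above).
- No background age-specific mortality, no re-transplantation, no exit from
  the model before year 10, no treatment interruption or dose modification.
- Costs are 2019 CNY throughout; no inflation or currency conversion.
- Ranges are treated as 95% intervals (or quarter-ranges) for sampling; if
  they are in fact min–max ranges, the PSA overstates parameter uncertainty.
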