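# Methods

## Model structure

Disease progression is modelled as a discrete-time Markov cohort over
five states: WHO functional classes FC I (mildest) to FC IV (most
severe) and absorbing death. The cycle length is 3 months — long enough
for a functional-class reassessment, short enough to capture treatment
effects. Transitions are restricted to adjacent classes (FC II can reach
FC I, FC III or death within one cycle, never FC IV), which matches the
clinical reading of class switching as a gradual process and keeps each
row of the transition matrix tridiagonal-plus-death.

Treatment enters multiplicatively: each arm's worsening and improvement
probabilities are the standard-treatment probabilities times the drug's
relative risks (sildenafil RR 0.43 worsening / 4.23 improvement;
beraprost 0.10 / 0.93). Death probabilities are class-specific
(0.002/0.013/0.016/0.240 per cycle for FC I–IV) and identical across
arms: the survival benefit of an effective drug is mediated entirely by
keeping patients in lower classes. Cohorts start in FC II or FC III,
the classes for which pulmonary selective therapy is indicated.

## Outcomes and costing

State membership during cycle *k* (the occupancy at the cycle's start)
accrues 0.25 life years, utility-weighted QALYs (EQ-5D utilities 0.74 /
0.71 / 0.56 / 0.51 for FC I–IV), and cost, each discounted by
`(1+0.03)^(-0.25k)`. Half-cycle correction is available behind a flag
but off by default — the simplest reading of "QALYs = life years x
utility", and the convention the calibration below absorbs either way.

Per-cycle state costs are built from components: admissions/cycle x
cost per admission (USD 808) + visits/cycle x cost per visit (USD 21),
plus the arm's drug cost in every living state (generic sildenafil
USD 92/cycle, beraprost USD 88/cycle), plus — under the societal
perspective only — household non-medical cost. Two transcription
choices in the source table are resolved in the bundled config and are
overridable: the per-visit cost is set to 21 ± 2 USD (the unique value
consistent with all four published per-class direct-medical totals
317/368/224/404), and FC IV has no outpatient-visit row (0.50 x 808 =
404 reproduces its total exactly). Drug cost accrues in FC IV too;
the published originator-price ICER multiples are consistent only
under that rule.

## Lifetime horizon (calibrated)

The source evaluation reports "lifetime" outcomes without a horizon,
cohort age or background-mortality table, yet its undiscounted life
expectancies cap near 28 years — a finite horizon in disguise. Rather
than invent an age-mortality structure, the package calibrates a fixed
horizon once: a grid search over 20–50 years in 5-year steps picks the
horizon minimising the total absolute deviation of the model's eight
life-year outputs (two arms x two starting classes, discounted and
undiscounted) from the published values. The winner — 140 cycles =
35 years, total deviation 5.3 years vs 15.2 for the runner-up — is
stored in `table1.yaml` and used by all deterministic runs
(`analysis/01_calibrate_horizon.py` reproduces the search). An
extinction-based horizon (`fixed:`/`extinction:` modes of
`choose_horizon`) is available for exploration.

## Distribution fitting and the PSA

Every uncertain input is summarised as mean ± SE with a family, fitted
by method of moments: beta for probabilities and utilities
(`alpha = m*k`, `beta = (1-m)*k`, `k = m(1-m)/se^2 - 1`), gamma for
counts and monetary amounts (`shape = m^2/se^2`, `scale = se^2/m`), and
lognormal for relative risks (`sigma^2 = ln(1 + se^2/m^2)`,
`mu = ln m - sigma^2/2`). The source table labels the RR rows "Beta",
which cannot hold a mean of 4.23; lognormal is the standard family for
ratio parameters and reproduces both moments exactly. Because every fit
is moment-matched, the family choice does not affect the base case —
only the PSA.

The PSA draws all non-fixed inputs independently (no covariance
information exists), with common random numbers across arms for shared
parameters and arm-specific RR draws; per-cycle drug costs and unit
prices are fixed. Draw *i* is seeded from `(seed, i)`, so any draw is
reproducible in isolation. When a sampled row's worsening + improvement
+ death exceeds 1 (large RR_improvement draws; ~18% of draws at the
default inputs), the excess is removed from worsening and improvement
proportionally with death untouched — death probabilities are the
anchored survival data — and the event is counted in the run manifest.

A known consequence of the lognormal-RR choice: the FC II starting
class sits almost exactly at the threshold (base-case ICER ~3078 vs WTP
3109), so its acceptability probability is governed by the median draw.
The lognormal's median RR_improvement (3.81) lies well below its mean
(4.23), which pushes P(sildenafil cost-effective | FC II) to ~0.42
rather than the ~0.50 a symmetric family would give. The FC III
probability (~0.53–0.59 across seeds) is insensitive to this. The
family is config-overridable per parameter.

One-way analysis varies each input over mean ± 1.96 SE clipped to its
domain, others held at means, and sorts by ICER swing. The threshold
analysis bisects a multiplier on the originator tablet price
(USD 2.18/20 mg; 270 tablets/cycle ≈ 3/day, implied by USD 92/cycle at
the USD 0.34 generic price) until the binding ICER — the maximum over
FC II and FC III starts — equals the WTP within 1 USD/QALY.

## Budget impact

The payer projection is an open cohort: a prevalent pool of 8000
patients split 50/50 between FC II and FC III, plus 605 incident
patients/year with the same split, each cohort entering in its starting
class at the start of its year (year 1 = prevalent pool + year-1
incidence) and traced quarterly through the arm's matrix. The annual
budget sums occupancy x (direct medical + drug) cost — the government
pays no household costs — undiscounted, as is standard for
budget-impact analyses (a discount flag exists). Entry timing is the
one structural choice the published year-by-year table constrains but
does not uniquely identify; the rule above is exposed in the config
(`include_year1_incidence`).

## Synthetic microdata

The cost and utility inputs originate from a 48-patient interview and
billing sample (18/19/10/1 across FC I–IV). `cohort_sim` generates
records with that structure: admission and visit counts Poisson at the
class mean (nonnegative and integer-valued, where the model itself uses
gamma for the per-cycle rates — both are supported, Poisson is the
record-level default), unit costs and non-medical costs from the fitted
gammas, utilities from the fitted betas (EQ-5D dimension-level
simulation is not attempted; no tariff is available). The estimator
returns per-class means and SEs (SD/sqrt(n)), with the SE flagged
missing for n = 1 — reproducing the degenerate FC IV situation of the
source data — and pooled unit-cost moments, in the same schema as the
model config so they can feed the engine directly.

What the generator does not emulate: within-patient correlation between
resource use and utility, billing-data skew beyond the gamma shape,
measurement error in EQ-5D responses, and the sampling design of the
two referral hospitals. Passing recovery tests therefore show estimator
correctness under the assumed laws, not robustness to real-data
violations of them.

## Numerical choices and degenerate inputs

- Cycle-0 accrual at the cycle start; discount factor 1 at k = 0.
- Row sums validated to 1e-12 at construction; occupancy mass to 1e-10
  per cycle; a capped row's stay probability is clamped at exactly 0
  against float dust.
- Beta fits require `se^2 < mean(1-mean)`; infeasible moments raise at
  fit time (never silently at draw time), naming the parameter.
- `se = 0` or family `fixed` inputs are degenerate point masses
  everywhere (PSA realisations then equal the means exactly).
- One-way bounds are clipped to the family domain with a warning (e.g.
  death in FC I, 0.002 ± 0.009, clips at 0).
- ICER with zero incremental QALYs is reported as NaN with an explicit
  dominance/indifference status instead.

## Problem sizes

Deterministic runs use the calibrated 140-cycle horizon; the PSA uses
1000 draws (matching the source analysis); the brute-force
path-enumeration oracle in the tests verifies the engine at horizons up
to 8 cycles, where exhaustive enumeration is exact and cheap; recovery
tests use 100 seeded repetitions at 200 patients per class and a
1000-per-class run for pipeline closure.

## Known limitations

- Two arms only; no multi-comparator frontier, no EVPI.
- No age- or sex-dependent background mortality; "lifetime" is the
  calibrated fixed horizon above, and lifetime costs inherit its
  uncertainty.
- Independence across sampled parameters (no copulas).
- No treatment switching or uptake dynamics in the budget projection.
- Currency is USD throughout; the IDR exchange rate (13,830/USD) is
  display metadata only.
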