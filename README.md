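# pahcea — cost-utility and budget-impact model of PAH drug therapy

`pahcea` is a decision-analytic model for the economic evaluation of
pulmonary arterial hypertension (PAH) drug therapy in Indonesia,
comparing **sildenafil** (intervention) with **beraprost** (comparator)
as first-line treatment. It is aimed at health-economics and HTA
analysts: the whole evaluation — Markov cohort simulation, cost-utility
analysis, probabilistic/one-way/threshold sensitivity analysis, and a
five-year budget-impact projection — runs from a single YAML parameter
file, and every stage is importable as a library function.

## The model

Disease progression is a discrete-time Markov chain over five states —
WHO functional classes FC I–IV plus absorbing death — advanced in
3-month cycles. Only adjacent-class moves are possible within a cycle.
For a treated arm, the per-cycle switching probabilities are the
standard-treatment probabilities scaled by the drug's relative risks:

```
p(worsen | FCi) = p0(FCi -> FCi+1) * RR_worsening
p(improve| FCi) = p0(FCi -> FCi-1) * RR_improvement
p(death  | FCi) = class-specific, identical across arms
```

A cohort starting in FC II or FC III is propagated to a calibrated
lifetime horizon (140 cycles = 35 years). Cycle *k* accrues, per living
state, 0.25 life years, utility-weighted QALYs, and per-cycle cost
(direct medical + household non-medical [societal perspective] + drug),
discounted by `(1 + r)^(-0.25 k)` with r = 3%/year. The headline
statistic is the incremental cost-effectiveness ratio

```
ICER = (C_sil - C_ber) / (Q_sil - Q_ber)   [USD per QALY gained]
```

judged against a willingness-to-pay threshold of one GDP per capita
(USD 3109/QALY). Uncertain inputs carry `{mean, SE, family}` and are
sampled by method-of-moments fits (beta for probabilities/utilities,
gamma for counts/costs, lognormal for relative risks) in the
probabilistic sensitivity analysis.

## Worked example

```bash
$ pahcea run-base-case --start-fc 3
FC 3: incremental cost 4510 USD, incremental QALY 1.591, ICER 2836 USD/QALY (cost-effective at WTP 3109)

$ pahcea run-threshold
originator sildenafil becomes cost-effective at a 84.3% price reduction (multiplier 0.1568, ICER 3109)

$ pahcea run-bia
5-year incremental budget: FC II 403,293 USD, FC III 3,655,462 USD, combined 4,058,755 USD
```

Reading the numbers: from an FC III start, sildenafil costs USD 4510
more than beraprost over a lifetime but yields 1.59 extra discounted
QALYs, i.e. USD 2836 per QALY gained — below the USD 3109 threshold, so
sildenafil is cost-effective at its generic price. At the originator
tablet price the ICER rises ~8-fold (FC III) to ~19-fold (FC II); the
price would have to fall by ~84% — essentially to the generic price —
to reach the threshold. Adopting sildenafil for the eligible population
(prevalence 8000, incidence 605/year, split 50/50 FC II/III) costs the
payer an extra ~USD 4.1 million over five years.

The numbered scripts under `analysis/` run the same stages as a
narrative sequence (horizon calibration, base case, PSA + CEAC, price
sensitivity, budget impact, synthetic-cohort closure) and write their
tables under `results/`. `pahcea reproduce-results` runs the whole
chain in one command. The bundled parameter file is
`src/pahcea/data/table1.yaml`; pass `--config` to override any input.

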