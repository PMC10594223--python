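# trialcea

Trial-based economic evaluation of psychotherapy session frequency for
depression: a complete, reproducible pipeline for cost-effectiveness
analyses run alongside a randomised controlled trial.

The package is aimed at health economists and trial statisticians. It
implements the standard toolkit of a trial-based cost–utility analysis
— and, because patient-level trial data are rarely shareable, ships a
seeded synthetic-trial generator with the same statistical structure so
every stage is testable end to end.

## What it computes

The motivating design is a 2×2 factorial trial comparing twice-weekly
with once-weekly sessions of psychotherapy (CBT or IPT) for major
depression over 12 months, from a societal perspective:

- **Outcomes.** Depression severity (BDI-II, analysed longitudinally
  with time-specific intercepts, a baseline-BDI covariate and
  cluster-robust participant variance), RAND-36 physical and social
  functioning (linear 0–100 transforms), and QALYs from EQ-5D-5L
  utilities by the trapezoid rule:
  `QALY = Σᵢ ½(uᵢ + uᵢ₊₁)(tᵢ₊₁ − tᵢ)` with time in years.
- **Costs** (€, index year 2021). Intervention, mental healthcare,
  other healthcare, medication and informal care valued by a unit-cost
  table; absenteeism by the friction-cost approach (cap 12 weeks = 60
  working days per episode; human-capital valuation as a sensitivity
  analysis); presenteeism as
  `(1 − efficiency) × complaint days × hours/day × wage`;
  unpaid work at a cleaner's shadow price.
- **Missing data.** Multiple imputation by chained equations with
  predictive mean matching (donor pool k = 5), stratified by trial arm,
  with the number of imputations doubled until the fraction of missing
  information of the headline parameters falls below 5% (or a cap is
  reached), and Rubin's rules pooling:
  `T = W + (1 + 1/m)B`.
- **Uncertainty and decision outputs.** Bias-corrected-and-accelerated
  bootstrap (participants resampled within arm, costs and effects
  jointly), ICER = ΔC/ΔE, cost-effectiveness plane quadrant
  proportions, and acceptability curves from the pooled net monetary
  benefit `NMB(λ) = λ·ΔE − ΔC`, with a cloud-proportion CEAC as a
  nonparametric cross-check.
- **Sensitivity analyses.** Healthcare perspective, human-capital
  absenteeism, recoding participant-periods with societal costs
  ≥ €10 000 as missing before re-imputation, and adjustment for
  pre-treatment societal costs.

## Worked example

```python
import trialcea as tc

trial = tc.TrialConfig(seed=1)       # synthetic 2x2 trial, n=200, ~31% dropout
config = tc.AnalysisConfig(b_replications=500, m_initial=4, m_max=8, seed=1)
data = tc.make_trial(trial)
results = tc.CostEffectivenessModel(data, config=config).fit()
print(results.summary())
```

```
Cost-effectiveness analysis: twice-weekly vs once-weekly psychotherapy
==========================================================================
participants: 200   imputations m: 8   bootstrap B/imputation: 500
perspective: societal   absenteeism: friction   seed: 1

Pooled adjusted differences (twice-weekly minus once-weekly)
--------------------------------------------------------------------------
outcome                             diff                    95% CI     FMI
BDI-II (overall effect over time)       -1.82          (-3.40 to -0.24)   0.245
QALYs (12 months)                  0.011         (-0.022 to 0.045)   0.067
Physical functioning (12 months)        1.96           (-2.02 to 5.95)   0.285
Social functioning (12 months)        4.82          (-0.37 to 10.00)   0.209
Societal costs (EUR)            1,942.81      (423.79 to 3,461.82)   0.053

Cost-effectiveness
--------------------------------------------------------------------------
outcome                             ICER           NE/SE/SW/NW     p(CE)
BDI-II (overall effect over time)       1,067   0.99/0.01/0.00/0.01    0.46@1,000
QALYs (12 months)                169,619   0.75/0.00/0.00/0.24   0.12@50,000
Physical functioning (12 months)         989   0.83/0.01/0.00/0.16    0.50@1,000
Social functioning (12 months)         403   0.96/0.01/0.00/0.03    0.85@1,000
```

Reading the table: the twice-weekly arm improves depression scores by
1.8 BDI-II points on average over follow-up but costs €1 943 more per
participant, so buying one point of improvement costs about €1 067
(the ICER); 99% of bootstrapped cost–effect pairs fall in the
north-east quadrant (more effective, more costly), and at a
willingness to pay of €1 000 per BDI-II point the probability that the
higher frequency is cost-effective is 0.46. `results.plot_plane("bdi")`
and `results.plot_ceac("bdi")` draw the corresponding figures, and
`results.save("outdir")` writes the full report (JSON, CSV tables,
plots).

The same analysis is scriptable from the shell:

```sh
trialcea simulate --seed 1 --out data/
trialcea analyze --data data/ --seed 1 --out report/
trialcea all --seed 1 --out everything/      # main + 4 sensitivity analyses
```

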