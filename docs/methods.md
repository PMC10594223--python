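# Methods

This note documents the statistical procedures, the synthetic-data
generator, the default parameters and the numerical choices behind
`trialcea`, in the order the pipeline runs them.

## Design and estimands

The pipeline targets a 2×2 factorial RCT (session frequency ×
psychotherapy type) analysed by intention to treat: every randomised
participant is analysed in the assigned arm, with missing assessments
multiply imputed, never dropped. All contrasts are twice-weekly minus
once-weekly, adjusted for therapy type (the second factor). Five
estimands are reported: the overall BDI-II difference over follow-up,
the 12-month differences in QALYs, physical functioning and social
functioning, and the difference in total annual costs under the chosen
perspective.

## Outcome construction

EQ-5D-5L profiles map to utilities through an additive value set
(tariff): utility = 1 − Σ decrements, with decrements non-negative and
non-decreasing in level within each dimension, anchored at
utility(11111) = 1. The package ships an illustrative synthetic tariff
for testing; a study would supply its national tariff as a CSV
(dimension, level, decrement). QALYs are the area under the
utility-time curve by the trapezoid rule with assessment months mapped
to years as months/12 (0, 0.25, 0.5, 0.75, 1). No flooring is applied,
so tariffs allowing negative utilities can produce negative QALYs.
Utilities are *not* interpolated over missing assessments: QALYs are
computed only on completed (post-imputation) trajectories, so the
imputation stage runs first.

RAND-36 subscale raw sums are rescaled linearly to 0–100 (higher =
better); item-level recoding beyond the linear transform is instrument
documentation, not part of this package.

## Costing

Costs are valued per participant per 3-month recall period in five
categories (intervention, mental healthcare, other healthcare,
medication, informal care) plus three productivity components
(absenteeism from paid work, absenteeism from unpaid work,
presenteeism), index year 2021, no discounting over the 12-month
horizon.

- Intervention costs are attended sessions × a configurable unit cost
  (default €100/session), allocated over the first two follow-up
  periods according to the delivery schedule (twice-weekly: 80%/20%;
  once-weekly: 65%/35%). They derive from administrative session
  counts and are therefore never missing.
- The friction-cost approach values each sickness episode up to the
  friction period, interpreted as 12 weeks × 5 working days = 60
  working days. Episodes spanning recall periods are tracked by an
  episode id and capped across periods in chronological order; the
  human-capital variant removes the cap. For every participant-period,
  human-capital ≥ friction, with equality iff no episode exceeds the
  cap.
- Presenteeism: (1 − efficiency) × days with complaints × contracted
  hours/day, valued at gender-specific wages (defaults €34/h female,
  €40/h male); unpaid work at a shadow price of €15/h.
- The societal total is the sum of all components; the healthcare
  perspective keeps only the healthcare-tagged categories. The
  perspective filters totals only — components are always retained.

## Missing data

Imputation operates on a participant-level frame holding baseline
covariates (always complete), timepoint-level outcomes and
period-level healthcare and non-healthcare costs — not annual
aggregates, so the skewness structure that predictive mean matching is
meant to respect is preserved, and aggregation happens after
imputation.

Chained equations with PMM (type-1 matching): each incomplete variable
is regressed on all other frame variables among the observed cases,
coefficients are perturbed by a proper Bayesian draw, and each missing
cell receives the observed value of a donor drawn uniformly from the
k = 5 cases with the closest predicted means. Ten sweeps per
imputation; constant and collinear predictors are dropped with a
logged warning. Chains run separately within each trial arm by default
(a pooled option exists); imputed values therefore always lie in the
observed support of the participant's own arm — in particular, costs
are never negative.

Per-imputation estimates are pooled by Rubin's rules
(T = W + (1 + 1/m)B, t-reference with Rubin's degrees of freedom) and
the number of imputations is doubled — reusing earlier imputations via
per-imputation seed substreams — until the FMI of the two headline
parameters (ΔC, ΔQALY) falls below 5% or m_max (default 40) is
reached. Note that the FMI converges to the information actually
missing, not to zero: with ~30% dropout the 5% rule is typically
unattainable and the procedure stops at m_max with a warning (not an
error). This mirrors how such stopping rules behave in practice; the
cap is the effective determinant of m under heavy missingness.

## Estimation and uncertainty

Twelve-month differences come from OLS on the completed data (outcome
~ arm + therapy type, plus pre-treatment societal costs in the cost
model when the baseline-adjustment sensitivity analysis is on). The
longitudinal BDI-II effect uses a fixed-effects-by-time linear model
(time-specific intercepts, arm main effect, baseline BDI-II, therapy
type) with cluster-robust participant variance — a transparent
approximation to a mixed model that targets the same estimand, the
overall arm effect over follow-up.

Because costs are heavily skewed, uncertainty around cost and
cost-effect statistics uses a nonparametric bootstrap: participants
are resampled within frequency arm (preserving arm sizes), costs and
effects jointly (preserving their correlation), B times within each of
the m completed datasets (default B = 5000; tests and the acceptance
script use 500). Intervals are bias-corrected and accelerated: z₀ from
the share of replicates below the point estimate (ties counted half),
acceleration from jackknife skewness, endpoints by linear
interpolation between order statistics; a switch disables the
acceleration term for plain bias-corrected intervals. A degenerate
replicate distribution collapses the interval to a point with a logged
warning. Scalar bootstrap intervals are computed per imputation and
pooled via Rubin's rules on the bootstrap variances; the replicate
pairs are concatenated across imputations for the plane and the CEACs.

## Decision-analytic outputs

Effects are oriented so improvement is positive before any plane or
CEAC logic (BDI-II differences are sign-flipped; QALYs and functioning
scores keep their direction). The ICER divides the pooled cost
difference by the pooled effect difference; a zero effect difference
yields an undefined-ICER flag rather than an exception. Quadrant
proportions use a half-open convention for boundary pairs (ΔE ≥ 0
favourable, ΔC ≥ 0 more costly). The primary CEAC is parametric: per
imputation, NMB(λ) = λ·ΔE − ΔC with variance
λ²var(ΔE) + var(ΔC) − 2λcov from the within-imputation bootstrap,
pooled per λ by Rubin's rules, probability = Φ(NMB/SE); the
cloud-proportion curve is a validation surface. The default λ grid
spans €0–100 000 in 251 steps and always contains the commonly quoted
ceiling ratios (€1 000 per point; €20 000–€50 000 per QALY).

## The synthetic-trial generator

The generator's defaults are the study conditions the package is
tested under:

- cells 49/49/47/55 (96 twice-weekly, 104 once-weekly), nine sites,
  assessments at months 0, 3, 6, 9, 12; baseline BDI-II ≥ 20
  (truncated normal, mean 31, s.d. 8), severity stratum at BDI-II ≥ 29;
- permuted-block randomisation (blocks of 4) within site × severity
  stratum, emulated with exact cell quotas; blocks are processed in
  random order so the few forced assignments implied by the unequal
  arm totals scatter across strata instead of accumulating in the last
  site (processing them in sequence would systematically place the
  leftover once-weekly slots in identifiable subgroups and bias the
  arm contrast);
- BDI-II trajectories: participant random intercept (s.d. 5) plus
  residual noise (s.d. 5) around group mean curves; the default arm
  difference (0, −2, −3.5, −0.5, −2) peaks at month 6, nearly vanishes
  at month 9 and is modest at 12 months;
- utilities are generated directly (an EQ-5D-5L state-profile mode
  exists for exercising the tariff), negatively correlated with
  concurrent BDI-II through a linear link applied to BDI net of the
  arm effect — so the configured per-timepoint utility difference is
  the *total* arm difference, not an addition on top of the
  symptom-mediated channel; the defaults integrate to ≈0.0175 QALYs;
- attended sessions: truncated normal means 16.5 (twice-weekly) and
  14.7 (once-weekly) on [0, 20];
- resource use is driven by a lognormal participant frailty
  (heavy-tailed annual costs), independent of symptom level so the
  configured cost difference stays exact; with probability 0.04 per
  participant (either arm) a psychiatric-admission outlier adds very
  high mental-healthcare costs in one random period; the configured
  annual societal cost difference (default €2 000) is loaded onto
  additional mental-healthcare contacts net of the intervention-cost
  difference implied by the extra 1.8 sessions (priced at the
  reference €100/session);
- absenteeism: at most one in-trial episode per employed participant
  (probability 0.45), lognormal duration with a tail beyond the
  60-day friction period, allocated to recall periods by calendar
  overlap; presenteeism and unpaid-work losses are symmetric across
  arms;
- follow-up loss: whole assessments go missing with logistic
  probability depending on education and baseline physical functioning
  (completers are more educated and fitter — MAR given observed
  covariates, never the unobserved value) plus a shared participant
  frailty making dropout monotone-tending; intercepts are calibrated
  per timepoint so expected follow-up matches the targets
  (1, .725, .765, .70, .69 — the 6-month fraction genuinely exceeds
  the 3-month one, so the targets are fractions followed up, not a
  monotone survival curve); 2% independent item-level missingness is
  added on top and the baseline assessment stays complete. Dropout
  mechanisms are identical across arms.

What the generator does *not* emulate: therapy-process variables
(alliance, adherence, delivery quality), symptom-dependent resource
use, cost–outcome correlation beyond shared arm effects,
between-site heterogeneity, and the 24-month follow-up. Passing tests
therefore demonstrate that the *methods* are implemented correctly and
recover known truths under realistic trial structure — not that any
particular clinical conclusion transfers to real data.

## Verification sizes and observed behaviour

The test suite checks each operation against independent oracles
(hand arithmetic, exhaustive bootstrap enumeration at n = 5,
closed-form orthant probabilities, pre-masking truths) and runs a
100-replicate end-to-end recovery study at n = 200, adaptive m capped
at 8, B = 500: pooled cost and QALY differences are unbiased within
Monte-Carlo error and interval coverage is near-nominal. Coverage for
the cost difference sits a little below 95% — the familiar behaviour
of confidence intervals for heavy-tailed cost means at this sample
size, shared by the bootstrap and Rubin-pooled intervals alike. The
acceptance script uses the same reduced sizes (B = 500, m ≤ 8,
20 recovery replicates) to keep a full run around two minutes.

## Known limitations

- The longitudinal model is a cluster-robust fixed-effects
  approximation, not a random-effects mixed model; with balanced
  completed data the arm-effect estimates are very close, but variance
  components are not reported.
- Pooling bootstrap intervals across imputations uses Rubin's rules on
  bootstrap variances; fully nested bootstrap-within-imputation BCa
  pooling has no consensus standard.
- The outlier sensitivity rule defaults to recoding *all* period costs
  of a flagged participant (conservative); a flag restricts recoding
  to the offending period only.
- Currency indexation beyond a single price year, multi-arm net-benefit
  regression, and value-of-information analysis are out of scope.
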