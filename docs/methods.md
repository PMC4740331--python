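# Methods

`hbocsim` models how identifying BRCA1/2 mutation carriers in a mammography
population — and the carriers' subsequent uptake of risk-reducing surgery —
translates into fewer breast and ovarian cancers over a 30–40-year horizon.
It has four computational parts: penetrance calibration, a deterministic
cohort model, screening-cascade accounting, and an individual-level
Monte-Carlo microsimulation used as a cross-checking oracle.

## Penetrance model

Carrier risk is represented as a per-year discrete hazard `h(a)` (probability
of onset in year `[a, a+1)` given cancer-free at age `a`), ages 0–85.
Cumulative incidence follows the life-table identity
`F(a) = 1 − ∏_{j<a}(1 − h(j))`.

Because full per-year penetrance tables are rarely printed, schedules are
calibrated from cumulative-risk anchors. Within each band between anchors
`(a1, F1)` and `(a2, F2)` the hazard is the constant solving
`(1−F2) = (1−F1)(1−h)^(a2−a1)`; the final band is held constant through age
85. The defaults are the four widely cited age-70 risks: breast 57%/49% and
ovarian 40%/18% for BRCA1/BRCA2. Calibration reproduces every anchor to
1e-9 by construction, and the module accepts arbitrary anchor sets so that
richer decade-wise tables can be dropped in. Hazard is zero below a
configurable `start_age` (default 25): hereditary breast/ovarian risk before
25 is negligible and the model's at-risk window starts at 35 anyway.

Whether the original calculators interpolated yearly or decade-wise
penetrance is generally unknowable from published summaries; the anchor-based
piecewise-constant schedule is this package's explicit, documented choice.

## Deterministic cohort model

State is an expected (real-valued) count of carriers per
(gene × site × intervention arm × entry age) stratum. Women enter at their
observed age (18–85); those aged 35–85 and cancer-free form the at-risk
pool. Prevalent cases are removed at window entry by multiplying carriers by
`1 − F_site(entry age)`; women aged 18–34 are dormant until they reach 35,
at which point `1 − F(35)` is applied. Each simulated year, every active
stratum loses `at_risk × h(age)` women from the pool and the pool is reset
before the next year; strata exit at age 85.

Identified carriers (a `detection_rate` fraction) are partitioned at entry
into arms by independent surgery-uptake fractions: none, mastectomy-only,
oophorectomy-only, both (product of uptakes). All surgeries happen at
identification (cohort entry).

**Efficacy accounting.** Surgical protection is applied as proportional
case scaling (thinning): the *counted* incident cancers in an arm are the
arm's risk ratio times the pool exits, while the pool itself is depleted by
the unthinned exits in every arm. Default ratios: mastectomy 0.05 on
breast; oophorectomy 0.05 on ovarian, plus 0.50 on breast when the surgery
happens before age 50 (the cutoff applies to surgery age, and the
protection then persists). In the both-surgeries arm breast protection uses
the mastectomy ratio alone — compounding 0.05 × 0.50 to a 97.5% effect is
not supported by the efficacy literature the assumptions come from. This
scaling construction has two properties the package relies on:

- full detection and full uptake yield *exactly* the assumed protection
  (95% / 95% / 50% reductions) regardless of the age distribution, which is
  how the efficacy assumptions are stated; a multiplicative hazard ratio
  would instead give age-structure-dependent reductions (e.g. ≈93.6% rather
  than 95% for ovarian at the age-85 horizon);
- conservation holds per stratum every year:
  `entry count = still at risk + cumulative pool exits`, with counted
  cancers equal to ratio × exits.

The percent reduction at a horizon is
`100 × (1 − cumulative_intervention / cumulative_baseline)`, 0 when the
baseline is 0. Arms are compared by a Pearson 2×2 chi-square on
{cancer by horizon, no cancer} × {baseline, intervention} with rounded
expected counts; any cell expectation below 1 sets a warning flag on the
result instead of raising.

## Screening-cascade accounting

Funnel counts (screened → informative → RST-positive → referral accepted →
attended → tested → carriers detected) are stored only as integers; every
percentage is re-derived at report time. Steps whose integer counts were
never published are left absent and their rates reported as undefined
rather than invented — the pooled participation numerator/denominator
(92,127 / 96,055) therefore lives in a small "combined" fixture, alongside
the two per-population fixtures. Expected carrier counts use
`n × [(1−aj)(f1+f2) + aj × aj_rate]` with defaults f1 = 0.058%,
f2 = 0.068%; the Ashkenazi fraction and carrier rate are exposed because
published expected counts are often not reproducible from the base
frequencies alone (61,924 × 0.126% = 78.0, not 85). Advanced-stage
fractions count stages III–IV over known stages, excluding unknowns from
the denominator; surgery-uptake rates are restricted to eligible carriers
(oophorectomy: over 35 with at least one intact ovary; mastectomy: female
carriers) with denominators always reported. Rounding matches reporting
convention: one decimal for funnel rates, nearest integer for stage
fractions.

## Synthetic populations and the microsimulation oracle

The generator draws one row per woman: integer age from a truncated normal
(mean 52, sd 12, bounds 18–85 — the mean matches the average carrier age of
≈52 in the study population; the true hospital age distribution was never
published), BRCA status as Bernoulli draws at the population frequencies,
and Bernoulli progression through each cascade step (defaults: 95.9%
participation, ~5% RST flag rate, 51% referral acceptance, 50% attendance,
76% testing uptake — the underserved-population values). Carrier RST
sensitivity defaults to 1.0 (no published estimate of carriers screening
negative) and is configurable; the non-carrier flag probability is solved
so the marginal flag rate hits the ~5% target.

Onset ages are drawn by exact inverse transform on the calibrated
cumulative curve (equivalent in distribution to year-by-year Bernoulli
draws at `h(a)`); surgical protection is Bernoulli thinning of the sampled
event at the arm's risk ratio — the individual-level counterpart of the
cohort model's case scaling. Scenario comparisons use common random
numbers: ages, carrier status, onset, detection/uptake and thinning
uniforms are drawn once and shared between the baseline and intervention
arms, which makes 3-standard-error agreement testable at n = 200,000 in
seconds. The reported Monte-Carlo standard error is exact-binomial:
conditional on the baseline cases, each survives into the intervention
count with a computable probability `k_i` (marginal over arm assignment
and thinning), so `SE = sqrt(Σ k_i(1−k_i)) / ΣX`.

What the generator does *not* emulate: family pedigrees (carrier status is
i.i.d.), the content of the RST questionnaire, stage at diagnosis,
competing mortality, or correlation between age and cascade adherence.
Passing oracle-equivalence tests therefore shows the deterministic and
stochastic implementations agree under the model's own assumptions, not
that the model captures every feature of a real mammography population.

## Problem sizes and numerical choices

- Default simulation population: 186,537 women (the cohort size the study
  design contemplates), truncated-normal ages; single-age cohorts of
  100,000 for the exact efficacy limits.
- Microsimulation checks run at n = 200,000 women (~250 carriers at the
  0.126% combined frequency) across a grid of seven scenarios including the
  two named ones.
- All Monte-Carlo code takes a single integer seed through
  `numpy.random.default_rng`; identical seeds give bit-identical
  populations, fixtures and summaries. JSON summaries are written with
  sorted keys and unrounded values (plus printed-precision strings) so
  reruns are byte-identical.
- Degenerate inputs: zero baseline cancers → reduction reported as 0;
  all-zero chi-square tables → NaN statistic with the low-expectation flag;
  zero denominators in cascade rates → undefined (`None`), never an
  exception.

## Known limitations

- No competing (non-cancer) mortality, second primaries, or contralateral
  disease; reductions are therefore upper bounds on what an ageing cohort
  would realise.
- Surgery timing is simplified to "at identification"; staggered uptake
  would dilute early-year reductions.
- The oophorectomy→breast 50% protection is carried as an assumption;
  more recent literature questions its size.
- Headline scenario reductions depend on the age distribution; with the
  synthetic default they are indicative (ordering and ranges), not
  reproductions of any specific hospital population.
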