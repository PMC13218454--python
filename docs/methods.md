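# Methods

`acescreen` implements a decision-analytic cost-utility model of baseline
laboratory screening — acetylcholine-receptor antibody (AChR-Ab) serology
and a thyroid function panel (TSH, FT3, FT4) — in patients presenting with
acquired comitant esotropia (ACE) and no overt signs of myasthenia gravis or
thyroid eye disease. Three strategies are compared from a healthcare-sector
perspective in 2024 Thai baht: no routine screening (symptom-triggered
testing), universal baseline screening, and targeted screening of a fixed
30% high-risk fraction of the cohort.

## Model structure

**Decision tree (first year).** For each test, prevalence *p* and accuracy
(Se, Sp) partition the cohort into
TP = p·Se, FN = p·(1−Se), FP = (1−p)·(1−Sp), TN = (1−p)·Sp.
The two diseases are mutually exclusive and the tests conditionally
independent (at prevalences of 2.7% and 0.9% the joint-disease mass is
negligible, and the tree has parallel branches). Each branch maps to an
initial Markov state: TP → diagnosed/treated disease, FN → undiagnosed
disease, FP and TN → idiopathic ACE. Every arm is charged a baseline
MRI (performed for all ACE patients regardless of strategy, so it cancels
from every increment); screening arms add the test panel
(1,900 + 170 + 170 + 150 = 2,390 THB/patient), chest CT for every serologic
positive (thymoma evaluation), and two extra work-up visits per false
positive.

**Markov cohort model.** Seven states over 10 annual cycles:
idiopathic ACE, ocular MG early-diagnosed, ocular MG undiagnosed (delayed),
generalized MG, hypothyroidism treated, hypothyroidism undetected, and
death (absorbing, background mortality only). Undiagnosed patients convert
to the corresponding diagnosed state at the symptom-triggered detection
rate, paying the diagnostic work-up (test + chest CT for MG; thyroid panel
for hypothyroidism) at that cycle as a transition toll. Everyone alive
attends two follow-up visits per year for the first three years
(6 × 750 = 4,500 THB undiscounted). Disease-specific annual treatment costs
are schema fields defaulting to 0 so the base case is reproducible from
publicly printed unit costs alone; users with access to local tariffs can
supply them.

**Discounting and half-cycle correction.** Costs and QALYs are discounted
at 3%/year. Each cycle contributes the trapezoidal average of its boundary
occupancies weighted by the end-of-cycle discount factor, so a full-health,
no-mortality cohort accrues exactly the annuity (1 − 1.03⁻¹⁰)/0.03 =
8.530203 QALYs per patient over the horizon. Trapezoidal averaging is the
conventional reading of "half-cycle correction"; pairing it with midpoint
rather than end-of-cycle discount factors would scale all totals by a
uniform 1.5% and cancel from every ICER comparison direction.

**Two QALY accounting modes.** Published cohort totals for models of this
kind appear on two different scales: an *accumulated* scale (utility ×
person-time, ≈ 8.5 QALYs/patient over 10 discounted years) and an
*endpoint* scale (discount-weighted average utility, ≤ 1 per patient).
The engine computes both — `endpoint` is `accumulated` divided by the
discounted horizon weight — records the mode in every result, and refuses
to mix modes in an incremental comparison. The accumulated mode is the
default for all sensitivity analyses.

## Parameters

Every field carries a provenance label (`paper` / `default` / `user`) and
the loader logs all fields filled from defaults. Key values:

| parameter | base value | provenance |
|---|---|---|
| MG prevalence | 0.027 (3/110) | paper |
| hypothyroidism prevalence | 0.009 (1/110) | paper |
| AChR-Ab Se / Sp | 0.75 / 0.98 | paper |
| TFT Se / Sp | 0.90 / 0.92 | paper |
| utilities: early OMG / delayed OMG / treated or delayed hypothyroid / idiopathic | 0.872 / 0.739 / 0.94 / 1.00 | paper |
| generalized-MG utility | 0.739 (set to delayed OMG) | default |
| discount rate / horizon / cohort | 3% / 10 y / 110 | paper |
| WTP band | 160,000–200,000 THB/QALY | paper |
| targeted fraction | 0.30 | paper |
| background mortality | 0.005/yr | default |
| OMG → generalized | 0.05/yr | default |
| incident disease from idiopathic | 0/yr | default |
| symptom-triggered detection | 0.25/yr | default |

The annual transition rates are nowhere published for this model; the
defaults above are deliberately simple placeholders (flat background
mortality of order the all-ages Thai rate; a modest ocular-to-generalized
conversion; a detection rate implying a mean of ~4 undiagnosed years).
They are fully overridable, flagged `default`, and eligible for both
sensitivity analyses. Because of this, the package's own base-case cohort
totals are *its own* results, not reproductions of the published totals;
only quantities that are pure arithmetic on printed numbers (incremental
costs/QALYs, ICERs from the strategy tables, the beta/gamma
parameterization) are reproduced exactly.

**A structural note on the targeted strategy.** The targeted arm is an
exact convex blend: fraction *f* of the cohort follows the universal
pathway, 1−f the no-screening pathway. Linearity then forces
ΔC and ΔQ of the targeted arm to be *f* times those of the universal arm,
so the targeted and universal ICERs against no screening coincide exactly.
A published pair of *different* ICERs for a proportional strategy implies
additional unprinted asymmetries (e.g. different downstream accounting);
this package reports the mathematically consistent equal-ICER result.

## Sensitivity analyses

**One-way DSA.** Each parameter is varied ±20% and the swing in the net
monetary benefit of universal vs no screening at 160,000 THB/QALY is
tabulated tornado-style. Parameters near the ceiling of [0, 1] — test
accuracies and utilities — are varied on their complement scale (error
rate, disutility): ±20% on a specificity of 0.98 would otherwise clip at
1.0 and produce clip-dependent, asymmetric bars, and "the utility decrement
of undiagnosed MG" is then a single varied quantity. Prevalences,
transition rates and costs vary on their natural scale; any residual
excursion outside [0, 1] is clipped with a logged warning. Under the base
case the three dominant parameters are the delayed-MG utility decrement,
the AChR-Ab test price, and MG prevalence; the MRI price swings exactly
zero because it is charged identically in both arms.

**PSA.** 10,000 independent Monte-Carlo draws by default. Probabilities
and utilities draw from beta distributions parameterized as α = p·n,
β = (1−p)·n, with n taken from the observed counts where available
(prevalences: n = 110) and n = 100 otherwise; the full-health idiopathic
utility is a point mass (a beta with p = 1 is degenerate). Costs draw from
gamma distributions with k = μ²/σ², θ = σ²/μ at a 20% coefficient of
variation — reading "variance ±20% of the mean" as CV = 0.2, since a
variance literally equal to 0.2μ has squared-baht units and would imply
absurdly tight costs. Draws where the delayed-OMG utility exceeds the
early-OMG utility are clipped to the admissible ordering (≈1% of draws).
Each parameter has its own child stream spawned from the root seed, so
results are bit-reproducible and adding a parameter does not disturb the
others' draws. Per draw both pure strategies are re-evaluated and
(ΔC, ΔQ) recorded; the CEAC is the fraction of draws with λ·ΔQ − ΔC > 0
over a 0–500,000 THB/QALY grid.

**Two-way threshold analysis.** The ICER of universal screening is
recomputed deterministically on a grid of AChR-Ab price (0–3,000 THB,
step 100) × MG prevalence (0.5–10%, step 0.25%), and cells below the WTP
threshold (or dominant) are flagged. Under the default transition rates
the base-case cell (2.7%, ฿1,900) is far from the cost-effective region;
the exact boundary location depends on the unprinted transition rates and
should be read qualitatively.

## Synthetic cohorts

`generate_cohort` emulates the published sample: Bernoulli(0.5) sex,
categorical esotropia type (7.2 / 46.4 / 46.4%), age from a normal(30.3,
20.5²) truncated to [3, 84] (the truncation raises the mean by ≈1.5 years
relative to the printed 30.3; this bias is accepted and visible in
summaries), mutually exclusive disease statuses at the base prevalences,
and test results drawn through Se/Sp conditional on true status. Refraction
and onset duration are log-skewed cosmetic covariates matched to the
printed median/mean and clipped to the printed ranges; the economic model
never reads them. The generator does **not** emulate: correlation between
age/sex and disease status, the individual clinical narratives of the four
real positive patients, or any secular trend over the 2014–2024 accrual
window — so passing cohort tests demonstrate marginal fidelity, not joint
realism.

## Numerical choices and degenerate inputs

- All internal arithmetic is per-patient in double precision; cohort totals
  are ×110 at report time and THB amounts are rounded only for display.
- Row-stochasticity, absorbing death, and mass conservation are validated
  to 1e-12/1e-9; outflow sums above 1 raise with the offending state named.
- ICERs are undefined (not infinite) at ΔQ = 0; dominance is then reported
  instead, and the WTP verdict refuses to classify an undefined ICER
  without dominance.
- Probabilities may be written as proportions or explicit percent strings;
  bare numerics above 1 are rejected to block silent 100× errors.
- Degenerate PSA inputs (p ∈ {0, 1}) become point masses rather than
  invalid beta distributions.

## Problem sizes

Default analyses: 10,000 PSA draws (~5 s), a 31 × 39 threshold grid
(~1 s), 15 tornado parameters (<1 s). The test suite uses 2,000 PSA draws
for the qualitative structure checks and n = 100,000 cohorts for margin
recovery; both sizes give Monte-Carlo errors far below the tested
tolerances.

## Known limitations

- The Markov transition rates are package defaults, not published values;
  absolute QALY and cost totals inherit that uncertainty (the sensitivity
  machinery exists precisely to explore it).
- No age-specific life tables, relapse states, or treatment adverse
  events; the thyroid pathway carries no utility decrement for undetected
  disease (treated and delayed hypothyroidism share 0.94), so thyroid
  screening contributes cost but essentially no QALY change.
- The targeted strategy is a proportional cost-reduction scenario, not a
  risk-enriched strategy: no differential prevalence or triage accuracy is
  modeled.
- PSA draws are independent across parameters; no correlation structure or
  structural (model-form) uncertainty is represented.
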