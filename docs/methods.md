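# Methods

## Clinical definitions

All thresholds live in `RunConfig`; none are hard-coded.

**Blood pressure.** Each subject carries three seated readings.  The final
systolic/diastolic pressure is the arithmetic mean of readings two and
three; the first reading is an accommodation measurement and is ignored.
Pulse pressure is SBP − DBP.

**Hypertension** is SBP ≥ 140 mmHg *or* DBP ≥ 90 mmHg (component-wise OR,
the standard reading of "≥ 140/90") *or* current antihypertensive
medication.  **Pre-hypertension** among non-hypertensives defaults to the
conjunctive window 120 ≤ SBP < 140 *and* 80 ≤ DBP < 90; the conventional
disjunctive (JNC-7 style, either component in its window) reading is
available as `prehtn_semantics: jnc7_or`.  Both are implemented because the
two conventions genuinely disagree on mixed-window subjects and the choice
materially changes the pre-HTN fraction (the AND form is roughly the
intersection, the OR form the union); neither is asserted as the only
defensible one.

**Treatment** is ≥ 20 antihypertensive medication-days per month; missing
medication-days count as untreated (conservative; such records are mostly
excluded upstream anyway).  **Control**, evaluated among treated subjects
only, uses strict inequalities at the elderly treatment target:
SBP < 150 and DBP < 90, with per-component flags and their conjunction.

**eGFR** uses the 2009 CKD-EPI creatinine equation with sex-specific
κ (0.7/0.9) and α (−0.329/−0.411) terms and the race coefficient fixed at
1 (East-Asian cohort; no race adjustment is used anywhere in the
pipeline).  CKD is eGFR < 60 mL/min/1.73 m².

**Diabetes** is fasting glucose ≥ 126 mg/dL, hypoglycemic medication or
insulin, or physician diagnosis; impaired glucose tolerance is
100–125 mg/dL inclusive.  **Dyslipidemia** is any of: total cholesterol
≥ 240 mg/dL or lipid-lowering medication, triglyceride ≥ 200 mg/dL,
HDL < 40 mg/dL.  **Smoking** is ≥ 5 lifetime packs or current smoking.
**Exercise** is vigorous activity ≥ 3 sessions/week of ≥ 20 min, or
moderate activity or walking ≥ 5 sessions/week of ≥ 30 min (walking shares
the moderate thresholds — the definition attaches walking to the moderate
clause).  BMI is weight/height²; obesity uses the Asian-Pacific cutoff
BMI ≥ 25 kg/m².

## Exclusions

Records missing any blood-pressure reading, or the hypertension medication
questionnaire, are excluded before analysis, in that order of precedence;
both reason codes are reported and the kept/excluded sets always partition
the input.

## Frailty index

The FI is the ratio of deficits present to deficits assessed over a
42-item codebook (11 comorbidities, 8 functional abilities, 8
signs/symptoms, 13 laboratory values — including the summarized SBP and
DBP — and 2 lifestyle items).  Classification: robust FI ≤ 0.10, pre-frail
0.10 < FI ≤ 0.21, frail FI > 0.21, with the boundary values inclusive
exactly as stated.

Per-item scoring rules are *data*: a TSV codebook maps every item to a
score in [0, 1] via a binary rule, an ordinal map (none 0 / moderate 0.5 /
severe 1), or threshold bands cutting a continuous laboratory value into
{0, 0.5, 1} at clinical reference limits declared item by item.  No
published per-item coding exists for this instrument, so the shipped
codebook is a reconstruction following standard deficit-accumulation
practice; all cutpoints are editable without touching code, and nothing in
the test surface claims item-level fidelity — validation rests on group
counts and synthetic recovery.

Missing responses score as missing, never 0.  The denominator is the
number of items actually assessed, with an 80% completeness floor
(⌈0.8 × 42⌉ = 34 items); below it the FI is undefined and the record is
flagged rather than classified.  Blood-pressure items are coded from the
measured (treatment-unadjusted) summary BP.

## Statistics

Continuous group comparisons use the pooled-variance unpaired t-test for
two groups and one-way ANOVA for three or more; proportions use the
Pearson chi-square without continuity correction (group sizes here are
large and the correction convention is otherwise arbitrary).  Logistic
models are maximum-likelihood fits (statsmodels) reported as OR = exp(β)
with Wald 95% CIs exp(β ± 1.96·SE) and Wald p-values; factors are
dummy-coded against declared reference levels (robust for frailty status,
normoglycemia for the diabetes/IGT factor).  Complete-case analysis
throughout, with the n actually used reported per fit.  Perfect or
quasi-separation and non-convergence raise explicit errors naming the
culprit term.  Frailty status as a 3-level outcome is fitted as one
multinomial logit with robust as reference (two separate binary fits are
available; the multinomial is the default because a single model keeps the
two contrasts internally consistent).  Two-tailed α = 0.05; no
multiple-testing adjustment.

The U-shape profile bins the cohort's summary SBP (default 10 mmHg) or
DBP (5 mmHg) into half-open bins spanning the observed range and reports
per-bin mean FI and n; bins with n < 20 are flagged and ignored when
locating the minimum.

Percentages in reports are recomputed from counts at display time, one
decimal, round-half-up; zero-denominator rates render as `NA`, never 0.0.

## Synthetic cohort

One scalar liability z ~ N(0, 1) drives everything — the simplest
structure that reproduces every qualitative finding at once:

* **Deficits.** The 40 non-BP items share one loading,
  P(deficit | z) = σ(−1.419 + 0.546·z), realized as questionnaire answers
  or as laboratory values drawn inside the codebook's healthy/deficit
  bands (so pipeline coding recovers the planted deficit exactly, and the
  pooled deficit count is exactly Binomial given z).  The two BP items are
  coded downstream from the generated blood pressure.
* **Cascade.** HTN ~ σ(0.499 + 0.276·z); treatment given HTN
  ~ σ(1.435 + 0.628·z); control given treatment ~ σ(1.413 − 0.039·z).
  These six numbers were calibrated once against the quadrature oracle so
  the defaults yield class fractions ≈ 0.17/0.39/0.44 and class-wise
  prevalence ≈ 0.49/0.61/0.68, treatment ≈ 0.75/0.75/0.86 and control
  ≈ 0.88/0.81/0.78.  The direct control slope is small because most of the
  class gradient in control arises structurally: uncontrolled subjects
  acquire BP deficit points, which pushes them toward the frail class.
* **Blood pressure.** Given the drawn cascade status, the summary BP
  comes from a status-consistent truncated normal whose mean carries a
  quadratic frailty term in max(z, 0)²: frail subjects are pulled toward
  the low-BP extreme when their status is on the low side (normotensive,
  controlled) and toward the high-BP extreme otherwise.  This plants the
  U-shaped mean-FI-vs-BP profile.  A symmetric ±γz² term does *not* work:
  non-hypertension already selects negative z, so a symmetric pull floods
  the low-BP tail with very robust subjects and inverts the shape.
  Readings two and three are built symmetric about the drawn summary value
  (their mean reproduces it bit-for-bit, so planted statuses are recovered
  exactly); reading one carries independent N(0, 6 mmHg) noise and is
  discarded by the pipeline.
* **Demographics and covariates.** Age truncated-normal (≥ 65) with a
  mild frailty slope; sex, smoking, activity, labs, sodium, income and
  education with plausible z-dependence.  These are calibration goals for
  the marginal means and gradients, not claims of distributional fidelity
  to any real survey.  In particular the joint SBP–DBP distribution is not
  calibrated, so the conjunctive pre-HTN fraction in synthetic cohorts
  (~4%) is well below a real elderly survey's (~21%); pre-HTN reproduction
  is therefore anchored on the published count fixture, not the generator.
* **Missingness** is zero by default; the screening fixture plants exactly
  10 BP-missing and 195 questionnaire-missing records among 4,557.

`expected_cascade` integrates the same model over z by quadrature
(trapezoid on [−6, 6], 1201 nodes): per status category it combines the
exact Binomial(40, p(z)) deficit count with the exact truncated-normal
band probabilities of the two BP items, conditioning on the category so
the FI-class/cascade coupling is handled without approximation.  The only
neglected effect is the rare floor that keeps a drawn SBP at least
5 mmHg above the drawn DBP (negligible probability mass).  With
`include_bp_items=False` the oracle classifies on the 40-item deficit-only
FI, under which zeroed slopes give exactly equal rates across classes —
used by the null-calibration tests.

## What passing tests do and do not show

The synthetic cohort validates the *machinery*: definitions applied
correctly, exact count bookkeeping, planted gradients and the U-shape
recovered, regression CIs with nominal coverage, chi-square agreeing with
its exact permutation null.  It does not validate the codebook's clinical
cutpoints against real survey data, survey design effects (weights,
strata, clustering are out of scope), or item-level deficit prevalences,
and real-data coefficients are not expected to be reproduced numerically.

## Numerical conventions and problem sizes

Deterministic seeding end to end: one integer seed yields byte-identical
cohorts and report bundles.  Boundary comparisons follow the stated
inclusivities (≥ 140, ≥ 20 days, < 150/90, ≤ 0.10, ≤ 0.21, ≥ 126,
100–125 inclusive, ≥ 240/200, < 40, ≥ 25).  Test problem sizes were chosen
so each check is decisive at desk scale: 4,557 for the exclusion fixture,
20,000 for U-shape and OR recovery, 50,000 for oracle agreement (±1.5
percentage points), 200 replicates for CI coverage, 200 tables of n=1,000
for the chi-square/permutation comparison — the permutation null there is
enumerated exactly (multivariate hypergeometric), removing Monte-Carlo
noise from the oracle side, and compared by mid-P, the standard convention
when a discrete null meets a continuous asymptotic p.

## Known limitations

* The deficit codebook is a reconstruction; ordinal severity maps and
  laboratory cutpoints are defensible defaults, not the survey's coding.
* The generator's single-liability structure makes all deficits
  conditionally independent given z; real deficits cluster (e.g. the
  diabetes item, glucose, and medication flags co-occur more strongly).
* Self-reported comorbidity items are generated independently of the
  corresponding laboratory values (coherent only through z).
* No survey weights/strata; estimates are unweighted complete-case.
* The exact permutation oracle is implemented for 2×3 tables; larger
  tables fall back to the sampled Monte-Carlo permutation check.
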