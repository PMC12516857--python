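# Methods

## The two-phase design and its estimator

The pipeline models a population study in which every cohort member is
screened with high-sensitivity instruments (Phase 1) and those above a
cut-off are invited to structured diagnostic interviews (Phase 2). Two
assumptions carry the estimator:

1. **Screen-negatives are non-cases.** The screens trade specificity for
   sensitivity, so a negative screen is taken as absence of the disorder.
   If sensitivity is below 1 this assumption biases prevalence *downward*
   by roughly `(1 − sensitivity) × prevalence`; the test suite asserts this
   direction empirically.
2. **Missing at random given screen status.** Screen-positives who were
   never interviewed are assumed to have the same prevalence as interviewed
   screen-positives, which justifies scaling the non-interviewed count `NI`
   by the interviewed case rate `D/(D+ND)`.

Under both assumptions the estimator is unbiased; the replicated recovery
study (500 cohorts of N = 2,000, response 0.5) checks that the mean
estimate sits within 3 Monte-Carlo SE of the configured truth in every cell
with an expected interviewed-case count of at least 5, and that an
informative-attrition variant (response odds of latent cases halved) is
flagged by a sign test.

**Inestimable cells.** When `NI > 0` but `D + ND = 0` the interviewed case
rate is undefined. Returning 0 would bias small groups low, so the
estimator raises instead, and the pipeline records the cell as
*inestimable* and excludes it from comparisons and the mean-diagnosis row.
With realistic small minority cells and ~50% response this occurs
regularly; it is a property of the design, not an error of the software.

**Sub-cohort imputation (gambling/gaming).** One of the study's two school
sub-cohorts never received the gambling/gaming questionnaire screens;
members of it were screened by the interviewer only when reached for a
M.I.N.I. or ADDIS interview (a positive interviewer screen then led to the
NODS/IGDS interview in the same call, so those entities accrue no `NI` in
sub-cohort 1). Never-screened members enter `NS1` and are imputed at
`PD2`, the adjusted prevalence among sub-cohort-2 members *not* reached
through the other interviews — the subset most comparable to the
never-screened. `PD2` is computed within the analysis group's own records
(keeping the estimator unbiased when groups genuinely differ) and is itself
attrition-adjusted, since that subset was screened and selectively
interviewed. An empty reference subset is an inestimable cell.

**Composites.** "Any anxiety disorder" (panic disorder, agoraphobia, social
anxiety, OCD, PTSD, GAD) and "at least one of all 20" are person-level
unions: `D` counts persons with ≥1 member diagnosis (multimorbid persons
once), `ND` persons whose every screen-indicated member entity was followed
up without a member diagnosis, `NI` persons with an indicated-but-missing
follow-up and no recorded member diagnosis. Persons with no indication for
any member contribute only to `T`, consistent with assumption 1. The union
deliberately omits the `PD2·NS1` term — a never-administered gambling
screen is treated as no indication — which can slightly understate the
all-20 composite in sub-cohort 1; the single-entity estimates are
unaffected.

**Mean diagnosis count** is the sum of the 20 adjusted prevalences
(expected diagnoses per member), so the attrition adjustment is inherited;
under complete response this equals the per-person average, which the tests
verify on hand fixtures.

## Group construction

Orientation comes from two 3-level attraction items; only the *at all* vs
*not at all* contrast matters (asexual = neither, homosexual = same-sex
only, heterosexual = opposite only, bisexual = both), and any missing item
makes the record unclassified — excluded from orientation analyses but
retained for the gender-discontent (GD) contrast, whose denominators differ
(per-question non-response is kept as missing, never imputed). GD pools
"doubts" and "not at all comfortable" responses and is analysed with legal
genders pooled, the published rule for a group this small (n ≈ 16); a
stratified variant exists behind a switch but defaults off. Orientation
analyses are gender-separated throughout.

## Statistics

Relative risk is computed from unrounded prevalences and displayed at 2 dp
(half-up); it is undefined, and rendered "-", unless both prevalences are
positive. Group differences use a Pearson chi-square without continuity
correction on adjusted case counts rounded to the nearest integer — the
plainest reading of "tested against the chi-square distribution" — with the
test isolated behind one function so Yates or Fisher variants can be
swapped in, and a flag marking tables with any expected cell below 5. No
multiple-testing correction is applied; every p-value is marginal. Star
codes: `*` p<0.05, `**` p<0.01, `***` p<0.001 (strict inequalities).
Display rounding is decimal half-up: percentages at 1 dp, RRs and mean
counts at 2 dp.

## The synthetic-cohort generator

The generator emulates the sampling design the estimator was built for,
with defaults calibrated to the emulated study's printed margins:

| parameter | default | basis |
|---|---|---|
| `N` | 949 | analytical sample size |
| `female_fraction` | 528/949 ≈ 0.556 | published gender split |
| `orientation_probs` | per-gender, ∝ (11, 18, 101, 385) F and (14, 10, 23, 361) M | published cell counts |
| `gd_prob` | 16/941 ≈ 0.017 | published GD rate |
| `item_missing_probs` | attraction ≈ 0.0138/item, contentment ≈ 0.0084 | published item response (923 and 941 of 949) |
| `true_prevalence` | published column estimates / 100 per gender × orientation stratum; GD override from the GD column | published prevalence table |
| `screening_sensitivity` | 0.95 per instrument | "generous cut-offs", high sensitivity |
| `screening_specificity` | 0.70 per instrument | reasonably high specificity |
| `interview_response_prob` | 387/758 ≈ 0.511 | published Phase-2 participation |
| `subcohort1_fraction` | 0.5 | two school cohorts of similar size (not printed) |

Instrument-level specificity is split geometrically across an instrument's
entities (per-entity specificity `spec^(1/k)` for `k` entities), so the
instrument-level false-positive rate matches the configured value; with
0.70 per instrument the expected overall selection rate is ≈ 0.80,
matching the published 758/949. Per-entity sensitivity is applied as
printed. Diagnoses are drawn independently across entities within a person
— comorbidity structure is not modelled, so the composite and
mean-diagnosis rows of a synthetic table will not reproduce a real
population's comorbidity, only its margins.

Diagnoses are revealed (as the latent truth) only for screen-positive
entities whose owning instrument was interviewed — an interview opens a
module only on screening indication. Interview response is one person-level
Bernoulli applied to every instrument the person screened into (one phone
contact covers all selected instruments). Informative attrition multiplies
the response *odds* of persons with any latent diagnosis; 1.0 is the MAR
identity.

**RNG contract.** One root seed feeds a `SeedSequence`; independent child
streams are derived in a fixed order — demographics, identity items,
missingness, response, then per-entity truth/screen stream pairs appended
in catalog order — so adding entities to the catalog never perturbs earlier
draws, and equal configs with equal seeds yield byte-identical cohorts.

**What the no-noise limit shows.** `no_noise_config` sets sensitivity,
specificity and response to 1, removes item non-response, and places
everyone in sub-cohort 2 (every member questionnaire-screened). In that
limit the adjusted estimate equals the exact latent-case proportion in
every cell, which the tests assert as exact equality over 200 seeded
cohorts. With a non-empty sub-cohort 1 exactness cannot hold realization by
realization — the `PD2·NS1` term is exact only in expectation — which is
why the oracle configuration empties it.

**What passing tests do not show.** The generator draws independent
entities, uses a single response probability rather than the messy
covariate-dependent attrition of a real cohort (beyond the one-parameter
informative variant), and treats screens as conditionally independent
given the latent status. Unbiasedness under these conditions does not
certify the estimator against violations the design itself acknowledges:
imperfect screen sensitivity and response mechanisms that depend on the
disorder itself both bias estimates, in the directions the test suite
demonstrates.

## Problem sizes

The replicated studies use 200 cohorts of N = 1,000 for the no-noise
oracle, 500 cohorts of N = 2,000 for each recovery arm, and 1,000 random
tables for the chi-square oracle — sizes at which the Monte-Carlo error of
every checked quantity is well below its acceptance band while the whole
suite stays comfortably interactive on one CPU.

## Known limitations

* No confidence intervals, survey weights or multiple-imputation
  alternatives — the estimator family reports point estimates only.
* The published RR cells not reproducible from printed prevalence pairs
  (computed by the original analysts from unrounded internal values) are
  not asserted; only the eight printed-consistent cells are.
* The chi-square choice (plain Pearson on adjusted counts) is one reading
  of an under-specified published procedure; it is isolated for swapping.
* Suicidality is treated as a binary module outcome without a severity
  threshold.
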