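# Methods

## The procedure

The package operationalizes a retrospective, visit-level eligibility
determination for a physical activity referral scheme (PARS). Each clinic
visit is one opportunity to refer, so the unit of analysis defaults to
visits rather than unique patients. A visit is *eligible* iff

```
eligible(v)  ⇔  in_scope(v)  ∧  inclusion(v)  ∧  ¬exclusion(v)
```

where `in_scope` checks age (18–80, inclusive at both ends), the study
window (inclusive at both ends; default 2021-03-15 … 2022-09-30) and an
optional clinic allow-list; `inclusion(v)` is true iff any diagnosis code
on the visit matches one of the inclusion criteria (five target chronic
conditions); and `exclusion(v)` is true iff any code matches an exclusion
criterion (exercise contraindications and acute illnesses). Because the
two criterion directions are per-visit predicates, the final eligible set
is invariant to filter order; only the staged attrition counts depend on
it, and the report fixes the conventional order inclusion-then-exclusion.

Reach is `numerator / denominator` with the denominator the eligible-visit
count (or distinct patients with ≥1 eligible visit) and the numerator the
count of visits carrying the referral code (default `REF201`) that are in
scope and meet the inclusion criteria. By default the numerator does *not*
re-apply the exclusion criteria: the flow that identifies referred patients
applies only the inclusion boundaries, and a clinician who placed a
referral has already judged it appropriate. Because this allows the
numerator to include visits outside the denominator set, a
`strict_numerator` mode intersects the numerator with the denominator;
both figures are reported side by side in the CLI output. Whether referred
visits should be a strict subset of eligible visits is genuinely
underdetermined for this procedure; the package implements both and asserts
neither as canonical.

A zero denominator yields an *undefined* proportion (JSON `null`), never 0.

## Code matching

ICD-10-CM codes are normalized (uppercased, single decimal point removed)
so dotted and undotted dialects match identically. Criteria patterns are
either exact codes or *truncated codes*: a trailing `*` matches every code
sharing the prefix. Two deliberate conventions:

* A wildcard matches its own stem at equal length (`J45.4*` matches a bare
  `J45.4`). Extracts sometimes contain non-billable header codes; excluding
  them would silently drop intended matches. This is the package's own
  choice — nothing in the source procedure says whether header codes occur.
* Validity is a shape check only (letter + 2 alphanumerics + up to 4
  more). The full ICD-10-CM release (>65,000 codes) is deliberately not
  embedded; criteria lists, not a code dictionary, are the source of truth.
  Invalid code strings never raise during classification — they match
  nothing and are counted in the run log.

Only single trailing wildcards are supported — no character classes or
ranges — because that is the entire published pattern language.

## Criteria fixtures

The bundled inclusion set has 30 exact codes across the five target
conditions (physical inactivity 3, obesity 17, dyslipidemia 4, diabetes 5,
hypertension 1); the exclusion set has 78 exact or truncated patterns.
The source spreadsheets behind these lists are not publicly deposited, so
the fixtures are **reconstructions** built to satisfy every published
constraint: the total and per-category counts, the named condition groups
(embolism, aortic stenosis, atrial fibrillation, fractures, chronic kidney
disease mapped to seven codes, moderate/severe asthma as the two asthma
truncations, recent myocardial infarction, …), and the explicit *absence*
of four conditions the clinical consensus rejected as contraindications
(coronary artery disease, diabetes, osteoporosis, back problems/acute back
injury) — a regression test enforces that absence. Per-pattern fidelity to
the unpublished originals cannot be verified; every row is tagged
`source=reconstruction` to keep that status explicit metadata rather than
silent ground truth.

Validation enforces that no inclusion stem and exclusion stem can capture
the same code (one stem prefixing the other with a wildcard on the shorter
side), since a code that simultaneously qualifies and disqualifies a visit
indicates a defective criteria file.

Both criterion directions evaluate the union of the problem-list and
encounter diagnosis fields by default — the source extract drew on both —
with per-direction source switches, because it is unstated whether
exclusion was restricted to encounter (acute) codes. Problem-list codes
are treated as active at every visit; no time-filtering of problem-list
entries is attempted.

## Synthetic extract generator

The generator emulates the structure the pipeline assumes, not real
clinical correlation patterns:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 5,000 | patients in the extract |
| `n_clinics` | 12 | primary-care clinics |
| window | 2021-03-15 … 2022-09-30 | study period (18.5 months) |
| `mean_visits_per_patient` | 4.3 | Poisson rate, minimum 1 visit |
| `age_range` | (18, 80) | uniform integer age, fixed per patient |
| `p_chronic` | 0.05/0.25/0.15/0.08/0.25 | patient-level prevalence of physical inactivity / obesity / dyslipidemia / diabetes / hypertension |
| `p_chronic_exclusion` | 0.12 | patient-level persistent contraindication |
| `p_acute_exclusion` | 0.125 | per-visit acute exclusionary diagnosis |
| `p_refer_given_eligible` | 0.0016 | referral propensity on eligible visits |
| `p_refer_noise` | 0.0002 | referral on ineligible visits |
| `p_clinic_switch` | 0.05 | patient moves clinics mid-window |

The defaults are the package's canonical study profile. The five chronic
prevalences are realistic for US primary care and were chosen so the
expected inclusion-pass fraction is `1 − ∏(1 − p_c) = 0.582`;
`p_chronic_exclusion` and `p_acute_exclusion` give an expected exclusion
removal of `1 − (1 − 0.12)(1 − 0.125) = 0.230` among included visits —
together reproducing the 58%/23%/55% attrition profile of the reference
evaluation. The mean visit rate (4.3/patient) matches that evaluation's
ratio of total visits to unique patients. The referral propensity has no
published anchor beyond the implied order of magnitude (hundreds of
referrals against hundreds of thousands of eligible visits), so the default
is set to that implied rate (~0.0016); it is a free parameter.

Mechanics that matter for testing:

* **Two diagnosis layers.** Chronic conditions (inclusion or exclusion)
  persist on the problem list across all of a patient's visits; acute
  exclusions are single-visit encounter diagnoses; neutral filler codes
  (validated to match no criterion) pad every visit.
* **Wildcard materialization.** Exclusionary wildcard patterns are turned
  into concrete codes (stem + random digit), so generated data exercises
  prefix matching rather than only exact matching.
* **Per-patient random streams.** Each patient gets a child seed keyed by
  patient index, so enlarging `n_patients` extends the population without
  reshuffling existing patients, and every probabilistic decision consumes
  its draws unconditionally, making eligibility pointwise monotone in
  `p_acute_exclusion` under a fixed seed (a tested invariant).
* **Ground-truth labels.** The generator emits its own per-visit record of
  scope/inclusion/exclusion/eligibility/referral. The pipeline must
  reproduce these labels exactly; that oracle, checked over 20 seeds at
  5,000 patients, is the package's primary correctness evidence.

What the generator does **not** emulate: comorbidity correlation (chronic
conditions are independent), visit-rate dependence on disease burden,
per-visit age drift (age is fixed per patient, a deliberate simplification
since the procedure treats age as an extract boundary), coding errors, or
clinician practice-style heterogeneity. Passing tests therefore demonstrate
that the pipeline computes the defined procedure exactly, not that the
procedure is clinically valid on real data.

## Numerical and statistical choices

* **Percent rounding** is half-away-from-zero to integers; this convention
  reproduces every published flow percentage (42, 58, 23, 55, 46) from the
  published counts, including 45.54% → 46%.
* **Unclassifiable records** (unparsable date, negative/missing age) are
  excluded from numerator and denominator alike, flagged in the output and
  counted in the run log; silent dropping is treated as a defect.
* **Orphan referrals** (rows referencing unknown visits) are warned about
  and ignored.
* **Profile-emulation testing.** Because chronic conditions persist across
  a patient's visits, visit-level fractions are clustered within patients
  (design effect ≈ mean visits/patient ≈ 4), so a naive visit-count
  binomial standard error understates the sampling noise by about a factor
  of 2. The profile test therefore estimates the standard error empirically
  from 10 independent replicate runs (~21,000 visits each) and requires the
  replicate mean to sit within 3 standard errors of the configured
  expectation — the statistically calibrated version of a 3-SE binomial
  check for this clustered design.
* **Prevalence recovery** is checked patient-level (where the binomial
  model is exact) against a 99% binomial confidence interval at 2,000
  patients.

## Problem sizes

The test suite and acceptance script run synthetic extracts of 5,000
patients (~21,500 visits) per seed — 20 seeds for the oracle-agreement
check, 10 for the profile check, 5 in the acceptance script — sizes at
which the binomial/cluster arithmetic above is stable and a full run
completes in about a minute on one CPU.

## Known limitations

* The reconstructed exclusion fixture matches published totals and
  condition groups, not the unpublished per-pattern originals; swap in a
  real criteria CSV via `load_criteria` for production use.
* ICD-10-CM only; national ICD-10 modifications and ICD-11 need their own
  criteria lists.
* No statistical inference on the reach proportion (reporting only), no
  free-text mining, no live EHR connectivity, and no modeling of the human
  criteria-development process beyond the `source` provenance tag.
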