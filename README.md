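# pars-reach

Eligibility determination and reach estimation for **physical activity
referral schemes (PARS)** from retrospective EHR extracts.

## The problem

PARS connect primary-care patients to community exercise programs, and
evaluating one retrospectively requires a *reach* estimate in the RE-AIM
sense:

```
reach = numerator / denominator
      = (referrals placed on qualifying visits) / (visits eligible for a referral)
```

Counting every clinic visit in the denominator overestimates the eligible
population: a clinician treating an acute illness, a recent myocardial
infarction, or a fresh fracture is unlikely to place an exercise referral
at that encounter. This package implements the visit-level procedure that
corrects for this:

1. **Scope** — keep visits of patients aged 18–80 inside the study window
   (and optionally an allow-list of clinics).
2. **Inclusion** — keep visits whose ICD-10-CM diagnoses (problem-list or
   encounter fields) match one of the five target chronic conditions:
   physical inactivity, obesity, dyslipidemia, diabetes, hypertension
   (30 bundled codes).
3. **Exclusion** — remove visits carrying a contraindicating diagnosis
   (78 bundled exact or truncated patterns: recent MI, embolism, aortic
   stenosis, atrial fibrillation, fractures, chronic kidney disease,
   moderate/severe asthma, acute illness, …).
4. **Report** — staged attrition counts with integer percent reductions
   (a text cohort-flow diagram plus JSON), and reach at the visit or
   unique-patient unit, with referrals identified by a configurable
   referral code (default `REF201`).

Criteria support *truncated codes*: a trailing `*` wildcard matches every
code sharing the prefix (`J45.4*` covers J45.40/J45.41/J45.42), and
matching is insensitive to the dotted/undotted code dialect.

Because real extracts of this kind are not publicly shareable, the package
includes a seeded **synthetic extract generator** that emulates the assumed
data structure — persistent problem-list conditions, one-off acute
encounter diagnoses, clinic switching, referral events — and emits its own
ground-truth labels, which the pipeline is tested against for exact
agreement.

## Worked example

```python
from pars_reach import (bundled_criteria, generate_extract, classify_visits,
                        attrition_from_classification, compute_reach)
from pars_reach.synthetic import SyntheticConfig

config = SyntheticConfig(seed=11, n_patients=2000, p_refer_given_eligible=0.01)
criteria = bundled_criteria()
extract = generate_extract(config, criteria)
classified = classify_visits(extract.visits, extract.diagnoses, config.scope(), criteria)
print(attrition_from_classification(classified, unit="visits").flow_text())
est = compute_reach(classified, extract.referrals, config.scope(), unit="visits")
print(f"reach: {est.numerator} / {est.denominator} = {100 * est.proportion:.2f}%")
```

prints

```
initial visits: n=8,548
  |- inclusion criteria: removed n=3,612 (42% of entering)
  v  remaining n=4,936 (58% of initial)
  |- exclusion criteria: removed n=1,157 (23% of entering)
  v  remaining n=3,779 (44% of initial)
final visits: n=3,779 (56% reduction from initial)
reach: 39 / 3779 = 1.03%
```

Reading: of 8,548 in-scope visits, 58% carried a target chronic condition;
23% of those carried a contraindication, leaving 3,779 referral-eligible
visits, of which 39 received a referral. The `examples/` directory has one
short script per capability (wildcard matching, criteria validation,
synthetic generation, the full pipeline).

## Command line

A thin CLI wraps the library:

```bash
pars-reach generate --out extract/ --seed 7 --n-patients 5000
pars-reach classify --input extract/ --out results/
pars-reach reach    --input extract/ --out results/ --unit visits
pars-reach report   --input extract/ --out results/
pars-reach validate-criteria
```

Every run writes a `manifest.json` (inputs, SHA-256 digests, configuration,
version) sufficient to reproduce it. Exit codes: 0 success, 2 schema
error, 3 configuration error.

## Data and fixtures

The bundled criteria CSVs
(`src/pars_reach/data/{inclusion,exclusion}_criteria.csv`) are
**reconstructions**: the reference evaluation's exact supplementary code
spreadsheets are not publicly deposited, so the lists were rebuilt to match
every published per-category count and condition description, and every
row is tagged `source=reconstruction`. See `docs/methods.md` for the model,
parameter meanings, and known limitations.
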