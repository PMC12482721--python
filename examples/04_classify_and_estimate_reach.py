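"""Full pipeline: classify visits, report attrition, estimate reach.

Runs the eligibility procedure on a synthetic extract: scope filtering
(ages 18-80, study window), inclusion criteria (the five chronic target
conditions), then exclusion criteria (contraindications), and finally a
reach estimate = referred eligible visits / all eligible visits.
"""

from pars_reach import (
    attrition_from_classification,
    bundled_criteria,
    classify_visits,
    compute_reach,
    generate_extract,
    unique_patient_counts,
)
from pars_reach.synthetic import SyntheticConfig

config = SyntheticConfig(seed=11, n_patients=2000, p_refer_given_eligible=0.01)
criteria = bundled_criteria()
extract = generate_extract(config, criteria)

classified = classify_visits(extract.visits, extract.diagnoses, config.scope(), criteria)

print(attrition_from_classification(classified, unit="visits").flow_text())
print()
print(attrition_from_classification(classified, unit="unique_patients").flow_text("unique patients"))
print()

for unit in ("visits", "unique_patients"):
    est = compute_reach(classified, extract.referrals, config.scope(), unit=unit)
    pct = f"{100 * est.proportion:.2f}%" if est.proportion is not None else "undefined"
    print(f"reach ({unit}): {est.numerator} / {est.denominator} = {pct}")

system = unique_patient_counts(extract.visits, "system")
per_clinic = unique_patient_counts(extract.visits, "per_clinic_sum")
print(f"unique patients: {system} system-wide, {per_clinic} when summed per clinic "
      f"({per_clinic - system} clinic switchers double-counted)")
# The flow text is the package's text rendering of a cohort attrition
# diagram; the reach proportion is the RE-AIM numerator/denominator ratio.
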