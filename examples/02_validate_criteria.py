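"""Inspect and validate the bundled inclusion/exclusion criteria sets.

The inclusion set holds 30 exact ICD-10-CM codes for the five chronic
conditions that make a visit referral-eligible; the exclusion set holds 78
exact or truncated patterns for contraindicating conditions. Validation
confirms that no code could count as qualifying and disqualifying at once.
"""

from pars_reach import bundled_criteria, bundled_exclusion, bundled_inclusion, validate_criteria

inclusion = bundled_inclusion()
exclusion = bundled_exclusion()
print(f"inclusion set: {len(inclusion)} codes; exclusion set: {len(exclusion)} patterns")

report = validate_criteria(bundled_criteria())
print(f"validation ok: {report.ok} "
      f"(duplicates: {len(report.duplicate_ids)}, "
      f"inclusion/exclusion overlaps: {len(report.overlaps)})")

print("inclusion codes per target condition:")
for category, n in report.category_counts["inclusion"].items():
    print(f"  {category}: {n}")
# The per-category counts (3/17/4/5/1) are the published split of the 30
# inclusion codes; zero overlaps means the two criterion directions are
# logically consistent.
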