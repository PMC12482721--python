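"""Truncated-code (trailing-wildcard) matching over the 18 asthma codes.

Asthma has 18 ICD-10-CM codes spanning mild to severe disease. A referral
scheme that excludes only moderate and severe persistent asthma can express
that with two truncated patterns, J45.4* and J45.5*, instead of six exact
codes. This script expands both patterns over the full asthma code family
and shows which codes each one captures.
"""

from pars_reach import expand_pattern, normalize_code, parse_pattern

ASTHMA_CODES = [
    "J45.20", "J45.21", "J45.22",       # mild intermittent
    "J45.30", "J45.31", "J45.32",       # mild persistent
    "J45.40", "J45.41", "J45.42",       # moderate persistent
    "J45.50", "J45.51", "J45.52",       # severe persistent
    "J45.901", "J45.902", "J45.909",    # unspecified
    "J45.990", "J45.991", "J45.998",    # other
]

universe = {normalize_code(c) for c in ASTHMA_CODES}

for raw_pattern in ("J45.4*", "J45.5*"):
    pattern = parse_pattern(raw_pattern)
    hits = sorted(c.raw for c in expand_pattern(pattern, universe))
    print(f"{raw_pattern} matches {len(hits)} of {len(universe)} codes: {', '.join(hits)}")

unmatched = len(universe) - 6
print(f"{unmatched} codes (mild and unspecified asthma) match neither pattern "
      f"and are not exclusionary.")
# Expected output: each pattern matches exactly 3 codes; 12 codes match neither.
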