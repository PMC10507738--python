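"""APOBEC3 sample stratification by the ln-ratio rule.

Classifies samples into low/mid/high APOBEC3 presence from attributed
mutation counts and compares group burdens.
"""

import pandas as pd

from mutotopo.cohorts import classify_apobec, compare_group_burden, group_burdens

rows = []
rows += [("tumorA", "SBS2")] * 800 + [("tumorA", "SBS5")] * 900     # balanced logs
rows += [("tumorB", "SBS13")] * 40 + [("tumorB", "SBS5")] * 90_000  # few APOBEC
rows += [("tumorC", "SBS2")] * 300 + [("tumorC", "SBS5")] * 1300
catalog = pd.DataFrame(rows, columns=["sample", "signature"])

classes = classify_apobec(catalog)
print(classes.to_string(index=False))

burdens = group_burdens(catalog)
fold, p = compare_group_burden(
    burdens[["tumorB"]].to_numpy(), burdens[["tumorA"]].to_numpy()
)
print(f"\nburden fold (B vs A): {fold:.2f}, Mann-Whitney p = {p:.2f}")
print()
print("ratio = ln(APOBEC mutations) / ln(other mutations); >= 0.90 is")
print("HIGH, (0.75, 0.90) MID (dropped from re-analyses), <= 0.75 LOW.")
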