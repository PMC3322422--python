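"""Classify repeat counts and tabulate carrier frequencies with exact CIs.

Builds a small screened cohort, classifies each sample's repeat count into
expanded / wild-type / indeterminate, and prints a stratified carrier table
with Clopper-Pearson 95% intervals.
"""

from c9screen.io import Subject, classify_repeat_count
from c9screen.stats import clopper_pearson, frequency_table

print("Repeat-count classification (pathogenic > 30, wild-type < 20):")
for count in (8, 25, 45, 700):
    print(f"  {count:4d} repeats -> {classify_repeat_count(count).value}")

# Exact intervals for published-style screening counts: k carriers of n
print("\nExact 95% CIs (Clopper-Pearson):")
for k, n in [(61, 289), (0, 3), (1, 1)]:
    ci = clopper_pearson(k, n)
    print(f"  {k:3d}/{n:<4d} -> {100 * ci.p_hat:5.1f}% "
          f"({100 * ci.lower:.1f}-{100 * ci.upper:.1f})")

subjects = [
    Subject(f"s{i}", "ALS", familial=i < 40, region="Finland",
            carrier=(i % 5 == 0), age_onset_y=55.0)
    for i in range(100)
]
table = frequency_table(subjects, ["familial"])
print("\nCarrier frequency by family history:")
print(table.to_string(index=False))
print("\nEach row: carriers k of n screened, the point estimate and the "
      "exact interval that contains the true rate with >= 95% probability.")
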