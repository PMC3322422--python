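"""Round-trip the whole pipeline through its on-disk formats.

Writes a synthetic cohort to TSV files, reads everything back, and runs
sharing, dating, penetrance and frequency stages from the files — exactly
what the `c9screen` command-line tool does.
"""

import tempfile
from pathlib import Path

from c9screen.age import extract_break_intervals, posterior_age
from c9screen.io import read_genotypes, read_marker_panel, read_repeat_counts, read_subjects
from c9screen.penetrance import km_curve, onset_and_censor_ages, age_at_penetrance
from c9screen.share import cohort_share
from c9screen.simulate import SimConfig, simulate_cohort, synthetic_panel
from c9screen.stats import frequency_table

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp)
    cohort = simulate_cohort(
        SimConfig(panel=synthetic_panel(seed=9), founder_age_G=100,
                  n_carriers=150, n_noncarriers=150, seed=9)
    )
    cohort.write(out)
    print("wrote:", sorted(p.name for p in out.iterdir()))

    panel = read_marker_panel(out / "panel.tsv")
    genotypes = read_genotypes(out / "genotypes.tsv", panel)
    subjects = read_subjects(out / "subjects.tsv")
    repeats = read_repeat_counts(out / "repeats.tsv")

    print(f"\npanel: {len(panel)} markers, locus at {panel.locus_bp:,} bp")
    print("repeat classes:",
          repeats["carrier_class"].value_counts().to_dict())

    shares, summary = cohort_share(genotypes, panel)
    print(f"any-share fraction: {summary.frac_any:.3f}")

    carriers = {s.sample_id for s in subjects if s.carrier}
    carrier_shares = [r for r in shares if r.sample_id in carriers]
    post = posterior_age(
        extract_break_intervals(carrier_shares, panel), seed=9
    )
    print(f"mutation age: {post.median_G:.0f} generations "
          f"(~{post.median_years:.0f} years; simulated at 100)")

    events, cens = onset_and_censor_ages(subjects)
    print(f"50% penetrance at "
          f"{age_at_penetrance(km_curve(events, cens), 0.5):.1f} y")

    table = frequency_table(subjects, ["diagnosis"])
    print("\ncarrier frequency:\n", table.to_string(index=False))
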