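"""Summarise multimorbidity burden on a synthetic cohort.

Prints the burden distribution (none / single / two-or-more conditions) and
the burden-by-BMI-band table.
"""

from pregmorb import (
    SimulationConfig,
    burden_distribution,
    default_morbidity_lexicon,
    extract_cohort,
    generate_cohort,
    stratified_table,
)

records, _ = generate_cohort(SimulationConfig(n_records=3000, seed=11))
profiles = extract_cohort(records, default_morbidity_lexicon())

dist = burden_distribution(profiles)
print(dist.to_frame().to_string(index=False))
print(f"\nmultimorbidity: {dist.n_multimorbidity} records "
      f"({dist.percent_multimorbidity}% of cohort)")

print("\nBurden by BMI band (column % within each burden class):")
print(stratified_table(profiles, records, "bmi").to_string(index=False))
# Note the empty 'none' cells in the BMI >= 25 bands: the derived
# overweight/obesity flags guarantee at least one condition there.
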