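"""Generate a small synthetic maternity cohort and peek at its free text.

The generator draws condition flags from realistic marginal prevalences,
renders them into semi-structured text (empty when healthy), and keeps the
generating truth alongside.
"""

from pregmorb import NoiseConfig, SimulationConfig, generate_cohort

config = SimulationConfig(
    n_records=8,
    seed=7,
    noise=NoiseConfig(typo_rate=0.2, uppercase_rate=0.3, filler_rate=0.3),
)
records, truth = generate_cohort(config)

print(records[["record_id", "maternal_age", "bmi", "medical_conditions_text"]].to_string(index=False))
print()
print("Ground-truth GDM outcomes:", truth["gdm"].tolist())
# Each non-empty text lists one noisy surface form per generated condition;
# the gdm flags come from a logistic model in the true condition flags.
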