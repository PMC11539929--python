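"""Generate a synthetic Medicare-style claims bundle with planted truth.

Builds a small seeded population whose per-beneficiary patterns (agitation
case, comparator, confirmation failures, enrollment gaps, severe-mental-
illness exclusions, one-day near-misses) are known in advance, and prints
how the planted mix decomposes.
"""

from agitad import default_generator_config, generate_population, write_bundle

config = default_generator_config(n_beneficiaries=2000, seed=11)
bundle, truth = generate_population(config)
write_bundle(bundle, "scratch/example_bundle")
truth.to_csv("scratch/example_bundle/ground_truth.csv", index=False)

print(f"beneficiaries:    {bundle.n_beneficiaries}")
print(f"medical claims:   {len(bundle.medical_claims)}")
print(f"pharmacy claims:  {len(bundle.pharmacy_claims)}")
print(f"study window:     {bundle.study_window[0].date()} .. "
      f"{bundle.study_window[1].date()}")
print("\nplanted pattern mix (each beneficiary must exit the identification")
print("algorithm through exactly this branch):")
print(truth["pattern"].value_counts().to_string())
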