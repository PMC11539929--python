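"""Baseline characteristics of the two cohorts, including the Charlson score.

Age bands, sex, race/ethnicity, region, entitlement, dual Medicare/Medicaid
eligibility (a low-income proxy) and the Charlson Comorbidity Index computed
from diagnosis codes in the 183-day pre-index window, as frequencies (%) and
mean (SD).
"""

from agitad import (assign_cohorts, baseline_table, default_code_sets,
                    default_generator_config, generate_population)

config = default_generator_config(n_beneficiaries=4000, seed=11)
bundle, _ = generate_population(config)
assignments, _ = assign_cohorts(bundle, default_code_sets())
table = baseline_table(bundle, assignments)

agit = table[table["cohort"] == "agitation"]
print("agitation cohort baseline profile:")
print(agit.to_string(index=False))
print("\ncategorical percentages within each variable sum to 100.0 "
      "(sum-preserving rounding); continuous rows carry mean and SD.")
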