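"""Tumor centrality (TVTB) and survival regression on a synthetic cohort.

Computes the distance from the third-ventricle reference point to each
tumor border, then fits the Cox model with the age x TVTB interaction and
reports the age-conditional per-cm hazard ratio of TVTB.
"""

import tumoratlas as ta
from tumoratlas.regression import ModelSpec, combined_hr_tvtb, fit_cox_os

# hazard-driven survival so the Cox model has a planted truth to recover
coefs = {"age_years": 0.079, "tvtb_cm": 0.6, "age_x_tvtb": -0.012}
config = ta.SimulationConfig(seed=11, n_patients=2000, hazard_coefs=coefs)
masks, registry, truth = ta.generate_cohort(config)

print(f"TVTB: median {registry.df['tvtb_cm'].median():.2f} cm, "
      f"{(registry.df['tvtb_cm'] == 0).sum()} tumors touch the reference point")

spec = ModelSpec(
    outcome="os",
    candidate_covariates=["age_years", "tvtb_cm"],
    interaction_terms=[("age_years", "tvtb_cm")],
)
result = fit_cox_os(registry, spec, screen=False)
print(result.summary.round(4))

for age in (60, 80):
    hr = combined_hr_tvtb(result, age)
    print(f"per-cm HR of TVTB at age {age}: {hr:.2f}")
# an HR below 1 means each extra centimeter away from the third ventricle
# lowers the hazard; the interaction makes the protection stronger with age.
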