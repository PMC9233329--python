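"""Per-item regressions of importance scores with jackknife-robust variances.

Each item's RIS is regressed on gender and cohort indicators; every
participant is omitted in turn and the regressions re-fitted, and the robust
variance of each coefficient is (n-1)/n times the sum of squared
leave-one-out deviations.  Here the utility-estimation stage is the identity
(the observed synthetic scores are taken as data), which is also how the
jackknife's correctness is audited against direct delete-one refits; swap in
``hb_ris_pipeline`` to re-estimate utilities inside every replicate.
"""

import capbws as cb
from capbws.regression import COEFFICIENT_NAMES, identity_pipeline

design = cb.generate_design(16, 6, 16, n_versions=3, n_iterations=10, seed=7)
truths = cb.simulate_population(cb.default_population_config(seed=5))
responses = cb.simulate_responses(design, truths, seed=11)
posterior = cb.fit_hb(responses, config=cb.McmcConfig.reduced(seed=3))
included, _ = cb.filter_inconsistent(posterior)
ris = cb.compute_ris(posterior, include_ids=included)
covariates = posterior.respondents

result = cb.jackknife_robust(identity_pipeline(ris.ris_individual), covariates)
print(f"n = {result.n} participants, J = 4 coefficients, "
      f"t-tests on {result.df} degrees of freedom\n")

table = cb.significance_table(result, ris.ris_individual, cb.ITEM_LABELS)
print("cells significant at p < 0.05 (estimate, robust SE):")
for _, row in table.iterrows():
    for name in COEFFICIENT_NAMES[:-1]:  # skip the intercept column
        if row[f"{name}_p"] < 0.05:
            print(f"  {row['label']:<42} {name:<24} "
                  f"{row[f'{name}_estimate']:+.2f} "
                  f"({row[f'{name}_robust_se']:.2f}){row[f'{name}_stars']}")
# The default generator plants negative effects on Freedom of expression
# (psychiatric) and Having suitable accommodation (expert).  In any single
# sample of 158, effects of this size hover around the significance
# boundary, and correlated estimation noise can flag a few other cells --
# the reason robust rather than model-based standard errors are used.
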