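"""Stepwise covariate selection on the troponin model.

Forward inclusion needs an OFV drop > 6.63 (p < 0.01, 1 df); backward
elimination removes a covariate unless dropping it raises the OFV by
more than 7.88 (p < 0.005).  On data simulated with a true
anthracycline-type effect, the type covariate should enter and survive.
"""

import cardiopd as cpd
from cardiopd.covariates import forward_backward, lrt_threshold
from cardiopd.models import CovariateEffect, TroponinModel

print(f"forward threshold : {lrt_threshold(0.01):.2f}")
print(f"backward threshold: {lrt_threshold(0.005):.2f}")

trial = cpd.simulate_trial(cpd.TrialDesign(n_subjects=120), seed=4)
candidates = [
    CovariateEffect("type_effect", "slope", "binary_power",
                    "anthracycline_type"),
    CovariateEffect("rtx_slope", "slope", "binary_power",
                    "prior_radiotherapy"),
]


def fit_subset(included):
    model = TroponinModel(trial.doses, trial.observations,
                          trial.covariates_frame, list(included))
    return cpd.fit(model, estimate_rse=False, compute_ebes=False)


trace = forward_backward(fit_subset, candidates)
print(trace.to_frame().to_string(index=False))
print(f"included: {[c.name for c in trace.included]}")
print(f"base OFV {trace.base_ofv:.1f} -> final OFV {trace.final_fit.ofv:.1f}")
# Only the anthracycline-type effect carries signal; the radiotherapy
# candidate should be rejected at the forward step.
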