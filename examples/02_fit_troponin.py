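"""Fit the anthracycline K-PD / direct-effect troponin T model.

Simulates a cohort at the published estimates, refits it from neutral
starting values and prints the recovered population parameters with their
relative standard errors.  TRP0 is the pre-treatment baseline (ng/L), ke
the K-PD elimination rate (1/day), SLOPE the proportional rise per mg of
virtual anthracycline amount, and the type effect the SLOPE multiplier for
epirubicin relative to doxorubicin.
"""

import cardiopd as cpd
from cardiopd.workflows import fit_troponin

trial = cpd.simulate_trial(cpd.TrialDesign(n_subjects=100), seed=2)
result = fit_troponin(trial.doses, trial.observations, trial.covariates_frame)

print(f"status: {result.convergence_status}; OFV = {result.ofv:.1f}")
for name in ("trp0", "ke", "slope", "type_effect"):
    print(f"  {name:12s} = {result.theta[name]:.4g}"
          f"   (RSE {result.rse.get(name, float('nan')):.1f}%)")
cv = result.omega.cv_percent()
print(f"  BSV: trp0 {cv['trp0']:.1f}% CV, slope {cv['slope']:.1f}% CV")
print(f"  proportional residual error: {100 * result.sigma.sd:.1f}%")
print(f"  eta shrinkage: { {k: round(v, 1) for k, v in result.eta_shrinkage.items()} }")
# Values should scatter around the simulation truth (4.7, 8.49e-3,
# 8.84e-3, 0.524) within a few reported RSEs.
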