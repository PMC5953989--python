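"""Model evaluation: prediction-corrected VPC and NPDE.

Both diagnostics simulate replicate trials at the observed design.  On
self-consistent data (simulated from the same model) the observed median
should sit inside the simulated 95% bands in ~95% of bins and the NPDE
sample should be approximately standard normal; a single cohort shares
its subject-level draws across bins, so occasional band exceedances are
expected.
"""

import numpy as np

import cardiopd as cpd
from cardiopd.models import CovariateEffect, TroponinModel

trial = cpd.simulate_trial(seed=6)  # full 206-subject design
eff = CovariateEffect("type_effect", "slope", "binary_power",
                      "anthracycline_type")
model = TroponinModel(trial.doses, trial.observations,
                      trial.covariates_frame, [eff])

theta = {"trp0": 4.7, "ke": 8.49e-3, "slope": 8.84e-3, "type_effect": 0.524}
omega = cpd.OmegaMatrix.from_cv(("trp0", "slope"), [39.2, 57.7])
sigma = cpd.SigmaParams(sd=0.301)

vpc = cpd.pcvpc(model, theta, omega, sigma, n_sim=500, seed=7, lloq=3.0)
t = vpc.table
inside = ((t["obs_p50"] >= t["sim_p50_lo"]) & (t["obs_p50"] <= t["sim_p50_hi"]))
print("pcVPC (500 replicates):")
print(t[["time", "n", "obs_p50", "sim_p50_lo", "sim_p50_hi"]].round(2)
      .to_string(index=False))
print(f"bins with observed median inside the 95% band: "
      f"{inside.sum()}/{len(t)}")

res = cpd.npde(model, theta, omega, sigma, n_sim=1000, seed=8, lloq=3.0)
print(f"NPDE: mean {res.mean:+.3f} (expect ~0), "
      f"variance {res.variance:.3f} (expect ~1), "
      f"Shapiro-Wilk p = {res.normality_pvalue:.2f}")
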