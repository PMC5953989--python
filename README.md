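# cardiopd

Pharmacodynamic modelling of cardiac biomarkers — troponin T and
left-ventricular ejection fraction (LVEF) — in breast-cancer patients
treated with anthracyclines followed by trastuzumab.

Anthracyclines damage cardiomyocytes (released troponin T is the
biomarker); trastuzumab causes a partly reversible decline in LVEF, and
patients differ widely in their sensitivity to it. `cardiopd` implements
the population (nonlinear mixed-effects) analysis that quantifies both
processes and links them: patients with a higher anthracycline-induced
troponin-T peak are more sensitive to trastuzumab-induced LVEF decline.
It is aimed at pharmacometricians and methods researchers who want a
fully scripted, simulation-testable version of this analysis — no NONMEM
required, no patient data needed.

## Models

**Anthracycline → troponin T** (K-PD, direct effect). Dosing records feed
a virtual compartment `dA/dt = -ke·A`; troponin T rises proportionally:

    TRP(t) = TRP0 · (1 + SLOPE_eff · A(t)),   SLOPE_eff = SLOPE · θ_type^EPI

**Trastuzumab → LVEF** (effect compartment + Emax). A fixed-parameter
two-compartment model generates trastuzumab concentrations, which
accumulate in an effect compartment with first-order recovery:

    dC_eff/dt = C_trast − (ln2 / T½,rec) · C_eff
    LVEF(t)  = LVEF0 · (1 − C_eff / (C_eff + EC50_i))
    EC50_i   = EC50_pop · (TRP_max,i / 18)^θ_peak

Both models carry lognormal between-subject variability (`P_i = P_pop·e^η`,
full Ω supported) and proportional residual error. Estimation maximizes a
Laplace-with-interaction marginal likelihood (the FOCE-I stand-in),
validated against adaptive Gauss–Hermite quadrature and closed-form
Gaussian marginals. On top of the estimator sit stepwise covariate
selection (forward ΔOFV > 6.63, backward > 7.88), prediction-corrected
VPCs, NPDE, shrinkage/RSE reporting, the clinical LVEF-decline rule
(< 45% or a ≥ 15-point drop), and a synthetic trial generator that
reproduces the 206-patient study design. See `docs/methods.md` for the
full account.

## Worked example

```python
import cardiopd as cpd
from cardiopd.workflows import fit_troponin

trial = cpd.simulate_trial(cpd.TrialDesign(n_subjects=100), seed=2)
result = fit_troponin(trial.doses, trial.observations, trial.covariates_frame)
print(result.theta, result.omega.cv_percent(), result.sigma.sd)
```

Running `python examples/02_fit_troponin.py` (which does exactly this and
formats the output) prints:

```
status: converged; OFV = 5001.3
  trp0         = 4.809   (RSE 4.1%)
  ke           = 0.008308   (RSE 4.9%)
  slope        = 0.009285   (RSE 7.2%)
  type_effect  = 0.4526   (RSE 18.9%)
  BSV: trp0 38.5% CV, slope 50.5% CV
  proportional residual error: 33.5%
  eta shrinkage: {'trp0': 4.3, 'slope': 20.2}
```

The cohort was simulated at TRP0 = 4.7 ng/L, ke = 8.49×10⁻³ /day,
SLOPE = 8.84×10⁻³ /mg and a type effect of 0.524, so each estimate sits
within about one standard error of its truth: the fit recovers the
baseline troponin, the ~82-day K-PD half-life, the per-mg proportional
effect and the roughly twofold weaker effect of epirubicin. The other
`examples/` scripts walk through trial simulation, the sequential
troponin → LVEF pipeline, covariate search, VPC/NPDE diagnostics, and
decline classification; a `cardiopd` CLI (`simulate`, `fit`, `covsearch`,
`vpc`, `npde`, `classify`) wires the same steps to config files.

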