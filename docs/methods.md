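# Methods

`cardiopd` implements a pharmacodynamic analysis of cardiac biomarkers in
breast-cancer patients treated with anthracyclines followed by trastuzumab:
two nonlinear mixed-effects models (anthracycline → troponin T, trastuzumab
→ LVEF), their estimation machinery, stepwise covariate selection,
simulation-based diagnostics, and a synthetic trial generator that
reproduces the study design so the whole pipeline is testable without
patient data.

## Structural models

**Anthracycline exposure (K-PD).** No anthracycline concentrations are
observed, so dosing records drive a virtual compartment with first-order
loss,

    dA/dt = -ke * A,    A(t) = sum_{t_d <= t} D_d * exp(-ke (t - t_d)),

with `A` in mg and `ke` (1/day) estimated from the biomarker data. Doses
enter as boluses: infusion durations (minutes–hours) are negligible against
the compartment's half-life (`ln 2 / ke` ≈ 82 days at the default `ke`).

**Troponin T (direct effect).**

    TRP(t) = TRP0 * (1 + SLOPE_eff * A(t)),
    SLOPE_eff = SLOPE                (doxorubicin)
              = SLOPE * theta_type   (epirubicin)

The direct-effect form places the troponin peak immediately after the last
anthracycline dose. An indirect-response (turnover) alternative is kept
only as a comparison stub (`structural.troponin_turnover_prediction`): it
delays and flattens the peak, conflicting with the observed day-21
concentrations and recovery rate, and is not a supported analysis path.

**Trastuzumab exposure.** Plasma concentrations follow a linear
two-compartment model with fixed population parameters (no between-subject
variability on PK), evaluated analytically by bi-exponential bolus
superposition. The parameter values are *configuration*, not estimates:
the defaults (CL 0.225 L/day, V1 2.95 L, Q 0.69 L/day, V2 2.68 L) are
literature-typical for a therapeutic IgG1 antibody, and any analysis
intending to reproduce a specific published PK model should supply that
model's values in the `pk_parameters` config block. All simulation-based
checks in this package use the same PK values for data generation and
refitting, so their outcomes do not depend on the exact choice.

**LVEF (effect compartment + Emax).** Cardiac damage accumulates in an
effect compartment fed by the trastuzumab concentration and draining at the
recovery rate constant,

    dCeff/dt = C_trast - (ln 2 / T_half_rec) * Ceff,
    LVEF(t) = LVEF0 * (1 - Ceff / (Ceff + EC50_i)).

`Ceff` integrates concentration over time (mg/L·day scale with time in
days); EC50 is expressed on that same scale and is *not* rescaled — at the
default parameters a year of weekly dosing yields `Ceff` a few percent of
EC50 for a median subject, i.e. LVEF declines of a few points, with the
large EC50 variability producing the clinically relevant declines in
sensitive subjects.

**Covariates.** Binary covariates enter as power multipliers
(`P_i = P_pop * theta^COV`), continuous covariates as median-normalized
powers (`P_i = P_pop * (COV/median)^theta`), categorical covariates as one
multiplier per non-reference level. The key clinical covariate links the
two models: the individual EC50 is scaled by the predicted troponin-T peak,

    EC50_i = EC50_pop * (TRP_max / 18)^theta_peak,

with 18 ng/L fixed (the cohort median peak; it is a normalization constant,
never re-estimated). The two models are estimated sequentially, not
simultaneously: troponin first, per-subject peaks from its empirical Bayes
estimates, then the LVEF model with those peaks as a fixed covariate. This
mirrors the pharmacology (anthracyclines damage myocytes and release
troponin; trastuzumab's functional effect is not expected to feed back on
troponin).

## Statistical model and estimation

Between-subject variability is lognormal (`P_i = P_pop * exp(eta_i)`,
`eta ~ N(0, Omega)`); by default the troponin model carries BSV on TRP0 and
SLOPE with a diagonal Omega, the LVEF model on LVEF0 and EC50 with a full
2×2 Omega (the baseline–sensitivity correlation is reported from the
covariances). Residual error is proportional for both biomarkers.
Below-LLOQ values (troponin T < 3 ng/L, NT-proBNP < 5 pg/mL) are replaced
by LLOQ/2, flagged, and enter the likelihood as ordinary observations; no
censored-likelihood (M3) handling.

The objective function is the full −2·log marginal likelihood (2π
constants included). Each subject's integral over `eta` is approximated by
a Laplace expansion about the conditional mode, with the residual variance
evaluated at that conditional estimate (η–ε interaction carried exactly).
Numerical layout:

* The inner problem (conditional modes) is a damped Newton iteration
  vectorized across all subjects: analytic gradients of the joint negative
  log density, Hessians by central differences of those gradients
  (step 1e-5), backtracking line search per subject, gradient tolerance
  1e-8, at most 80 iterations. Subjects whose inner problem fails are
  flagged and the OFV becomes +inf for that evaluation.
* The outer problem optimizes positive parameters on the log scale, the
  Omega matrix through its Cholesky factor (log-diagonal), and the residual
  SD on the log scale, with L-BFGS-B (function tolerance 1e-11 relative,
  finite-difference step 1e-6). Random effects with variance below 1e-10
  are treated as structurally absent, which makes the omega → 0 limit exact.
* Relative standard errors come from the observed Fisher information: a
  central-difference Hessian of the OFV at the optimum (step 1e-4),
  covariance `2 H^{-1}`, delta method to the natural scale. Omega RSEs are
  reported on the variance (omega²) scale.
* Empirical Bayes estimates are the conditional modes at the final
  estimates; eta-shrinkage is `100(1 - SD(EBE)/omega)` per effect and
  epsilon-shrinkage `100(1 - SD(IWRES))`.

**Accuracy of the approximation.** The Laplace OFV is validated two ways:
it matches the closed-form Gaussian marginal exactly on a linear toy model,
and it is compared against adaptive Gauss–Hermite quadrature (15 nodes per
dimension, mode-centered, itself verified against brute-force grid
integration). At the troponin model's estimated variability (BSV 39/58%,
proportional error 30%) the Laplace error is about 0.03–0.04 OFV units per
subject with the 10-visit design; it shrinks with richer data and smaller
variability. Likelihood-ratio decisions (thresholds 6.63/7.88) compare two
models evaluated with the same approximation, so most of this error
cancels in OFV differences.

## Covariate selection

Greedy forward inclusion / backward elimination over declared
covariate–parameter candidates. Forward: the candidate with the largest
OFV drop exceeding the chi-squared quantile at p < 0.01 enters (6.63 for
1 df); repeat until none qualifies. Backward: any retained candidate whose
removal raises the OFV by at most the p < 0.005 quantile (7.88 for 1 df)
is removed, weakest first. Categorical candidates consume (levels − 1)
degrees of freedom and use the correspondingly larger thresholds. Ties
break by candidate list order; fits are memoized by candidate subset; a
candidate whose fit fails is skipped with a warning.

## Diagnostics

* **pcVPC**: simulates replicate datasets at the observed design (same
  doses, times, covariates; fresh eta and epsilon), prediction-corrects
  observed and simulated values by the ratio of the bin-median population
  prediction to the record's population prediction, and compares observed
  5th/50th/95th percentiles per time bin with the simulation distribution
  of those percentiles (default 500 replicates, 95% CIs). Bins default to
  the unique nominal visit times, falling back to quantile bins when visit
  times are subject-relative. When the observed data carry LLOQ/2
  substitution the same rule is applied to the simulated replicates, so
  the comparison is like-with-like.
* **NPDE**: per subject, observation vectors are decorrelated with the
  Cholesky factor of the simulated covariance; each observation's rank in
  its simulated predictive sample (clipped to [1/(K+1), K/(K+1)]) maps
  through the standard normal quantile. Under a correct model the sample
  is standard normal; the summary reports mean, variance and a
  Shapiro–Wilk statistic. A singular simulated covariance falls back to
  non-decorrelated errors with a warning.
* **GOF table**: per observation, population prediction (eta = 0),
  individual prediction (EBE), residuals and IWRES. Note that with
  proportional error the conditional mode is not exactly the
  noise-free truth even for perfect data — the prediction-dependent
  variance pulls the mode slightly — so IWRES ≈ 0 for noiseless data only
  as sigma → 0.
* **LVEF decline classifier**: clinically relevant decline iff any
  follow-up LVEF < 0.45 or any drop from baseline ≥ 0.15 — read as
  *absolute* LVEF percentage points (cardio-oncology convention, and the
  only reading consistent with the companion "< 45%" rule); the boundary
  (exactly 15 points) counts as a decline.

## Synthetic trial generator

The generator reproduces the 206-patient design: 87.9% doxorubicin /
12.1% epirubicin; 2–6 cycles every 21 days (probabilities
0.08/0.17/0.40/0.20/0.15 over 2..6 — median 4); per-cycle doses triangular
within the reported ranges peaking at the reported medians (doxorubicin
75/110/150 mg, epirubicin 100/170/200 mg); a gap to trastuzumab that is
triangular 14/21/30 days for 94% of subjects with a 6% uniform tail to 217
days (matching the reported median 21, range 14–217, 94% ≤ 30 days);
weekly (4→2 mg/kg, 144/206 subjects) or 3-weekly (8→6 mg/kg) trastuzumab
for 52 weeks with doses scaled by body weight; biomarker sampling at the
protocol visits (troponin/NT-proBNP: pre-anthracycline, pre-trastuzumab,
weeks 3–92; LVEF: the same minus weeks 3 and 64). Baseline samples are
drawn the day before the first anthracycline dose. Body weight
(50/70/100 kg triangular) and age (25/50/69) are plausible defaults; the
paper-level sources report only medians and ranges for doses and neither
for weight.

Observations are generated from the structural models with lognormal BSV,
proportional error and LLOQ/2 substitution; the latent truth table (etas,
individual parameters, true troponin peak) is emitted alongside, so
parameter- and covariate-recovery tests have an exact oracle. NT-proBNP is
emitted as exposure-independent lognormal noise around a subject-level
baseline — format fidelity only; the analysis deliberately contains no
longitudinal NT-proBNP model. An optional informative-dropout transform
removes trastuzumab doses and LVEF records after a subject first meets the
clinical decline rule, for stress-testing the diagnostics.

All randomness flows from one master seed through per-subject substreams
(`SeedSequence.spawn`), so a subject's data are invariant to cohort size.

**What passing tests show — and what they do not.** The generator matches
the trial's design and the fitted models' statistical structure, so
parameter-recovery and calibration results demonstrate that the estimation
and diagnostic machinery is correct *under the stated model*. Real data
add features the generator does not emulate: visit-time jitter and missed
visits, assay batch effects, model misspecification, informative dropout
(off by default), and covariate correlations beyond those induced by the
design. Recovery tolerances on real data would be correspondingly wider.

## Problem sizes and defaults

Simulation-based checks run at the study's size (206 subjects, ~2060
troponin and ~1650 LVEF observations); pcVPC uses 500 replicates and NPDE
1000. Operating-characteristic checks of the covariate search use 12
replicates per arm — enough to distinguish the high-power alternative
(type effect 0.524) from the ~1% null inclusion rate, chosen so the whole
suite runs comfortably on a single CPU. The package's estimation defaults
(tolerances, starting values, thresholds) are stated above and in the
docstrings; all stochastic routines take explicit seeds.

## Known limitations

* FOCE-I proper is not implemented; the Laplace-with-interaction objective
  is its closest mode-based relative, and the quadrature comparisons bound
  the difference on this problem class.
* No SAEM, no Bayesian posterior, no bootstrap/sandwich covariance.
* BLQ handling is substitution (as in the source analysis), not censored
  likelihood; heavy censoring would bias low concentrations.
* The trastuzumab PK is fixed and bolus-approximated; target-mediated
  elimination and PK variability are out of scope.
* `Ceff`/EC50 units are internally consistent but tied to the day time
  unit; comparisons with analyses using other unit conventions require
  rescaling.
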