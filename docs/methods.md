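# Methods

`dalbapk` implements a complete population-pharmacokinetic analysis of
dalbavancin for long-term suppressive therapy of ventricular-assist-device
(VAD) driveline infections: a structural PK model, a nonlinear
mixed-effects estimator for sparse therapeutic-drug-monitoring data,
diagnostics, and Monte Carlo dosing simulations that translate exposure
into probability of target attainment (PTA) and cumulative fraction of
response (CFR) against *S. aureus*.

## Structural model

Disposition is a linear mammillary two-compartment model with zero-order
intravenous infusion into the central compartment, parameterized by
clearance `CL` (L/h), central volume `V1` (L), inter-compartmental
clearance `Q` (L/h) and peripheral volume `V2` (L).  Micro constants are
`k10 = CL/V1`, `k12 = Q/V1`, `k21 = Q/V2`; the hybrid constants
`alpha > beta` are the roots of `s² − (k10+k12+k21)s + k10·k21 = 0`.
Because dalbavancin's terminal phase (t½ ≈ 320 h under the reference
parameters) is two orders of magnitude slower than its distribution
phase, `beta` is computed as `k10·k21/alpha` rather than by the direct
quadratic formula; together with `expm1`-based exponentials this keeps
the analytic solution accurate to ≈1e-10 relative against a
high-accuracy ODE integration.

Concentrations and AUCs for arbitrary dosing histories are exact
superpositions of per-dose closed forms (during- and post-infusion
branches share one expression via `min(t, T_inf)` / `max(t − T_inf, 0)`).
AUC over a window is the difference of the closed-form running integral,
so AUC is exactly additive over adjacent windows and satisfies the mass
balance `AUC∞ = Dose/CL`.  `Q = 0` is accepted as the degenerate
one-compartment limit; the beta mode then carries no mass and the
terminal half-life is reported as `ln2/k10`.

Reference ("typical") parameters throughout are the VAD-cohort estimates
CL 0.050 L/h, V1 6.5 L, Q 0.476 L/h (fixed), V2 15.4 L, giving
Vss = 21.9 L.

## Population model

Inter-individual variability is log-normal and diagonal: individual
parameters are `p_i = p_typ · exp(η_i)` with `η_i ~ N(0, ω_p²)`.  The
`ω` values (0.230 for CL, 0.260 for V1, 0.410 for V2; none for Q) are
**standard deviations of the log-scale random effects** — the
Monolix/NONMEM convention.  Misreading them as variances changes every
downstream number, so the code and docstrings state the convention
explicitly.  Residual error is proportional, `y = c·(1 + b·ε)` with
`b = 0.100`; constant and combined error models are implemented for
model exploration but proportional is the shipped default.

Residual error is applied only when emulating *measurements* (synthetic
datasets, VPC).  Exposure metrics entering PTA use the error-free
individual profiles; assay noise is not part of a patient's
pharmacokinetics, and including it would only blur the attainment
fractions.  This convention is stated explicitly because either choice is
defensible and they give different attainment fractions.

Random-number streams are derived from one master seed via tagged
`SeedSequence` substreams, so adding one simulation task never perturbs
the draws of another, and every result is bit-reproducible given its
seed.

## Exposure metric and target attainment

The pharmacodynamic index is `fAUC24/MIC`: the free AUC over the **last
24 h before redosing** divided by the MIC, the conservative choice for
suppressive therapy because it measures the trough-phase exposure.
Protein binding enters as a deterministic scenario scalar: free
concentration = `(1 − PB/100)` × total, with scenarios at 93 (label),
96-98 (observed in the VAD cohort) and 99 % bound.  Attainment uses the
strict inequality `fAUC24/MIC > threshold` with thresholds 27.1
(stasis), 53.3 (1-log kill) and 111.1 (2-log kill); PTA and CFR are
"desirable" at ≥ 90 %.

Two decisions that were genuinely open:

* **Evaluation interval.**  For regimens with several doses per cycle
  (e.g. day 1 + day 8 every 6 weeks) a 24-h window is evaluated before
  *every* scheduled redosing of the final cycle, and the regimen-level
  exposure is the worst (minimum) across windows.  For all six shipped
  regimens this coincides with the cycle-end window, but the rule is
  explicit so irregular regimens are handled conservatively.
* **Steady state.**  Exposures are evaluated on the final cycle of a
  6-cycle explicit simulation (accumulation is material at a 320-h
  half-life: the q3w steady-state trough is ≈ 50 % above the first-dose
  trough).  Explicit simulation keeps a single code path for irregular
  cycles; single-course behaviour is available by constructing a
  regimen with `n_cycles=1`.

CFR weights the PTA curve by a MIC frequency distribution on the EUCAST
doubling-dilution grid 0.016-2 mg/L.  The EUCAST frequency table itself
is not reproduced anywhere in the analysis; the packaged
`mic_saureus_synthetic.csv` is a clearly-labelled synthetic stand-in
with the qualitative shape of the public wild-type distribution (mode
two dilutions below the 0.125 mg/L ECOFF, thin upper tail).  It is a
config input, never hard-coded; substantive use should replace it with a
dated EUCAST export.

## Estimation

The fitter maximizes the marginal likelihood of the nonlinear
mixed-effects model by SAEM.  Individual log-parameters
`φ_i = μ + Β·x_i + η_i` are sampled by Metropolis-Hastings (one
independence kernel from the prior plus two adaptive random-walk
kernels per iteration, acceptance steered to ≈ 0.3); sufficient
statistics are smoothed with step 1 during 400 exploration iterations
and step `1/k` during 200 smoothing iterations; M-steps are exact
(linear regression for `μ`/`Β`, moment updates for `ω²`, closed form for
proportional/constant error SD).  During exploration the variance
estimates may shrink by at most 5 % per iteration (simulated-annealing
constraint) so they cannot collapse before the chains find the
high-likelihood region.  Floors of 0.02 (ω) and 1e-4 (error SD) keep
degenerate boundaries numerically safe; sparse designs do occasionally
drive an ω to the floor, which is a legitimate boundary ML estimate for
that replicate, not a failure.  Convergence is declared from the
relative change of the estimate trajectory over the final smoothing
iterations (tolerance 1e-3 per iteration); a failed check is returned
as `converged=False`, never silently.

Constraints and conventions:

* Subjects are processed in sorted-ID order, so record order never
  affects the result; fits are bit-deterministic given seed and
  settings.
* Only total-concentration records enter the fit; unbound observations
  serve protein-binding summaries.
* Below-quantification-limit handling is the simple QL/2 replacement
  (strictly `DV < QL`, or an explicit flag; values at the limit are
  kept), applied as a pipeline step before fitting.  The
  censored-likelihood (M3) approach is deliberately out of scope to
  stay comparable with the simple-imputation convention the study
  cohort was analysed under.
* Every free structural parameter must carry IIV (the sampler works on
  individual log-parameters); parameters without IIV must be fixed, as
  Q is in the final model.
* Default initial values (CL 0.057 L/h, V1 10 L, V2 10 L) are published
  dalbavancin estimates from earlier cohorts, intentionally distinct
  from this model's reference values so recovery experiments never
  start at their own truth.

The objective function value (OFV = −2 log L) is computed after
fitting: by Monte Carlo importance sampling (default, 10,000 draws per
subject from a Gaussian proposal at the per-subject conditional mode,
covariance inflated ×1.5, Monte Carlo SE reported) or by the
deterministic Laplace approximation.  AIC = OFV + 2p and
BIC = OFV + p·log(n_subjects) count p as: typical values with IIV +
their ωs + error parameters + covariate exponents (a fixed Q is not
counted).  On a one-random-effect problem the importance-sampling OFV
agrees with adaptive Gauss-Hermite quadrature to < 0.01.

Covariate effects are power models on median-normalized covariates,
`p_typ,i = p_typ · (cov_i/median)^γ` — the functional form is this
package's choice among the standard options.  The
stepwise search adds the best candidate while ΔOFV > 3.84 (χ²₁,
p < 0.05) and prunes retained effects whose removal costs < 6.63
(p < 0.01), logging every tested candidate.  The search uses the
Laplace OFV by default so selection decisions are deterministic.

Standard errors come from a numerically differentiated Fisher
information matrix of the Laplace objective, computed on the log scale
so RSEs are invariant to unit rescaling; a singular information matrix
raises an error that recommends the bootstrap instead.  The bootstrap
resamples whole subjects (record resampling is invalid for sparse
repeated measures), refits each replicate with a reduced SAEM schedule,
and reports percentile CIs, excluded-failure counts and a quality flag
above 20 % failures.

## Diagnostics

Goodness of fit reports observed-vs-predicted R² for population
predictions (typical + covariates) and individual predictions
(empirical Bayes estimates, the MCMC conditional means at the final
parameters).  η-shrinkage is `100·(1 − SD(EBE η)/ω)`.  The VPC
simulates replicate datasets at the observed design with the same QL
censoring + QL/2 imputation as the real pipeline (bands are otherwise
incomparable near the 12.5 mg/L limit), bins by exact nominal time when
there are few distinct times (the study design has three) and by time
quantiles otherwise, and envelopes each observed percentile with the
2.5-97.5 % band of the simulated percentiles.  The conditioning
diagnostic is the max/min eigenvalue ratio of the estimates' correlation
matrix, capped and flagged at 1e12.

## Synthetic cohorts

The default generator reproduces the study conditions: 13 subjects,
1500 mg over 0.5 h on day 1 (t = 0) and day 8 (t = 168 h) of a 6-week
cycle; samples at end-of-infusion + 30 min (t = 1.0 h), the day-8
trough (168 h, immediately before the second dose) and the week-6
trough (1008 h, immediately before the next cycle).  Clinical records
date such troughs "day 7" and "day 42" (*before redosing*); with doses
on days 8 and 43 these are the same instants, resolved here as 168 h
and 1008 h.  One engineered subject draws CrCl uniformly on [15, 30) mL/min
and receives the reduced 1000 mg dose; all other CrCl draws are
truncated to [30, 200].  Covariates match the cohort table (age 57±9 y,
BSA 1.95±0.17 m², albumin 42.5±5.7 mg/dL, CrCl 90.8±34.7 mL/min,
log-normal weight with median 76 kg and IQR 20 kg, protein binding
uniform on 96-98 %) but carry no PK effect by default, matching the
null covariate result; a covariate-effect mode powers selection
experiments.  An optional missingness knob drops one record to match
the cohort's 38 (not 39) samples.

What the generator does **not** emulate: real sampling-time deviations
from nominal times, assay failures other than BQL, inter-occasion
variability, correlated random effects, covariate-driven PK, or
infection outcomes.  Tests passing on these cohorts therefore
demonstrate correctness of the pipeline under the stated model, not
validity of the model for any particular patient.

## Problem sizes and numerical choices

Defaults match the study conditions: 10,000 simulated individuals for
PTA/CFR and VPC, 1000 bootstrap replicates, importance sampling with
10,000 draws.  The recovery experiment in `scripts/acceptance.py` uses
20 replicate 100-subject cohorts and full SAEM schedules; the test
suite uses the same sizes for its acceptance checks and reduced
schedules (`SAEMSettings.fast()`) for bootstrap and repeated-fit
property tests, sizes chosen so the entire suite completes in a few
minutes on one CPU without changing any scientific default.

## Known limitations

* One- and two-compartment structural models only; a three-compartment
  model is not estimable here.
* No inter-occasion variability and no off-diagonal ω.
* The week-6 trough of the reference model overpredicts the observed
  cohort mean by ≈ 27 % (see the acceptance summary); the model is used
  as printed, without recalibration.
* The packaged MIC distribution is synthetic (see above).
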