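# dalbapk

Population pharmacokinetics and dose-regimen simulation of **dalbavancin**
for long-term suppressive outpatient therapy of ventricular-assist-device
(VAD) driveline infections.

Patients with an implanted VAD are prone to persistent device infections
whose source cannot be removed, so they receive antibiotic suppression for
months.  Dalbavancin's very long terminal half-life (≈ 320 h under the
model shipped here) makes infrequent intravenous dosing attractive, but
only the unbound drug is active and plasma protein binding in these
patients runs 96-98 % (label: 93 %), so the feasible interval between
1500 mg doses depends critically on binding and on the pathogen MIC.
`dalbapk` is for clinical pharmacologists and pharmacometricians who want
to fit such sparse therapeutic-drug-monitoring data and stress-test
long-interval regimens by simulation.

## What the package implements

* **Analytic PK engine** — two-compartment IV-infusion model
  (CL, V1, Q, V2), closed-form concentrations and AUCs by superposition;
  exact, fast, vectorized over populations.
* **Nonlinear mixed-effects estimation (SAEM)** — log-normal
  inter-individual variability `p_i = p_typ·e^{η_i}`, η ~ N(0, ω²),
  proportional residual error `y = c(1 + bε)`, QL/2 imputation of
  below-quantification-limit values (12.5 mg/L total, 1 mg/L unbound),
  marginal likelihood by importance sampling or Laplace, stepwise
  power-model covariate search (forward ΔOFV > 3.84, backward > 6.63),
  FIM or bootstrap standard errors.
* **Diagnostics** — observed-vs-predicted R², visual predictive check
  with QL-aware simulation bands, subject-resampling bootstrap,
  η-shrinkage, estimate-correlation condition number.
* **Dosing simulation & target attainment** — 10,000-subject Monte Carlo
  populations; free AUC over the last 24 h before redosing
  (`fAUC24`); PTA(MIC) = % of subjects with `fAUC24/MIC > θ` for
  θ ∈ {27.1 stasis, 53.3 1-log kill, 111.1 2-log kill}; CFR = PTA
  weighted by a MIC frequency distribution; desirable at ≥ 90 %.
* **Synthetic study replica** — 13-subject cohorts with the study's
  design (1500 mg day 1 + day 8 q6w, three sparse samples, demographics,
  96-98 % binding) and known ground truth, for end-to-end testing.

The reference model (typical CL 0.050 L/h, V1 6.5 L, Q 0.476 L/h fixed,
V2 15.4 L; ω_CL 0.230, ω_V1 0.260, ω_V2 0.410; b 0.100) is available as
`vad_population_model()`.

## Worked example

```python
from dalbapk import (load_regimen, vad_population_model, sample_population,
                     pta_curve, cfr, default_mic_distribution)

pop = sample_population(vad_population_model(), 10_000, seed=1)
reg = load_regimen("1500-q3w")                  # 1500 mg every 3 weeks
curve = pta_curve(pop, reg, pb=99.0, threshold="stasis")
for mic, v in zip(curve.mics, curve.pta):
    print(f"MIC {mic:g}: PTA {v:.1f} %")
print(f"CFR = {cfr(curve, default_mic_distribution()).cfr:.1f} %")
```

Output:

```
MIC 0.016: PTA 100.0 %
MIC 0.03: PTA 100.0 %
MIC 0.06: PTA 99.6 %
MIC 0.125: PTA 95.2 %
MIC 0.25: PTA 61.9 %
MIC 0.5: PTA 5.7 %
MIC 1: PTA 0.0 %
MIC 2: PTA 0.0 %
CFR = 98.3 %
```

Reading: even in the worst-case 99 %
protein-binding scenario, 1500 mg every 3 weeks keeps the probability of
attaining the stasis target above 90 % up to the *S. aureus*
epidemiological cut-off of 0.125 mg/L, and the distribution-weighted
CFR is 98.3 % — the regimen is "desirable" in this scenario.  PTA drops
steeply for rarer high-MIC isolates, which is why individual MICs and
measured binding matter for interval selection.

The same analyses are scriptable from a shell:

```bash
dalbapk generate --n 13 --seed 1 --out cohort.csv
dalbapk fit cohort.csv --out fit.json
dalbapk pta --regimen 1500-q3w --pb 99 --target stasis --n 10000 --seed 1
dalbapk cfr --regimen 1500-q5w --pb 98 --target stasis --n 10000 --seed 1
```

Six regimen presets ship with the package: `1500-d1-d8-q6w`,
`1500-d1-d15-q6w`, `1000-q2w`, `1500-q3w`, `1500-q4w`, `1500-q5w`.
The packaged MIC distribution is a **synthetic** EUCAST-style snapshot
(the public frequency table is not redistributable here); pass your own
two-column CSV (`mic_mg_per_L,frequency`) for substantive work.

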