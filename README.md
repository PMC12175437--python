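# hfpefcmr

Contrast-free discrimination of heart failure with preserved ejection
fraction (HFpEF) from its comorbid look-alikes — obesity and type 2
diabetes (T2DM) — using quantitative cardiac MR markers, rebuilt as a
fully tested, synthetic-data-driven analysis pipeline.

HFpEF diagnosis is notoriously ambiguous in obese, diabetic patients
because symptoms and imaging findings overlap with the comorbidities
themselves. The pipeline implements the candidate CMR markers and the
statistics needed to ask which of them actually separates HFpEF in a
three-group cohort (obese controls without cardiovascular disease,
T2DM, and HFpEF with T2DM):

- **Quantitative first-pass perfusion.** Dual-bolus acquisition: a dilute
  pre-bolus measures the arterial input function (AIF) without signal
  saturation; a full bolus drives tissue enhancement; the two are
  reconciled by the bolus concentration ratio. The tissue impulse
  response is modeled as a Fermi function
  `R_F(t) = A / (exp((t − μ)/k) + 1)`, fitted by damped nonlinear least
  squares so that the tissue curve equals the AIF convolved with `R_F`.
  Myocardial blood flow is `MBF = R_F(0)`; the myocardial perfusion
  reserve is `MPR = MBF_stress / MBF_rest`.
- **Diffuse fibrosis.** Extracellular volume fraction from native and
  post-contrast T1 of septal myocardium and blood pool:
  `ECV = (1 − HCT) · ΔR1_myo / ΔR1_blood` with `ΔR1 = 1/T1_post − 1/T1_native`.
- **Left-atrial mechanics.** Lagrangian length strain referenced to LV
  end-diastole, decomposed into reservoir (peak), booster (value at the
  pre-atrial-contraction frame) and conduit (their difference), so that
  `reservoir = conduit + booster` holds identically; biplane area–length
  volumes `V = 8/(3π) · A_2ch · A_4ch / L`.
- **Cohort statistics.** One-way ANOVA with Tukey–Kramer post-hoc pairs,
  Pearson chi-squared, Pearson correlation with log-transform of skewed
  biomarkers, univariable and age/sex/BMI-adjusted logistic regression
  (Wald CIs), ROC analysis with DeLong AUC confidence intervals and
  Youden-optimal operating points, day-1/day-8 test–retest ICC(2,1)
  with Cicchetti bands, and a sensitivity re-analysis excluding
  subjects with atrial-arrhythmia history.

No pixel data are touched anywhere: the pipeline consumes time–signal
curves, scalar T1 panels, and per-frame LA contours/lengths as
delimited text, and a first-class synthetic-data module generates all
of them from stated distributions — every generator is the exact
forward model of its analysis stage, so recovery is testable down to
machine precision.

## Worked example

Synthesize one noisy dual-bolus study with known flows and quantify it
back from the curve files:

```bash
hfpefcmr synth perfusion --seed 7 --rest-mbf 1.0 --stress-mbf 3.2 \
    --noise-sd 2.0 --out demo_study
hfpefcmr quantify --study demo_study/manifest.json --out demo_study/mbf.csv
```

prints

```
MBF rest 1.002, stress 3.176 mL/g/min; MPR 3.168
```

i.e. the Fermi deconvolution recovers the generating flows (1.0 and
3.2 mL/g/min) to within a few percent under noise, and `mbf.csv` holds
the fitted shape parameters per state
(`A=1.046, μ=3.95 s, k=1.26 s` at rest, `rss`, convergence flag).

The full study emulation runs as numbered scripts:

```bash
python analysis/01_simulate_cohort.py                 # 35-subject cohort + example signal files
python analysis/02_quantify_perfusion.py              # MBF/MPR from synthetic dual-bolus studies
python analysis/03_compute_ecv.py                     # ECV from inverted T1 panels
python analysis/04_la_mechanics.py                    # LA strain + biplane volumes
python analysis/05_group_comparisons.py               # ANOVA/Tukey/chi-squared tables
python analysis/06_discrimination_and_reproducibility.py  # logistic, ROC, ICC, sensitivity
```

On the default seed the last script reports, among others, a
univariable odds ratio per mL of LA maximum volume of 1.03 (p = 0.043),
LA conduit strain OR 0.78 per percentage point (p = 0.006), MPR
test–retest ICC(2,1) of 0.96 (excellent), and 3 of 35 subjects excluded
in the arrhythmia sensitivity analysis — the qualitative pattern the
study conditions encode: atrial mechanics discriminate HFpEF while
perfusion reserve and ECV overlap across groups. `hfpefcmr pipeline`
runs the same chain end-to-end into one report bundle; identical seed
and config give byte-identical results.

## Layout

```
src/hfpefcmr/     library: curves, synth, cohort, perfusion, ecv, la,
                  stats, presets, pipeline, cli
analysis/         numbered narrative drivers writing results/ tables
tests/            pytest suite (unit, property, acceptance)
scripts/          acceptance recomputation
docs/methods.md   models, assumptions, numerical choices, limitations
```
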