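# Methods

This note documents the models the package implements, the synthetic
data that drives them, the numerical choices that matter, and what the
passing tests do and do not establish.

## Quantitative perfusion by Fermi-constrained deconvolution

### Model

First-pass signal is assumed proportional to contrast concentration
within the fitted range (the rationale of the dual-bolus design: the
dilute pre-bolus keeps the blood-pool signal in the linear regime). The
tissue curve is the discrete causal convolution of the AIF with a
tissue impulse response constrained to the Fermi family,

    tissue(t_i) = dt * Σ_{j≤i} AIF(t_j) · R_F(t_i − t_j),
    R_F(t) = A / (exp((t − μ)/k) + 1),

with amplitude `A` (flow units), shoulder `μ` (s) and decay width `k`
(s). Myocardial blood flow is the initial response value
`MBF = R_F(0) = A/(exp(−μ/k)+1)`, converted by a configurable constant
(default 1 signal unit ≡ 1 mL/g/min, the convention under which the
generator works directly in flow units). MPR is the stress/rest MBF
ratio, computed per curve pair and averaged afterwards when several
pairs exist.

### Processing chain and its numerical choices

1. **First-pass window.** Landmarks (onset, peak, end) are detected on
   an internally smoothed copy of the curve (edge-normalized moving
   average, default width 5) so single-sample noise cannot act as an
   onset or valley. Detectability requires the smoothed peak to exceed
   the baseline mean by 5 baseline SDs (config-exposed). The onset is
   the first departure from the baseline band backtracked to the band
   edge, widened by a `width//2 + 1` sample margin so the window opens
   on flat baseline — on baseline-subtracted data the convolution model
   represents those leading near-zero samples exactly. The window ends
   at the first post-peak local minimum that behaves like a
   recirculation valley: it must dip below 0.6 of the peak enhancement
   and the curve must re-rise by at least 0.2 of it afterwards. A plain
   "first local minimum" rule truncates noisy curves one or two samples
   after the peak and destroys the deconvolution; the two
   qualifications reproduce the plain rule exactly on clean curves
   (verified against an exhaustive-scan oracle on a two-lobe curve).
2. **Smoothing.** Centered moving average, default width 3, implemented
   with `(w−1)/2` zeros prepended before a zero-padded convolution and
   the trailing `(w−1)/2` samples dropped. Because the pre-onset signal
   of a baseline-subtracted first-pass window is zero, this makes
   smoothing and the convolution model commute exactly — ordinary
   'same'-mode smoothing leaves an edge mismatch that alone breaks the
   0.1% noiseless-recovery requirement.
3. **Registration.** `preprocess_pair` aligns the AIF and tissue
   windows by an integer-sample shift, by default the difference of the
   detected onsets. The composed `quantify_study`, however, registers by
   the shared acquisition clock (shift 0) by default: the onset of a
   slowly rising, noisy tissue curve is detected systematically late,
   and each sample of misregistration biases MBF by roughly 2–3%,
   whereas an unremoved transit delay δ is absorbed by the Fermi
   shoulder (μ → μ + δ) and changes `R_F(0)` only through the
   saturation factor — under 3% for μ ≳ 3k, the physiological regime.
   A residual-based shift search cannot do better, because an integer
   shift is exactly compensable inside the model family (the fit
   surface is flat across shifts). `registration="onset"` restores
   onset alignment for data without a shared clock. This is a
   deliberate deviation from a pure onset-alignment design, adopted
   after the onset-alignment pipeline failed the noisy Monte-Carlo
   recovery it is meant to pass.
4. **Fitting.** `scipy.optimize.least_squares` (bounded
   trust-region-reflective damped least squares) on residuals
   `tissue − dt·(AIF ⊛ R_F)`, bounds `A ≥ 0`, `0 ≤ μ ≤ window`,
   `k ≥ dt/10`, tolerances `xtol 1e-8`, `gtol 1e-10`. When no explicit
   start is given the fit multi-starts from three deterministic points
   — the wide default (`A₀ = peak(tissue)/∫AIF`, `μ₀ = 0.25·window`,
   `k₀ = 0.1·window`) plus two starts at contrast-transit scale —
   because the landscape has local minima that trade the shoulder
   against the amplitude at low SNR. Non-convergence returns the best
   iterate flagged `converged=False` with a warning. Exponentials are
   clipped at ±700 to avoid overflow at extreme `k`.
5. **Ties** in peak/minimum detection break toward the earliest sample.

### Accuracy under the study conditions

Noiseless synthetic studies are recovered at machine precision (the
0.1% requirement holds with ~12 orders of margin). At Gaussian noise of
5% of the tissue peak, the median absolute MBF error over 200
replicates is ~6–7% (requirement: <10%); the error distribution has a
heavy tail (p90 ≈ 18%) driven by genuinely ambiguous noise draws where
a shoulderless response fits as well as the true plateau — an intrinsic
identifiability limit of Fermi deconvolution at this SNR, not an
optimizer artifact (a 0.01-resolution grid search over (μ, k) with the
amplitude profiled out agrees with the optimizer's minimum RSS within
1%).

## ECV

`ECV = (1 − HCT) · (1/T1_myo_post − 1/T1_myo_native) /
(1/T1_blood_post − 1/T1_blood_native)`, stored as a fraction and
rendered as percent in reports. Inputs are scalar septal-ROI T1 values
in ms; no relaxometry is performed. A non-positive blood ΔR1 ("no blood
contrast effect") is an error; a result outside 15–60% warns but does
not fail, since extreme values are suspicious rather than invalid. The
generator inverts the equation for `T1_myo_post` given a target ECV, so
the round trip is exact to 1e-12 relative. Visit averaging applies to
ECV like all repeated measurements.

## LA mechanics

Strain is Lagrangian length strain `ε(t) = 100·(L(t) − L_ref)/L_ref`
with the LV end-diastolic frame as reference (strain zero there);
reservoir = max ε, booster = ε at the pre-atrial-contraction frame,
conduit = reservoir − booster — the standard feature-tracking
convention, which makes `reservoir = conduit + booster` an identity
that is nevertheless asserted on every output. The pre-A frame is an
input (known from the generator for synthetic data); an atrial-minimum
reference convention would change the numbers and is intentionally not
the default. Volumes use biplane area–length over the 2- and 4-chamber
views with the frame-wise mean of the two view lengths; Simpson
summation is out of scope. Strains are computed per view and averaged,
then averaged across visits. Frame indices are 0-based.

The trajectory generator builds the strain curve from three half-cosine
segments through (ref 0) → (end-systolic peak = reservoir) → (pre-A =
booster) → (0), so segment monotonicity guarantees the peak is the
global maximum; areas scale as length squared with view-specific
constants (0.55/0.65), and an optional target maximum volume rescales
the geometry in closed form.

## Synthetic cohort

Groups: obese controls without CVD (n=6), T2DM (n=16), HFpEF with T2DM
(n=13) — 35 subjects, visits on days 1 and 8. Continuous variables are
normal with the per-group means/SDs collected in `presets.GROUP_STATS`
(demographics, MPR, ECV%, LA volumes and strains, biomarkers);
Pentraxin-3 is right-skewed and drawn log-normal with moment matching
(`σ² = ln(1+cv²)`, `m = ln μ − σ²/2`); sex and arrhythmia history are
Bernoulli (female 2/6, 1/16, 5/13; arrhythmia 3/13 in the HFpEF group
only). Biomarkers are censored to their immunoassay reportable ranges
(Galectin-3 3.13–100, Pentraxin-3 0.094–192, IL1RL1 1.6–200 ng/mL) by
truncation-resampling of the whole subject draw — redrawing rather than
clipping avoids probability atoms at the bounds and preserves the
day-1/day-8 correlation structure; a clip fallback after 1000 redraws
guards pathological specs.

Test–retest values decompose additively: subject latent (between-SD =
the group SD unless overridden) plus independent visit noise with
`σ_w² = σ_b²(1−ρ)/ρ` for target ICC ρ, plus an optional systematic
day-8 offset. The offset depresses the absolute-agreement ICC(2,1)
below the consistency ICC — the property the ICC(2) choice is meant to
capture. Empirical ICC converges to the target (checked at n=500 within
0.05). All generation is deterministic in the seed.

What the generator does **not** emulate: between-variable correlations
within subject (each variable is drawn independently, so multivariable
structure beyond group membership is absent), measurement error models
specific to each device, missingness, and any pixel-level imaging
physics. Passing tests therefore demonstrate correctness of the
computational chain under the stated marginal distributions, not
robustness to real-world artifacts. The noise model and SNR of the
signal curves are config-exposed defaults (2% of tissue peak in the
pipeline; 5% in the stress test), not claims about any scanner.

## Statistics

Standard procedures are delegated: ANOVA to `scipy.stats.f_oneway`
(with the zero-within-variance edge resolved explicitly: unequal means
→ p=0, equal → F=0, p=1), Tukey–Kramer to `scipy.stats.tukey_hsd`,
chi-squared to `scipy.stats.chi2_contingency` without continuity
correction (the >2×2 convention, matching R's default for these
tables), Pearson correlation to `scipy.stats.pearsonr`, logistic
regression to `statsmodels.Logit` with Wald 95% CIs (the conventional
reporting form at these sample sizes), and ICC to
`pingouin.intraclass_corr` (absolute-agreement single-measure row, the
F-based CI). Natural logs are used for all transforms; tests are
two-sided at 0.05. Natriuretic peptide levels are an inclusion
criterion of the emulated design and are excluded from regression
models.

Separation handling: at n=35 logistic fits are fragile; complete or
quasi-complete separation (singular Hessian, perfect prediction, or
explosive coefficients) is detected and flagged with a warning rather
than silently reported or auto-penalized, and replicate-averaging
utilities skip flagged fits. The ROC machinery is implemented in the
package: empirical AUC as the Mann–Whitney concordance probability,
DeLong placement-variance 95% CI (a bootstrap CI is not provided),
Youden threshold over midpoints between adjacent observed values with
ties broken toward higher specificity and a "≥ threshold calls
positive" convention. Markers whose lower values indicate disease
(strains, MPR) are sign-flipped before ROC analysis and the threshold
mapped back. Cicchetti bands: <0.40 poor, 0.40–0.59 fair, 0.60–0.74
good, ≥0.75 excellent.

## Pipeline and problem sizes

The end-to-end pipeline generates the cohort, synthesizes raw signal
data for a configurable subject subset (default 6–8 subjects for the
perfusion stage; T1 panels and LA trajectories for all 35), quantifies
them back, runs the statistics chain on the subject-level table, and
writes delimited-text tables plus a JSON summary; identical config and
seed give byte-identical bundles, and any stage failure aborts with the
stage named. Replicate counts used by the verification suite — 500
cohort replicates for the odds-ratio recoveries, 200 noise replicates
for the perfusion Monte Carlo, 2000 null cohorts for the ANOVA type-I
calibration, 100 draws for the LA round trip — are the package's chosen
problem sizes, balancing Monte-Carlo error against runtime on a single
CPU.

## Known limitations

- One representative curve per slice/subject; no AHA 16-segment or
  pixel-wise mapping, and no model-independent deconvolution.
- The MBF unit conversion is a convention, not a calibration; absolute
  flows in physical units require an external constant.
- Clock-based registration assumes AIF and tissue curves share an
  acquisition clock; for asynchronous data use onset registration and
  expect the documented noise sensitivity.
- The logistic odds-ratio replicate means are slightly above the
  infinite-n discriminant-analysis value because small-sample MLE bias
  pushes coefficients away from zero; the acceptance comparisons are
  run at the study's own n where this bias is part of the estimand.
- Between-variable independence in the generator means multivariable
  adjusted models exercise the code path but not realistic confounding.
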