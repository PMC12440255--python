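# nidot

Infant high-density diffuse optical tomography (HD-DOT) prediction-error
analysis, reimplemented as a tested, reusable Python pipeline with a
synthetic-data generator standing in for raw infant recordings.

## The problem

In a probabilistic cueing paradigm, 6- to 8-month-old infants hear a 750 ms
audio cue that is followed 80% of the time by a 1800 ms cartoon appearing on
screen (*expected* trials) and 20% of the time by its omission (*unexpected*
trials), separated by 3–5 s jittered baselines. Unexpected omissions elicit
prediction errors in the medial prefrontal cortex (mPFC), measurable as
hemodynamic responses with a 12-tile, 1728-channel-per-wavelength HD-DOT
cap at 4.6 Hz. Infant attention fluctuates strongly from trial to trial, so
a concurrent 100 Hz eye-tracker provides a per-trial **dwell-time ratio**
(DTR) — valid gaze time inside the display-spanning area of interest divided
by total valid tracking time over the cue-to-stimulus-end window — which
enters the hemodynamic model as a parametric modulator. Finally, maternal
trait anxiety (STAI, 20–80, clinical cutoff >40) is related to the infants'
unexpected-event responses.

The package is for researchers who want to (a) prototype or teach this kind
of gaze-modulated optical-imaging analysis end to end, (b) stress-test each
stage against planted ground truth, or (c) reuse individual stages (motion
correction, Beer–Lambert conversion, FIR GLMs, mixed models) on their own
channel-format data.

## What it computes

- **Channel cleaning** — pruning by source–detector separation (>60 mm) and
  intensity coefficient of variation (>8%), motion detection
  (tMotion=1, tMask=1, STDEV=15, AMPthresh=0.4), spline (p=0.99), wavelet
  (IQR=0.8) and TDDR corrections, zero-phase FIR band-pass 0.01–0.5 Hz.
- **Beer–Lambert conversion** — ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF
  inverted per source–detector pair with DPF = 5.1.
- **Forward model & reconstruction** — semi-infinite diffusion Green's
  function sensitivities J (Rytov), zeroth-order Tikhonov inverse
  x = Jᵀ(JJᵀ + λ·σ²max·I)⁻¹y with λ = 0.01, and sensitivity-weighted
  aggregation of 12–45 mm channels into six frontal ROIs (L/R mPFC, L/R
  mSFG, L/R middle PFC).
- **GLM** — FIR basis with 28 post-onset bins per condition (betas averaged
  over bins 12–24, the 3–6 s infant HRF peak) or a canonical single-gamma
  HRF with 4 s time-to-peak; one DTR modulator column (scaled 0.1–1,
  convolved with the canonical HRF) across all trials; fitted by AR(P)IRLS —
  BIC-selected autoregressive prewhitening plus Tukey bisquare reweighting;
  Benjamini–Hochberg correction over the 6 ROIs × 2 contrasts = 12
  comparisons of the main analysis.
- **Group inference** — random-intercept mixed models
  (DTR ∼ condition + (1|subject), beta ∼ −1 + cond + cond:TraitAnxiety +
  (1|subject), …) estimated by profiled REML with Satterthwaite-style
  degrees of freedom, Nakagawa marginal/conditional R², and logistic
  prediction of clinical anxiety (STAI > 40) from the right-mPFC
  unexpected-event response.
- **Synthetic cohorts** — trial schedules, gaze traces whose in-AOI fraction
  is an unbiased estimate of a planted engagement, two-wavelength OD
  channels whose response amplitude is `beta·(a + (1−a)·DTR)` with
  attention coupling `a`, and STAI scores coupled to the unexpected-event
  amplitude — so every claim above is testable against ground truth.

## Worked example

```python
import numpy as np
from nidot import synth, group

# 31 infants, ~27 trials each, planted DTR condition effect of -0.10
cohort = synth.generate_cohort(n_subjects=31, b1=0.0, seed=7, n_trials=27)
dtr = synth.simulate_dtr_table(cohort, seed=8)
fit = group.fit_random_intercept(dtr, "dtr", "condition")
print(fit.summary_frame().round(4))
print(f"R2_marginal={fit.r2_marginal:.3f}  R2_conditional={fit.r2_conditional:.3f}")

# 25 mother-infant pairs with planted trait-anxiety coupling (0.02 uM/point)
anx = synth.generate_cohort(n_subjects=25, seed=9)
fit2 = group.fit_anxiety_interaction(synth.simulate_beta_table(anx, seed=10))
est, se, t, p = group.unexpected_anxiety_slope(fit2)
print(f"unexpected trait-anxiety slope: b={est:.4f} uM/point, t={t:.2f}, p={p:.4f}")
```

prints

```
                         estimate      se        t       dof    p
Intercept                  0.5216  0.0309  16.8982   30.6978  0.0
condition[T.unexpected]   -0.1167  0.0183  -6.3823  808.5102  0.0
R2_marginal=0.029  R2_conditional=0.427
unexpected trait-anxiety slope: b=0.0280 uM/point, t=9.16, p=0.0000
```

The condition row recovers the planted engagement drop on unexpected trials
(−0.10, here estimated −0.117 ± 0.018 on one cohort) with trial-level
degrees of freedom near 810; the intercept is tested against ~31
between-subject dof. The conditional R² (~0.43) shows that subject identity
explains far more DTR variance than condition does (marginal R² ~0.03). The
anxiety model recovers the planted positive coupling between maternal trait
anxiety and the infant's unexpected-event response amplitude.

Full pipelines run from the shell:

```bash
nidot run --preset roi_glm_branch --seed 7 --out out/        # FIR GLM + group models
nidot run --preset image_branch  --seed 7 --out out_img/     # reconstruction branch
nidot synth --out cohort/ --seed 1 --n-subjects 2            # CSV exports of raw data
```

## Layout

```
src/nidot/
  synth.py          # cohort generator (schedules, gaze, OD channels, STAI)
  gaze.py           # DTR computation, scaling, inclusion rules
  preprocess.py     # pruning, motion correction, filtering, MBLL, epoching
  forward_recon.py  # Green's-function sensitivities, Tikhonov, ROI weights
  glm.py            # designs, AR-IRLS, bin averaging, contrasts, BH-FDR
  group.py          # mixed models, Satterthwaite dof, R2, logistic
  pipeline.py       # the two presets, provenance, serialization
  cli.py            # nidot synth|preprocess|recon|fit|group|run
docs/methods.md     # model assumptions, parameter choices, limitations
```
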