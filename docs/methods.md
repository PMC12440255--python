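# Methods

This note records the models the package implements, the assumptions and
defaults behind them, and what the synthetic-data tests do and do not
establish about real recordings.

## Paradigm and synthetic cohorts

A session is a sequence of trials: a 750 ms auditory cue, then a 1800 ms
outcome window in which the cued cartoon appears with probability 0.8
(expected) or is omitted (unexpected), preceded by a baseline drawn
uniformly from 3–5 s. Events are modelled time-locked to the outcome-window
onset in both conditions, since for omissions that is the moment the
expectation is violated.

The generator plants, per subject: condition response amplitudes
`beta_expected`, `beta_unexpected` (µM ΔHbO at full engagement; ΔHbR is
−0.5×ΔHbO), a per-trial true dwell-time ratio (DTR), and STAI trait/state
scores. Per-trial DTR is

    dtr(i) = intercept + habituation·i + condition_effect·1[unexpected] + ε,

clipped to [0, 1]. Defaults: subject intercepts ~ Normal(0.75, 0.26)
truncated to [0.05, 0.95], habituation −0.010 per trial, condition effect
−0.10, trial noise SD 0.20. These were calibrated jointly so that the
condition-model mixed fit shows a small marginal R² (~0.02) against a
large conditional R² (~0.44) — engagement dominated by stable
between-infant differences — while the planted −0.10 condition effect stays
recoverable despite the clipping at the ratio bounds (mean recovered
estimate ≈ −0.09 across cohorts; the bounds attenuate slightly, which is a
property of any bounded engagement measure).

Attention couples to the neural response multiplicatively:

    amplitude(trial) = beta_condition · (a + (1 − a)·dtr_true),

with coupling `a = 0.5` by default (`a = 1` disables coupling and makes
planted betas exactly recoverable). Responses are impulse trains convolved
with the canonical infant HRF and mapped to two-wavelength optical density
through the same extinction matrix the Beer–Lambert inversion uses
(735/850 nm, Gratzer/Prahl compilation), so the forward/inverse round trip
is exact by construction. Noise components (each exercising one cleaning
stage): AR(1) white noise, sinusoidal drift, a 2.0 Hz cardiac line (placed
below the 2.3 Hz Nyquist of 4.6 Hz sampling; infant heart-rate realism is
secondary to filter testing), and Poisson-scheduled spikes and baseline
shifts recorded in the ground truth. No noise spectra are published for the
emulated recordings; defaults are chosen for test coverage, not realism.

Gaze traces are Bernoulli: inside a trial window each 10 ms sample is
on-screen with probability `dtr_true`, so the measured in-AOI fraction is an
unbiased binomial estimate of the planted engagement; samples are dropped
(invalid) independently at the configured loss rate. Trial counts per
subject are drawn from 19–36 (the observed range of the paradigm;
mean ≈ 27).

STAI scores are Normal(36, 9) truncated to [20, 80]; the planted coupling is
`beta_unexpected = b0 + b1·(trait − 36) + ε` with `b1 = 0.02` µM per STAI
point by default, plus a shared per-subject hemodynamic offset (SD 0.08 µM)
that gives the group models a genuine random-intercept component. State
anxiety is generated uncoupled.

## Gaze: dwell-time ratio

DTR is valid-in-AOI time over valid tracking time in the half-open window
[cue onset, cue onset + 2.55 s); invalid samples count in neither numerator
nor denominator, and a trial with no valid samples is *missing*, not zero.
Missing-DTR trials are dropped from the design, never imputed. Scaling to
[0.1, 1] for the modulator uses the fixed affine map from the theoretical
[0, 1] domain — not per-subject min–max — so the modulator is comparable
across subjects and well defined for constant series. Subjects need at
least 3 usable trials of each type to be included.

## Channel cleaning

- **Pruning**: separation > 60 mm, or intensity CV > 8% over artifact-free
  samples. CV is computed on intensity; OD input is converted through
  I = exp(−OD) against a unit baseline (whether the original analysis used
  raw intensity or OD for CV is not stated; intensity is the standard
  choice and is flagged in the configuration).
- **Motion detection**: sliding 1 s windows flagged when peak-to-peak OD
  exceeds 0.4, or 15× the channel's SD of sample-to-sample differences;
  flags dilated by ±1 s. The contract (thresholds plus dilation) is
  specified and validated against planted artifacts rather than reproducing
  any particular toolbox's windowing internals.
- **Spline** (p = 0.99): within each masked segment a smoothing spline
  (csaps-style parameter mapped to the scipy penalty as λ = (1−p)/p) is
  subtracted and the segment re-leveled to the preceding clean mean;
  unmasked samples are untouched. Spline and wavelet are applied
  sequentially to all channels.
- **Wavelet** (IQR = 0.8, db2, up to ⌊log₂N⌋−1 levels): detail coefficients
  outside the quartile fences are zeroed. Transients concentrate in few
  large coefficients and are removed; oscillations spread across many
  coefficients set the fences themselves and survive.
- **TDDR**: split at 0.5 Hz; on the slow part's first difference, iterate
  Tukey bisquare weights (c = 4.685, σ = 1.4826·median|r|, residuals
  centered on the weighted mean) to convergence, then shrink the
  *deviations around the robust mean* — d → µ + w·(d − µ) — integrate, and
  add the fast part back. Keeping µ means a constant derivative (a pure
  trend) passes unchanged; the published reference drops µ, which detrends
  as a side effect but is otherwise equivalent (our outputs agree with the
  mne implementation to r > 0.97 interior on artifact-free data and match
  its artifact residuals to a fraction of a percent). A known property of
  the algorithm — ours and the reference alike — is multiplicative
  attenuation of responses whose derivative is comparable to the slow-band
  noise derivative (E[ψ′] ≈ 0.76 under Gaussian-dominated slow noise);
  amplitudes are faithfully preserved only in the intended operating regime
  where slow noise (e.g. vasomotor oscillation) dominates the derivative
  distribution. The HRF-recovery test therefore plants an
  oscillation-dominated background.
- **Band-pass** 0.01–0.5 Hz: Kaiser-window FIR (34 dB design, transition
  half-width f_lo), applied forward–backward for zero phase so bin-indexed
  FIR averaging carries no latency bias. The design meets ≥20 dB
  attenuation at f_lo/2 and 2·f_hi with ≤5% passband ripple; it needs
  ≈180 s of data at 4.6 Hz and raises an explicit error naming the minimum
  length on shorter input.
- **Beer–Lambert**: per source–detector pair,
  ΔOD(λ) = [ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR]·d·DPF is solved for (ΔHbO, ΔHbR)
  with DPF = 5.1 at both wavelengths. Pairs missing a wavelength yield
  missing hemoglobin. Extinction coefficients ship in-source (natural-log
  convention, cm⁻¹ M⁻¹, converted to mm⁻¹ µM⁻¹).
- **Epoching**: 9 s epochs from 2 s before outcome onset; the 2 s pre-onset
  mean is the baseline, per epoch and channel.

Two stage orders are encoded as presets. Image branch: detect → spline →
wavelet → band-pass → Beer–Lambert → epoch → reconstruct. ROI/GLM branch:
trim (2 s before first event to 3 s after last event end) → resample to
4 Hz (polyphase, anti-aliased) → TDDR → Beer–Lambert → ROI aggregation →
FIR GLM.

## Forward model and reconstruction

Finite-element fluence modeling on a layered infant mesh is out of scope;
the package substitutes the continuous-wave diffusion approximation for a
semi-infinite homogeneous medium with an extrapolated boundary
(µa = 0.017 mm⁻¹, µs′ = 0.74 mm⁻¹, n = 1.4 by default; optical properties
are configurable since none are published for the emulated system).
Channel sensitivity to nodal absorption is the Rytov adjoint product
J[c,n] = Φ(s→n)·Φ(n→d)/Φ(s→d)·v. The toy cortex is a regular node grid
8–26 mm deep under the 12-tile probe patch; the six ROIs are disks standing
in for atlas parcels, so absolute anatomical placement is not comparable to
a registered atlas — only the algebra and the weighting method are.

The inverse is zeroth-order Tikhonov, x = Jᵀ(JJᵀ + λ·s·I)⁻¹y with λ = 0.01
and s the largest diagonal entry of JJᵀ (the scaling convention is recorded
in output provenance, since only the hyperparameter value itself is
conventional). Two-wavelength absorption images are unmixed node-wise
through the extinction matrix. ROI channel weights are proportional to a
channel's total |J| over the ROI's nodes, over channels with 12–45 mm
separation, normalized to sum to one; missing channels are renormalized
out at aggregation time.

## GLM

The FIR design has 28 unit-impulse regressors per condition at lags
0..27 samples. Bin b is labeled to cover [(b−1)/rate, b/rate) post-onset;
the summary window "bins 12–24 (3–6 s)" resolves under the labeled
convention to internal bins 13–24, i.e. exactly [3.00, 6.00) s at 4 Hz —
the mapping is explicit in `bins_to_window` and configurable. The
engagement modulator is a single column — scaled-DTR stick heights at all
usable onsets convolved with the canonical HRF — shared across conditions
and *not* orthogonalized against the condition regressors; collinearity is
monitored via the design condition number with a warning at 1e6 (a constant
DTR makes the modulator proportional to the summed canonical condition
regressors). Intercept and linear drift are always appended: trimming and
filtering make them near-degenerate, but they stabilize small-sample fits.

Fitting (AR-IRLS): iterate (1) Tukey bisquare robust regression
(c = 4.685, 95% efficiency) on the whitened model, (2) AR order selection
by BIC over 0..⌈4·rate⌉ via Levinson–Durbin/Yule–Walker on the residuals,
(3) AR whitening of response and design; stop at relative β change < 1e-4
or 20 iterations. The residual autocovariance is computed with the robust
weights (products w_t·w_{t+k}): an unweighted estimate is biased toward
whiteness by spike contamination, which under-whitens and understates the
standard errors (95% CI coverage ~0.86 instead of ~0.93 at 5% spike
contamination). Standard errors come from the final whitened robust fit;
degrees of freedom are (whitened samples − parameters). An exact-fit early
exit returns the least-squares solution when residuals vanish, where robust
scale estimation is degenerate.

Canonical HRF: h(t) = (t/p)^k·exp(k(1−t/p)), unit peak at p = 4 s, shape
k = 6. Note the kernel's tail is non-negligible at 7 s (~0.3 of peak), so a
28-bin FIR window does not span the full response; exact-recovery tests use
enough bins to cover the kernel, while the default 28-bin analysis measures
the response relative to the unmodeled steady-state tail, attenuating
betas by a condition-independent factor — contrasts and group inferences
are unaffected.

Contrasts are wᵀβ with t = wᵀβ/SE at the fit's dof; the main-analysis
family for Benjamini–Hochberg is 6 ROIs × 2 contrasts = 12 tests at
q = 0.05, applied per chromophore.

## Group models

The random-intercept linear mixed model is estimated by REML (ML
switchable), profiling the likelihood over the variance ratio
σ²_subject/σ²_resid with closed-form GLS via Sherman–Morrison per subject;
the profiled REML log-likelihood matches the exact multivariate-normal
marginal. Fixed effects are tested with a Satterthwaite-style approximation:
ν = 2g²/(∇gᵀA∇g), where g is the contrast variance as a function of the
variance components and A is the inverse numerical REML information.
Subject-level effects land near the subject count, trial-level effects near
the trial count (e.g. ~810 for the condition effect with 31 × 27 trials),
mirroring the fractional dof convention of the lme4/lmerTest ecosystem.
At the σ²_subject = 0 boundary the fit is flagged and dof fall back to the
residual value. Zero between-subject variance reduces the fit to ordinary
regression.

Nakagawa R²: R²m = σ²_fixed/(σ²_fixed+σ²_subject+σ²_resid), with σ²_fixed
the variance of fixed-effect predictions over rows; R²c adds σ²_subject to
the numerator.

The anxiety model is `beta ∼ −1 + cond + cond:TraitAnxiety + (1|subject)`
on the n = 25 subset with maternal scores; the unexpected-condition slope
is the quantity of interest, and under the planted-null generator its test
rejects at 5.0% over 500 cohorts (Satterthwaite calibration). Logistic
prediction of clinical status (STAI > 40) from the right-mPFC
unexpected-event response is a maximum-likelihood fit with a Wald test;
perfect separation is flagged rather than reported as a finite estimate.
Reported dof follow each fitted model; no attempt is made to
reverse-engineer pooling conventions that are not fully described for the
emulated analysis.

## The engagement-confound mechanism

The package's central scientific property: when attention couples into the
response (a < 1) and engagement differs by condition, a GLM without the DTR
modulator attributes engagement differences to condition. With equal planted
condition gains, the shared modulator makes the contrast estimator exactly
unbiased — the acceptance test plants that structure (a = 0.4, equal gains,
engagement 0.10 lower on unexpected trials) and verifies material bias
without the modulator (>3× the Monte-Carlo SE over 500 replicates) and no
detectable bias with it. With *unequal* gains, the multiplicative coupling
implies condition-specific engagement slopes that one shared modulator
cannot fully absorb; a qualitative test verifies the practical consequence:
the naive contrast is attenuated toward null and modeling engagement moves
it toward the planted difference — condition effects emerge only when
engagement is modeled.

## Problem sizes

Monte-Carlo suites are sized for a desktop run: recovery and calibration
loops use a single source–detector pair and canonical-basis fits
(300–500 replicates), group-model simulations use truth-level DTR/beta
tables (binomial gaze sampling without materializing 100 Hz traces), and
pipeline smoke tests use 2-subject cohorts on reduced tile grids. The
statistical contracts they verify are size-invariant (unbiasedness,
coverage, type-I error); what changes with size is only Monte-Carlo
resolution.

## Known limitations

- The analytic semi-infinite forward model ignores curvature, layered
  optics and anisotropy; reconstructed positions are only meaningful
  relative to the toy geometry.
- The DTR generator is linear-Gaussian clipped to [0, 1]; real infant gaze
  has fixation/saccade structure, autocorrelated dropout, and floor/ceiling
  masses that the binomial model does not emulate, so passing recovery
  tests demonstrate estimator correctness, not robustness to eye-tracker
  pathology.
- TDDR's small-signal attenuation outside its operating regime (above) is
  inherited from the algorithm, not corrected.
- The logistic prediction uses ~25 subjects; separation is common at that
  size and is surfaced as a flag instead of an estimate.
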