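"""Synthetic cohorts with the paradigm's timing, gaze, optical and anxiety structure.

Every downstream stage of the package is testable against data produced
here: jittered trial schedules with 80/20 expected/unexpected outcomes,
100 Hz gaze traces whose in-AOI fraction is an unbiased estimate of a
planted per-trial engagement (dwell-time ratio), 4.6 Hz two-wavelength
optical-density channel data carrying HRF-shaped responses whose amplitude
is coupled to engagement, and per-subject maternal STAI anxiety scores
coupled to the unexpected-event response amplitude.

The attention-coupling model: the trial response amplitude is
``beta_condition * (a + (1 - a) * dtr_true)`` with coupling ``a`` in [0, 1];
at ``a = 1`` engagement has no effect and planted betas are exactly
recoverable by the GLM stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import optics
from .containers import CONDITIONS, EXPECTED, UNEXPECTED, ChannelTimeseries, ProbeLayout, Trial, TrialSchedule, default_probe
from .gaze import GazeRecording
from .glm import canonical_hrf

DEFAULT_OPTICAL_RATE_HZ = 4.6
DEFAULT_GAZE_RATE_HZ = 100.0


def generate_trial_schedule(
    n_trials: int,
    p_expected: float = 0.8,
    seed: int = 0,
    cue_dur_s: float = 0.75,
    stim_dur_s: float = 1.8,
    baseline_range_s: tuple[float, float] = (3.0, 5.0),
) -> TrialSchedule:
    """Draw a session schedule: jittered baseline, cue, outcome window.

    Each trial is a 750 ms audio cue followed by a 1800 ms stimulus window
    (the cued cartoon appears with probability ``p_expected``; otherwise the
    outcome is omitted — an unexpected trial), preceded by a baseline drawn
    uniformly from ``baseline_range_s``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 < p_expected <= 1.0:
        raise ValueError("p_expected must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    t = 0.0
    trials = []
    for _ in range(n_trials):
        t += rng.uniform(*baseline_range_s)
        cue_onset = t
        stim_onset = cue_onset + cue_dur_s
        ttype = EXPECTED if rng.random() < p_expected else UNEXPECTED
        trials.append(Trial(cue_onset_s=cue_onset, stim_onset_s=stim_onset, type=ttype))
        t = stim_onset + stim_dur_s
    session_end = t + rng.uniform(*baseline_range_s)
    return TrialSchedule(
        trials=tuple(trials),
        cue_dur_s=cue_dur_s,
        stim_dur_s=stim_dur_s,
        baseline_range_s=baseline_range_s,
        session_end_s=session_end,
    )


@dataclass
class GroundTruth:
    """Planted per-subject effects and per-trial engagement.

    Units: betas in uM (HbO response amplitude at full engagement), anxiety
    on the 20-80 STAI scale, engagement quantities as ratios in [0, 1].
    """

    beta_expected: float = 0.3
    beta_unexpected: float = 0.5
    trait_anxiety: float = 36.0
    state_anxiety: float = 36.0
    engagement_intercept: float = 0.75
    habituation_slope: float = -0.010  # ratio per trial
    condition_gaze_effect: float = -0.10  # DTR shift on unexpected trials
    attention_coupling: float = 0.5  # a in beta*(a + (1-a)*DTR)
    anxiety_slope: float = 0.0  # uM per STAI point, on beta_unexpected
    hbr_ratio: float = -0.5  # planted dHbR = ratio * dHbO
    dtr_true: np.ndarray | None = None
    artifacts: list[dict] = field(default_factory=list)

    def plant_dtr(self, schedule: TrialSchedule, rng: np.random.Generator, noise_sd: float = 0.20) -> None:
        """Fill per-trial true DTR from intercept, habituation and condition."""
        n = schedule.n_trials
        d = (
            self.engagement_intercept
            + self.habituation_slope * np.arange(n)
            + self.condition_gaze_effect * (schedule.types == UNEXPECTED)
            + rng.normal(0.0, noise_sd, n)
        )
        self.dtr_true = np.clip(d, 0.0, 1.0)


def make_ground_truth(schedule: TrialSchedule, seed: int = 0, dtr_noise_sd: float = 0.20, **kw) -> GroundTruth:
    rng = np.random.default_rng(seed)
    truth = GroundTruth(**kw)
    truth.plant_dtr(schedule, rng, noise_sd=dtr_noise_sd)
    return truth


def generate_gaze(
    schedule: TrialSchedule,
    truth: GroundTruth,
    sample_rate_hz: float = DEFAULT_GAZE_RATE_HZ,
    loss_rate: float = 0.05,
    seed: int = 0,
    screen_px: tuple[int, int] = (1920, 1080),
    baseline_look_rate: float = 0.6,
) -> GazeRecording:
    """Simulate a gaze trace whose per-trial in-AOI fraction estimates dtr_true.

    Within each trial window every sample is independently on-screen with
    probability ``dtr_true`` of that trial, so the measured dwell-time ratio
    is an unbiased estimate of the planted one. Samples are dropped (flagged
    invalid) independently with probability ``loss_rate``; off-AOI samples
    are placed off-screen.
    """
    if schedule.n_trials == 0:
        raise ValueError("schedule has no trials")
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    if not 0.0 <= loss_rate < 1.0:
        raise ValueError("loss_rate must lie in [0, 1)")
    if truth.dtr_true is None or len(truth.dtr_true) != schedule.n_trials:
        raise ValueError("truth.dtr_true must be planted for this schedule")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, schedule.session_end_s, 1.0 / sample_rate_hz)
    n = len(t)
    p_look = np.full(n, baseline_look_rate)
    win_len = schedule.cue_dur_s + schedule.stim_dur_s
    for i, t0 in enumerate(schedule.cue_onsets):
        sel = (t >= t0) & (t < t0 + win_len)
        p_look[sel] = truth.dtr_true[i]
    on_screen = rng.random(n) < p_look
    valid = rng.random(n) >= loss_rate
    w, h = screen_px
    x = np.where(on_screen, rng.uniform(0, w, n), rng.uniform(-200, -50, n))
    y = np.where(on_screen, rng.uniform(0, h, n), rng.uniform(0, h, n))
    return GazeRecording(time_s=t, x_px=x, y_px=y, valid=valid, screen_px=screen_px)


@dataclass
class NoiseConfig:
    """Optical-density noise model for the channel generator.

    Defaults are chosen for pipeline test coverage (each component exercises
    one cleaning stage) rather than for physiological realism; cardiac noise
    sits at 2.0 Hz, below the 2.3 Hz Nyquist of 4.6 Hz sampling.
    """

    white_sd: float = 2e-3  # OD, AR(1) innovation scale
    ar1_phi: float = 0.5
    drift_amp: float = 5e-3  # OD
    drift_freq_hz: float = 0.003
    cardiac_amp: float = 1e-3  # OD
    cardiac_freq_hz: float = 2.0
    spike_rate_per_min: float = 0.0
    spike_amp: float = 0.05  # OD
    spike_width_s: float = 0.4
    shift_rate_per_min: float = 0.0
    shift_amp: float = 0.02  # OD

    @classmethod
    def quiet(cls) -> "NoiseConfig":
        """No noise at all — for exact-recovery oracles."""
        return cls(white_sd=0.0, ar1_phi=0.0, drift_amp=0.0, cardiac_amp=0.0)


def trial_amplitudes(schedule: TrialSchedule, truth: GroundTruth) -> np.ndarray:
    """Planted per-trial HbO response amplitudes (uM), engagement-coupled."""
    a = truth.attention_coupling
    beta = np.where(schedule.types == UNEXPECTED, truth.beta_unexpected, truth.beta_expected)
    return beta * (a + (1.0 - a) * truth.dtr_true)


def hb_signal(
    schedule: TrialSchedule,
    truth: GroundTruth,
    rate_hz: float = DEFAULT_OPTICAL_RATE_HZ,
    hrf_peak_s: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless (dHbO, dHbR) truth signal (uM) on the session time grid."""
    n = int(np.ceil(schedule.session_end_s * rate_hz))
    sticks = np.zeros(n)
    idx = np.round(schedule.stim_onsets * rate_hz).astype(int)
    amps = trial_amplitudes(schedule, truth)
    for i, a in zip(idx, amps):
        if 0 <= i < n:
            sticks[i] += a
    kern = canonical_hrf(np.arange(0.0, 20.0, 1.0 / rate_hz), peak_s=hrf_peak_s)
    hbo = np.convolve(sticks, kern)[:n]
    return hbo, truth.hbr_ratio * hbo


def generate_channel_data(
    schedule: TrialSchedule,
    truth: GroundTruth,
    probe: ProbeLayout,
    noise_cfg: NoiseConfig | None = None,
    seed: int = 0,
    rate_hz: float = DEFAULT_OPTICAL_RATE_HZ,
    dpf: float = optics.DEFAULT_DPF,
) -> tuple[ChannelTimeseries, GroundTruth]:
    """Simulate two-wavelength OD channel data for one subject.

    Every channel sees the same underlying hemoglobin response (spatially
    homogeneous activation), mapped to OD through the same extinction matrix
    that the Beer-Lambert inversion later uses, plus independent noise and
    artifacts. Planted spikes and baseline shifts are appended to
    ``truth.artifacts`` and the (timeseries, truth) pair is returned.
    """
    noise_cfg = noise_cfg or NoiseConfig()
    rng = np.random.default_rng(seed)
    hbo, hbr = hb_signal(schedule, truth, rate_hz=rate_hz)
    n = len(hbo)
    t = np.arange(n) / rate_hz

    wavelengths = tuple(sorted(probe.wavelengths_nm))
    E = optics.extinction_matrix(wavelengths)  # raises for unknown wavelengths
    wl_row = {wl: i for i, wl in enumerate(wavelengths)}
    tbl = probe.channels
    unknown = set(tbl["wavelength_nm"]) - set(wavelengths)
    if unknown:
        raise ValueError(f"channel table has unknown wavelengths: {sorted(unknown)}")

    data = np.empty((len(tbl), n))
    wl_idx = tbl["wavelength_nm"].map(wl_row).to_numpy()
    dist = tbl["distance_mm"].to_numpy()
    L = dist * dpf
    data[:] = (
        np.outer(E[wl_idx, 0] * L, hbo) + np.outer(E[wl_idx, 1] * L, hbr)
    )

    nc = len(tbl)
    if noise_cfg.white_sd > 0:
        w = rng.normal(0.0, noise_cfg.white_sd, (nc, n))
        if noise_cfg.ar1_phi:
            w = sps.lfilter([1.0], [1.0, -noise_cfg.ar1_phi], w, axis=1)
        data += w
    if noise_cfg.drift_amp > 0:
        ph = rng.uniform(0, 2 * np.pi, nc)
        data += noise_cfg.drift_amp * np.sin(2 * np.pi * noise_cfg.drift_freq_hz * t + ph[:, None])
    if noise_cfg.cardiac_amp > 0:
        ph = rng.uniform(0, 2 * np.pi, nc)
        data += noise_cfg.cardiac_amp * np.sin(2 * np.pi * noise_cfg.cardiac_freq_hz * t + ph[:, None])

    minutes = n / rate_hz / 60.0
    for ch in range(nc):
        for _ in range(rng.poisson(noise_cfg.spike_rate_per_min * minutes)):
            t0 = rng.uniform(0, t[-1])
            amp = noise_cfg.spike_amp * rng.choice([-1, 1]) * rng.uniform(0.5, 1.5)
            data[ch] += amp * np.exp(-np.abs(t - t0) / noise_cfg.spike_width_s)
            truth.artifacts.append({"channel": ch, "time_s": t0, "kind": "spike", "amplitude": amp})
        for _ in range(rng.poisson(noise_cfg.shift_rate_per_min * minutes)):
            t0 = rng.uniform(0, t[-1])
            amp = noise_cfg.shift_amp * rng.choice([-1, 1]) * rng.uniform(0.5, 1.5)
            data[ch] += amp * (t >= t0)
            truth.artifacts.append({"channel": ch, "time_s": t0, "kind": "shift", "amplitude": amp})

    ts = ChannelTimeseries(data=data, rate_hz=rate_hz, channels=tbl.copy().reset_index(drop=True), kind="od")
    return ts, truth


@dataclass
class AnxietyConfig:
    """Maternal STAI generation and its coupling to neural responses.

    STAI scores are drawn Normal(36, 9) truncated to the instrument's 20-80
    range; the clinical fraction (score > 40) is controlled by the mean.
    ``slope`` couples trait anxiety to the unexpected-event amplitude
    (uM per STAI point, applied to the mean-centered trait score); state
    anxiety is generated uncoupled.
    """

    trait_mean: float = 36.0
    trait_sd: float = 9.0
    state_mean: float = 36.0
    state_sd: float = 9.0
    score_range: tuple[float, float] = (20.0, 80.0)
    clinical_cutoff: float = 40.0
    beta_expected_mean: float = 0.3
    beta_unexpected_base: float = 0.5
    beta_between_sd: float = 0.1
    subject_offset_sd: float = 0.08  # shared hemodynamic-gain offset per subject
    slope: float = 0.02  # uM per STAI point (default coupling when planted)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


@dataclass
class SubjectRecord:
    subject: int
    schedule: TrialSchedule
    truth: GroundTruth


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    anxiety_cfg: AnxietyConfig
    b1: float

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            d = asdict(s.truth)
            d.pop("dtr_true")
            d.pop("artifacts")
            d["subject"] = s.subject
            d["n_trials"] = s.schedule.n_trials
            rows.append(d)
        return pd.DataFrame(rows)


def generate_cohort(
    n_subjects: int = 25,
    anxiety_cfg: AnxietyConfig | None = None,
    b1: float | None = None,
    seed: int = 0,
    n_trials: int | None = None,
    p_expected: float = 0.8,
    attention_coupling: float = 0.5,
    condition_gaze_effect: float = -0.10,
) -> Cohort:
    """Generate a cohort of subjects with anxiety-coupled unexpected betas.

    The planted coupling is ``beta_unexpected_i = b0 + b1*(trait_i - mean) +
    eps_i``; state anxiety is generated uncoupled. The anxiety analyses of
    the emulated study use n = 25 (mothers who completed the STAI); the
    gaze/GLM analyses use n = 31. Trial counts per subject are drawn from
    the observed range (about 19 to 36, mean near 27) unless fixed.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    cfg = anxiety_cfg or AnxietyConfig()
    if b1 is None:
        b1 = cfg.slope
    if cfg.trait_sd == 0 and b1 != 0:
        warnings.warn("trait anxiety variance is zero but b1 != 0; the coupling is unidentifiable")
    rng = np.random.default_rng(seed)
    lo, hi = cfg.score_range
    trait = _truncated_normal(rng, cfg.trait_mean, cfg.trait_sd, lo, hi, n_subjects)
    state = _truncated_normal(rng, cfg.state_mean, cfg.state_sd, lo, hi, n_subjects)
    subjects = []
    for i in range(n_subjects):
        nt = n_trials if n_trials is not None else int(rng.integers(19, 37))
        schedule = generate_trial_schedule(nt, p_expected=p_expected, seed=int(rng.integers(0, 2**31 - 1)))
        offset = rng.normal(0, cfg.subject_offset_sd)
        truth = GroundTruth(
            beta_expected=cfg.beta_expected_mean + offset + rng.normal(0, cfg.beta_between_sd),
            beta_unexpected=cfg.beta_unexpected_base
            + offset
            + b1 * (trait[i] - cfg.trait_mean)
            + rng.normal(0, cfg.beta_between_sd),
            trait_anxiety=float(trait[i]),
            state_anxiety=float(state[i]),
            engagement_intercept=float(_truncated_normal(rng, 0.75, 0.26, 0.05, 0.95, 1)[0]),
            attention_coupling=attention_coupling,
            condition_gaze_effect=condition_gaze_effect,
            anxiety_slope=b1,
        )
        truth.plant_dtr(schedule, rng)
        subjects.append(SubjectRecord(subject=i, schedule=schedule, truth=truth))
    return Cohort(subjects=subjects, anxiety_cfg=cfg, b1=b1)


def simulate_dtr_table(cohort: Cohort, seed: int = 0, samples_per_trial: int = 255) -> pd.DataFrame:
    """Measured per-trial DTRs for a cohort, simulated at the truth level.

    Each measured DTR is a binomial fraction over ``samples_per_trial``
    valid gaze samples (the count a 2.55 s window holds at 100 Hz), the same
    sampling law the full gaze trace induces, without materializing 100 Hz
    recordings. Long format: subject, trial, type, dtr.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in cohort.subjects:
        meas = rng.binomial(samples_per_trial, s.truth.dtr_true) / samples_per_trial
        for j in range(s.schedule.n_trials):
            rows.append(
                {
                    "subject": s.subject,
                    "trial": j,
                    "type": s.schedule.types[j],
                    "condition": s.schedule.types[j],
                    "dtr": meas[j],
                }
            )
    return pd.DataFrame(rows)


def simulate_beta_table(
    cohort: Cohort,
    measurement_sd: float = 0.08,
    seed: int = 0,
    roi: str = "R_mPFC",
    chromophore: str = "HbO",
) -> pd.DataFrame:
    """Measured subject x condition betas with estimation noise, long format.

    Emulates the output of the single-ROI GLM stage at its default SNR
    (within-subject beta standard error ~0.08 uM) without running per-channel
    fits; used by the group-inference simulations.
    """
    rng = np.random.default_rng(seed)
    cut = cohort.anxiety_cfg.clinical_cutoff
    rows = []
    for s in cohort.subjects:
        for cond, beta in ((EXPECTED, s.truth.beta_expected), (UNEXPECTED, s.truth.beta_unexpected)):
            rows.append(
                {
                    "subject": s.subject,
                    "roi": roi,
                    "chromophore": chromophore,
                    "condition": cond,
                    "beta": beta + rng.normal(0, measurement_sd),
                    "trait_anxiety": s.truth.trait_anxiety,
                    "state_anxiety": s.truth.state_anxiety,
                    "clinical": s.truth.trait_anxiety > cut,
                }
            )
    return pd.DataFrame(rows)


__all__ = [
    "AnxietyConfig",
    "Cohort",
    "GroundTruth",
    "NoiseConfig",
    "SubjectRecord",
    "default_probe",
    "generate_channel_data",
    "generate_cohort",
    "generate_gaze",
    "generate_trial_schedule",
    "hb_signal",
    "make_ground_truth",
    "simulate_beta_table",
    "simulate_dtr_table",
    "trial_amplitudes",
]
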