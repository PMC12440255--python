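"""Channel-space cleaning for optical timeseries.

Implements the two cleaning chains used by the analysis: the image branch
(motion detection -> spline -> wavelet -> band-pass -> Beer-Lambert ->
epoching) and the ROI/GLM branch (trim/resample -> TDDR -> Beer-Lambert ->
ROI aggregation). Parameters keep the names they are usually printed under
(tMotion, tMask, STDEV, AMPthresh, p, IQR, DPF).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pywt
from scipy import interpolate, signal
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from . import optics
from .containers import ChannelTimeseries, EpochSet, MotionMask, ProbeLayout, TrialSchedule


# ---------------------------------------------------------------------------
# channel pruning
# ---------------------------------------------------------------------------

def prune_channels(
    ts: ChannelTimeseries,
    probe: ProbeLayout | None = None,
    max_sep_mm: float = 60.0,
    cv_max: float = 8.0,
    mask: MotionMask | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Reject channels by source-detector separation and coefficient of variation.

    A channel is rejected if its separation exceeds ``max_sep_mm`` (default
    60 mm) or its intensity coefficient of variation over artifact-free
    samples exceeds ``cv_max`` percent (default 8%). CV is computed on
    intensity; optical-density input is converted through I = exp(-OD)
    relative to a unit baseline. Returns (keep flags, report frame with
    columns channel, distance_mm, cv_percent, keep, reason).
    """
    dist = ts.channels["distance_mm"].to_numpy()
    if ts.kind == "intensity":
        inten = ts.data
    elif ts.kind == "od":
        inten = np.exp(-ts.data)
    else:
        raise ValueError("prune_channels requires intensity or od data")
    times = ts.times
    keep = np.ones(ts.n_channels, dtype=bool)
    cvs = np.full(ts.n_channels, np.nan)
    reasons = [""] * ts.n_channels
    for c in range(ts.n_channels):
        if dist[c] > max_sep_mm:
            keep[c] = False
            reasons[c] = f"separation {dist[c]:.1f} mm > {max_sep_mm} mm"
        x = inten[c]
        if mask is not None:
            x = x[~mask.sample_mask(c, times)]
        if x.size == 0:
            keep[c] = False
            reasons[c] = (reasons[c] + "; " if reasons[c] else "") + "uncomputable CV (no artifact-free samples)"
            continue
        m = x.mean()
        cv = 100.0 * x.std() / abs(m) if m != 0 else np.inf
        cvs[c] = cv
        if cv > cv_max:
            keep[c] = False
            reasons[c] = (reasons[c] + "; " if reasons[c] else "") + f"CV {cv:.2f}% > {cv_max}%"
    report = pd.DataFrame(
        {"channel": np.arange(ts.n_channels), "distance_mm": dist, "cv_percent": cvs, "keep": keep, "reason": reasons}
    )
    return keep, report


# ---------------------------------------------------------------------------
# motion detection
# ---------------------------------------------------------------------------

def detect_motion(
    ts: ChannelTimeseries,
    t_motion_s: float = 1.0,
    t_mask_s: float = 1.0,
    std_thresh: float = 15.0,
    amp_thresh: float = 0.4,
) -> MotionMask:
    """Flag motion artifacts per channel on optical-density data.

    Any sliding window of ``t_motion_s`` whose peak-to-peak OD change exceeds
    ``amp_thresh``, or exceeds ``std_thresh`` times the channel's standard
    deviation of sample-to-sample differences, is flagged and dilated by
    +/- ``t_mask_s``.
    """
    if ts.kind != "od":
        raise ValueError("detect_motion expects optical-density data")
    w = int(round(t_motion_s * ts.rate_hz))
    if w < 2:
        raise ValueError("t_motion_s must span at least 2 samples at this rate")
    dilate = int(round(t_mask_s * ts.rate_hz))
    segments = []
    dt = 1.0 / ts.rate_hz
    for c in range(ts.n_channels):
        x = ts.data[c]
        ptp = maximum_filter1d(x, size=w) - minimum_filter1d(x, size=w)
        sd = np.diff(x).std() if len(x) > 1 else 0.0
        bad = (ptp > amp_thresh) | ((sd > 0) & (ptp > std_thresh * sd))
        if dilate > 0 and bad.any():
            bad = maximum_filter1d(bad.astype(np.uint8), size=2 * dilate + 1).astype(bool)
        segs = []
        if bad.any():
            idx = np.flatnonzero(bad)
            starts = idx[np.r_[True, np.diff(idx) > 1]]
            ends = idx[np.r_[np.diff(idx) > 1, True]]
            segs = [(ts.t0_s + s * dt, ts.t0_s + e * dt) for s, e in zip(starts, ends)]
        segments.append(MotionMask.merge(segs))
    return MotionMask(segments)


# ---------------------------------------------------------------------------
# motion correction: spline, wavelet, TDDR
# ---------------------------------------------------------------------------

def correct_spline(ts: ChannelTimeseries, mask: MotionMask, p: float = 0.99) -> ChannelTimeseries:
    """Smoothing-spline correction of masked segments (MATLAB csaps parameter p).

    Within each artifact segment a smoothing spline is fitted and subtracted,
    then the segment is re-leveled so its mean matches the preceding clean
    segment. Samples outside artifact segments are unchanged. Segments
    shorter than 3 samples receive a mean-shift correction only.
    """
    if ts.kind != "od":
        raise ValueError("correct_spline expects optical-density data")
    if not 0.0 < p < 1.0:
        raise ValueError("spline parameter p must lie in (0, 1)")
    lam = (1.0 - p) / p  # csaps trade-off -> scipy penalty weight
    out = ts.copy_with()
    times = ts.times
    for c in range(ts.n_channels):
        x = out.data[c]
        for t0, t1 in mask.segments[c]:
            sel = np.flatnonzero((times >= t0) & (times <= t1))
            if sel.size == 0:
                continue
            ref = _preceding_clean_mean(x, times, sel, mask.segments[c], ts.rate_hz)
            if sel.size < 3:
                x[sel] += ref - x[sel].mean()
                continue
            spl = interpolate.make_smoothing_spline(times[sel], x[sel], lam=lam)
            seg = x[sel] - spl(times[sel])
            x[sel] = seg - seg.mean() + ref
    return out


def _preceding_clean_mean(x, times, sel, segs, rate_hz, window_s: float = 2.0) -> float:
    """Mean of up to ``window_s`` of clean data just before a segment."""
    start = sel[0]
    n_back = int(round(window_s * rate_hz))
    lo = max(0, start - n_back)
    idx = np.arange(lo, start)
    if idx.size:
        bad = np.zeros(len(times), dtype=bool)
        for s, e in segs:
            bad |= (times >= s) & (times <= e)
        idx = idx[~bad[idx]]
    if idx.size == 0:
        return float(x[sel[0]])
    return float(x[idx].mean())


def correct_wavelet(ts: ChannelTimeseries, iqr_mult: float = 0.8, wavelet: str = "db2") -> ChannelTimeseries:
    """Wavelet motion correction: zero outlying detail coefficients.

    Per channel: multi-level discrete wavelet decomposition (default db2, up
    to floor(log2(N)) - 1 levels); at each detail level, coefficients outside
    [Q1 - iqr_mult*IQR, Q3 + iqr_mult*IQR] are set to zero; reconstruct.
    Transient artifacts concentrate in few large shallow-level coefficients
    and are removed; oscillations spread over many coefficients set the
    fences themselves and survive.
    """
    if ts.kind != "od":
        raise ValueError("correct_wavelet expects optical-density data")
    n = ts.n_times
    level = min(pywt.dwt_max_level(n, wavelet), max(int(np.floor(np.log2(n))) - 1, 0))
    if level < 1:
        warnings.warn("recording shorter than one wavelet decomposition level; returning input unchanged")
        return ts.copy_with()
    out = ts.copy_with()
    for c in range(ts.n_channels):
        coeffs = pywt.wavedec(out.data[c], wavelet, level=level)
        cleaned = [coeffs[0]]
        for d in coeffs[1:]:
            q1, q3 = np.percentile(d, [25, 75])
            iqr = q3 - q1
            lo, hi = q1 - iqr_mult * iqr, q3 + iqr_mult * iqr
            d = np.where((d < lo) | (d > hi), 0.0, d)
            cleaned.append(d)
        out.data[c] = pywt.waverec(cleaned, wavelet)[:n]
    return out


def correct_tddr(ts: ChannelTimeseries, split_hz: float = 0.5, tukey_c: float = 4.685) -> ChannelTimeseries:
    """Temporal derivative distribution repair.

    Per channel the signal is split at ``split_hz`` into slow and fast parts;
    on the slow part's first difference, Tukey bisquare weights are iterated
    to convergence (sigma = 1.4826 * median |r|, residuals centered by the
    weighted mean; stop at max |dw| < 1e-6 or 50 iterations); the final
    weights shrink the derivative deviations around the robust mean
    (d -> mu + w*(d - mu), so a constant derivative — a pure trend — passes
    unchanged), the result is re-integrated and the fast part added back.
    A constant channel is returned unchanged.
    """
    if ts.kind != "od":
        raise ValueError("correct_tddr expects optical-density data")
    out = ts.copy_with()
    nyq = ts.rate_hz / 2.0
    do_split = 0 < split_hz < nyq
    if do_split:
        sos = signal.butter(3, split_hz / nyq, btype="low", output="sos")
    for c in range(ts.n_channels):
        x = out.data[c]
        if np.allclose(x, x[0]):
            continue
        slow = signal.sosfiltfilt(sos, x) if do_split else x.copy()
        fast = x - slow
        d = np.diff(slow)
        w = _tddr_weights(d, tukey_c)
        mu = np.average(d, weights=w) if w.sum() > 0 else 0.0
        d_new = mu + w * (d - mu)
        corrected = np.concatenate([[slow[0]], slow[0] + np.cumsum(d_new)])
        out.data[c] = corrected + fast
    return out


def _tddr_weights(d: np.ndarray, tukey_c: float, tol: float = 1e-6, max_iter: int = 50) -> np.ndarray:
    w = np.ones_like(d)
    for _ in range(max_iter):
        mu = np.average(d, weights=w) if w.sum() > 0 else d.mean()
        r = d - mu
        sigma = 1.4826 * np.median(np.abs(r))
        if sigma == 0:
            return np.ones_like(d)
        u = r / (tukey_c * sigma)
        w_new = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if np.max(np.abs(w_new - w)) < tol:
            return w_new
        w = w_new
    return w


# ---------------------------------------------------------------------------
# filtering / resampling / conversion
# ---------------------------------------------------------------------------

def bandpass(
    ts: ChannelTimeseries,
    f_lo: float = 0.01,
    f_hi: float = 0.5,
    attenuation_db: float = 34.0,
) -> ChannelTimeseries:
    """Zero-phase FIR band-pass (default 0.01-0.5 Hz).

    A Kaiser-window FIR filter is applied forward-backward (zero phase, no
    latency bias in bin-indexed FIR averaging). The design places transition
    bands so that f_lo/2 and 2*f_hi are attenuated by at least 20 dB after
    the two passes while the passband stays within 5%.
    """
    if not 0 < f_lo < f_hi < ts.rate_hz / 2:
        raise ValueError("need 0 < f_lo < f_hi < Nyquist")
    width = min(f_lo, f_hi)
    numtaps, beta = signal.kaiserord(attenuation_db, width / (ts.rate_hz / 2))
    numtaps |= 1
    if numtaps >= ts.n_times:
        min_s = numtaps / ts.rate_hz
        raise ValueError(
            f"band-pass filter unrealizable: needs at least {numtaps + 1} samples "
            f"({min_s:.0f} s at {ts.rate_hz} Hz), got {ts.n_times}"
        )
    hi_edge = min(1.5 * f_hi, 0.98 * ts.rate_hz / 2)
    taps = signal.firwin(numtaps, [f_lo, hi_edge], pass_zero=False, window=("kaiser", beta), fs=ts.rate_hz)
    out = ts.copy_with()
    padlen = min(3 * numtaps, ts.n_times - 2)
    out.data = signal.filtfilt(taps, [1.0], out.data, axis=1, padlen=padlen)
    return out


def mbll(
    ts: ChannelTimeseries,
    dpf: float = optics.DEFAULT_DPF,
    extinction: np.ndarray | None = None,
    keep: np.ndarray | None = None,
) -> ChannelTimeseries:
    """Modified Beer-Lambert conversion: OD channels -> HbO/HbR pairs (uM).

    Each source-detector pair must have both wavelengths present and
    unpruned; pairs missing a wavelength yield missing (NaN) hemoglobin
    rows. Output rows come in (HbO, HbR) pairs per source-detector pair with
    a ``chromophore`` column in the channel table.
    """
    if ts.kind != "od":
        raise ValueError("mbll expects optical-density data")
    tbl = ts.channels.reset_index(drop=True)
    wavelengths = tuple(sorted(tbl["wavelength_nm"].unique()))
    if len(wavelengths) != 2:
        raise ValueError("mbll requires exactly two wavelengths")
    E = optics.extinction_matrix(wavelengths) if extinction is None else np.asarray(extinction, dtype=float)
    if abs(np.linalg.det(E)) < 1e-18:
        raise ValueError("extinction matrix is singular")
    usable = np.ones(len(tbl), dtype=bool) if keep is None else np.asarray(keep, dtype=bool)

    rows = []
    data_rows = []
    for (src, det), grp in tbl.groupby(["source", "detector"], sort=True):
        dist = float(grp["distance_mm"].iloc[0])
        by_wl = {}
        for i in grp.index:
            if usable[i]:
                by_wl[float(tbl.loc[i, "wavelength_nm"])] = i
        complete = all(wl in by_wl for wl in wavelengths)
        if complete:
            od = np.vstack([ts.data[by_wl[wl]] for wl in wavelengths])
            hb = np.linalg.solve(E, od / (dist * dpf))
        else:
            hb = np.full((2, ts.n_times), np.nan)
        for k, chrom in enumerate(("HbO", "HbR")):
            rows.append({"source": src, "detector": det, "distance_mm": dist, "chromophore": chrom})
            data_rows.append(hb[k])
    return ChannelTimeseries(
        data=np.vstack(data_rows),
        rate_hz=ts.rate_hz,
        channels=pd.DataFrame(rows),
        kind="hb",
        t0_s=ts.t0_s,
    )


def resample_trim(
    ts: ChannelTimeseries,
    target_hz: float = 4.0,
    schedule: TrialSchedule | None = None,
    pre_s: float = 2.0,
    post_s: float = 3.0,
) -> ChannelTimeseries:
    """Trim to [first cue - 2 s, last event end + 3 s], then resample.

    Resampling uses polyphase anti-aliased rational resampling (4.6 -> 4 Hz
    by default). ``t0_s`` is updated to the crop start.
    """
    if target_hz > ts.rate_hz:
        raise ValueError("target_hz must not exceed the source rate")
    out = ts.copy_with()
    if schedule is not None:
        t_start = schedule.cue_onsets[0] - pre_s
        t_end = schedule.trial_ends[-1] + post_s
        times = ts.times
        if schedule.cue_onsets[0] < times[0] - 1e-9 or schedule.trial_ends[-1] > times[-1] + 1e-9:
            raise ValueError("schedule lies outside the recording span")
        sel = (times >= t_start) & (times <= t_end)
        out.data = out.data[:, sel]
        out.t0_s = float(times[sel][0])
    if abs(target_hz - ts.rate_hz) < 1e-12:
        return out
    from fractions import Fraction

    frac = Fraction(target_hz / ts.rate_hz).limit_denominator(1000)
    out.data = signal.resample_poly(out.data, frac.numerator, frac.denominator, axis=1)
    out.rate_hz = target_hz
    return out


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def block_average(
    ts: ChannelTimeseries,
    schedule: TrialSchedule,
    window_s: tuple[float, float] = (-2.0, 7.0),
    baseline_s: tuple[float, float] = (-2.0, 0.0),
) -> EpochSet:
    """Epoch around outcome onsets and subtract the pre-onset baseline.

    Default 9-s epochs from 2 s before onset, baseline = mean over the 2 s
    pre-onset interval, per epoch and channel. Epochs extending past the
    recording end are dropped with a warning.
    """
    if ts.kind != "hb":
        raise ValueError("block_average expects hemoglobin data")
    rate = ts.rate_hz
    n_ep = int(round((window_s[1] - window_s[0]) * rate))
    b0 = int(round((baseline_s[0] - window_s[0]) * rate))
    b1 = int(round((baseline_s[1] - window_s[0]) * rate))
    epochs: dict[str, list[np.ndarray]] = {}
    dropped: dict[str, int] = {}
    for onset, ttype in zip(schedule.stim_onsets, schedule.types):
        i0 = int(round((onset + window_s[0] - ts.t0_s) * rate))
        if i0 < 0 or i0 + n_ep > ts.n_times:
            dropped[ttype] = dropped.get(ttype, 0) + 1
            continue
        ep = ts.data[:, i0 : i0 + n_ep].copy()
        ep -= ep[:, b0:b1].mean(axis=1, keepdims=True)
        epochs.setdefault(ttype, []).append(ep)
    if dropped:
        warnings.warn(f"dropped epochs extending past the recording: {dropped}")
    return EpochSet(
        epochs={k: np.stack(v) for k, v in epochs.items()},
        rate_hz=rate,
        window_s=window_s,
        baseline_s=baseline_s,
        channels=ts.channels,
        dropped=dropped,
    )
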