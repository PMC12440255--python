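"""Eye-tracking dwell-time ratios (DTR) and inclusion rules.

DTR is the per-trial fraction of *valid* gaze time spent inside the area of
interest (AOI), computed over the window from auditory cue onset to the end
of the expected stimulus presentation. Signal loss is handled with a
valid-time denominator: invalid samples count in neither numerator nor
denominator, so a trial with zero valid samples yields a *missing* DTR, not
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CONDITIONS, TrialSchedule

DEFAULT_SCREEN = (1920, 1080)


@dataclass
class GazeRecording:
    """Gaze samples (nominally 100 Hz) with validity flags.

    ``aoi`` is an (x0, y0, x1, y1) rectangle in pixels; the default spans the
    full display.
    """

    time_s: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    screen_px: tuple[int, int] = DEFAULT_SCREEN
    aoi: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.time_s) == len(self.x_px) == len(self.y_px) == len(self.valid)):
            raise ValueError("gaze sample arrays must have equal length")
        if np.any(np.diff(self.time_s) < 0):
            raise ValueError("gaze timestamps must be non-decreasing")
        if self.aoi is None:
            self.aoi = (0.0, 0.0, float(self.screen_px[0]), float(self.screen_px[1]))
        x0, y0, x1, y1 = self.aoi
        if not (0 <= x0 < x1 <= self.screen_px[0] and 0 <= y0 < y1 <= self.screen_px[1]):
            raise ValueError("AOI must lie within the screen bounds")

    def in_aoi(self) -> np.ndarray:
        x0, y0, x1, y1 = self.aoi
        return (self.x_px >= x0) & (self.x_px < x1) & (self.y_px >= y0) & (self.y_px < y1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time_s, "x_px": self.x_px, "y_px": self.y_px, "valid": self.valid.astype(int)}
        )


@dataclass
class DTRSeries:
    """Per-trial dwell-time ratios; NaN marks a trial with no valid samples."""

    dtr: np.ndarray
    valid_time_s: np.ndarray
    windows: list[tuple[float, float]]
    types: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    @property
    def n_trials(self) -> int:
        return len(self.dtr)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.dtr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "type": self.types,
                "dtr": self.dtr,
                "valid_time_s": self.valid_time_s,
            }
        )


def compute_dtr(gaze: GazeRecording, schedule: TrialSchedule) -> DTRSeries:
    """Per-trial DTR over [cue onset, cue onset + cue_dur + stim_dur).

    Samples are attributed to a trial window by timestamp (half-open
    interval); invalid samples are excluded from both numerator and
    denominator. With the default 750 ms cue and 1800 ms stimulus the window
    is 2.55 s long.
    """
    if schedule.n_trials == 0:
        raise ValueError("schedule has no trials")
    if gaze.time_s.size == 0 or gaze.time_s[-1] < schedule.trial_ends[-1] - 1e-9:
        raise ValueError("gaze recording does not cover the schedule's time span")
    in_aoi = gaze.in_aoi()
    dt = _nominal_dt(gaze.time_s)
    dtr = np.full(schedule.n_trials, np.nan)
    valid_time = np.zeros(schedule.n_trials)
    windows: list[tuple[float, float]] = []
    win_len = schedule.cue_dur_s + schedule.stim_dur_s
    for i, t0 in enumerate(schedule.cue_onsets):
        t1 = t0 + win_len
        windows.append((t0, t1))
        sel = (gaze.time_s >= t0) & (gaze.time_s < t1) & gaze.valid
        n_valid = int(sel.sum())
        valid_time[i] = n_valid * dt
        if n_valid:
            dtr[i] = in_aoi[sel].sum() / n_valid
    return DTRSeries(dtr=dtr, valid_time_s=valid_time, windows=windows, types=schedule.types)


def _nominal_dt(time_s: np.ndarray) -> float:
    if len(time_s) < 2:
        return 0.01
    d = np.diff(time_s)
    d = d[d > 0]
    return float(np.median(d)) if d.size else 0.01


def scale_dtr(dtr: "DTRSeries | np.ndarray", lo: float = 0.1, hi: float = 1.0) -> np.ndarray:
    """Affine map of DTR from the theoretical [0, 1] domain onto [lo, hi].

    The map is fixed (x -> lo + (hi-lo)*x), not a per-subject min-max
    rescaling, so the engagement modulator is comparable across subjects and
    well defined for constant series. Missing values stay missing.
    """
    if lo >= hi:
        raise ValueError("scale bounds require lo < hi")
    x = dtr.dtr if isinstance(dtr, DTRSeries) else np.asarray(dtr, dtype=float)
    return lo + (hi - lo) * x


def subject_inclusion(
    dtr: DTRSeries, schedule: TrialSchedule, min_per_type: int = 3
) -> tuple[bool, dict[str, int]]:
    """Inclusion rule: at least ``min_per_type`` usable trials of each type.

    A trial is usable when its DTR is non-missing. Returns the include flag
    and the per-type usable counts.
    """
    if dtr.n_trials != schedule.n_trials:
        raise ValueError("DTR series and schedule are not aligned")
    usable = ~dtr.missing
    types = schedule.types
    counts = {c: int(np.sum(usable & (types == c))) for c in CONDITIONS}
    include = all(counts[c] >= min_per_type for c in CONDITIONS)
    return include, counts


def read_gaze_csv(path, screen_px: tuple[int, int] = DEFAULT_SCREEN) -> GazeRecording:
    df = pd.read_csv(path)
    return GazeRecording(
        time_s=df["time_s"].to_numpy(),
        x_px=df["x_px"].to_numpy(),
        y_px=df["y_px"].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool),
        screen_px=screen_px,
    )


def write_gaze_csv(gaze: GazeRecording, path) -> None:
    gaze.to_frame().to_csv(path, index=False)
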