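"""Shared in-memory containers: trial schedules, probe layouts, channel data.

These types are deliberately thin wrappers over numpy arrays and pandas
frames so that every pipeline stage can be driven, inspected and serialized
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

EXPECTED = "expected"
UNEXPECTED = "unexpected"
CONDITIONS = (EXPECTED, UNEXPECTED)


@dataclass(frozen=True)
class Trial:
    """One trial: auditory cue onset, outcome (stimulus-window) onset, type.

    For unexpected trials ``stim_onset_s`` marks the time the cartoon *would*
    have appeared; events are modelled time-locked to that moment in both
    conditions.
    """

    cue_onset_s: float
    stim_onset_s: float
    type: str

    def __post_init__(self) -> None:
        if self.type not in CONDITIONS:
            raise ValueError(f"unknown trial type {self.type!r}")


@dataclass(frozen=True)
class TrialSchedule:
    """Event schedule of a session.

    The paradigm: a 750 ms audio cue, a 1800 ms stimulus window in which the
    cued cartoon appears (expected) or is omitted (unexpected), separated by
    jittered 3-5 s baselines.
    """

    trials: tuple[Trial, ...]
    cue_dur_s: float = 0.75
    stim_dur_s: float = 1.8
    baseline_range_s: tuple[float, float] = (3.0, 5.0)
    session_end_s: float = 0.0

    def __post_init__(self) -> None:
        onsets = self.cue_onsets
        if len(onsets) and np.any(np.diff(onsets) <= 0):
            raise ValueError("cue onsets must be strictly increasing")
        if len(onsets) and (onsets[0] < 0 or self.trial_ends[-1] > self.session_end_s):
            raise ValueError("trial windows must lie within [0, session_end_s]")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def cue_onsets(self) -> np.ndarray:
        return np.array([t.cue_onset_s for t in self.trials], dtype=float)

    @property
    def stim_onsets(self) -> np.ndarray:
        return np.array([t.stim_onset_s for t in self.trials], dtype=float)

    @property
    def types(self) -> np.ndarray:
        return np.array([t.type for t in self.trials], dtype=object)

    @property
    def trial_ends(self) -> np.ndarray:
        """End of each trial window (cue onset + cue + stimulus duration)."""
        return self.cue_onsets + self.cue_dur_s + self.stim_dur_s

    def counts(self) -> dict[str, int]:
        types = self.types
        return {c: int(np.sum(types == c)) for c in CONDITIONS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": self.cue_onsets,
                "stim_onset_s": self.stim_onsets,
                "duration_s": self.cue_dur_s + self.stim_dur_s,
                "type": self.types,
            }
        )


@dataclass(frozen=True)
class ProbeLayout:
    """Optode geometry and the logical channel table.

    ``channels`` has one row per (source, detector, wavelength) triple with
    columns ``source``, ``detector``, ``wavelength_nm``, ``distance_mm`` and
    ``tile_source`` / ``tile_detector``. The default cap is a 12-tile patch,
    each tile carrying 3 sources and 4 detectors; all cross pairs are logical
    channels, 36 x 48 = 1728 per wavelength.
    """

    sources: np.ndarray  # (n_sources, 3) mm, scalp plane z = 0
    detectors: np.ndarray  # (n_detectors, 3) mm
    channels: pd.DataFrame
    wavelengths_nm: tuple[float, ...]

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_detectors(self) -> int:
        return len(self.detectors)

    def channels_at(self, wavelength_nm: float) -> pd.DataFrame:
        return self.channels[self.channels["wavelength_nm"] == wavelength_nm]

    def pair_table(self) -> pd.DataFrame:
        """Unique source-detector pairs (wavelength collapsed)."""
        cols = ["source", "detector", "distance_mm"]
        return self.channels[cols].drop_duplicates(["source", "detector"]).reset_index(drop=True)


def default_probe(
    n_tile_cols: int = 4,
    n_tile_rows: int = 3,
    tile_spacing_mm: float = 34.0,
    wavelengths_nm: tuple[float, ...] = (735.0, 850.0),
) -> ProbeLayout:
    """Build the default 12-tile cap on a flat scalp patch.

    Each hexagonal tile holds 3 sources (inner triangle, 6 mm radius) and
    4 detectors (outer square, 10.5 mm radius). Real cap geometry is not
    published; this toy patch reproduces the channel-count arithmetic and a
    realistic spread of source-detector separations.
    """
    src_local = 6.0 * np.array(
        [[np.cos(a), np.sin(a), 0.0] for a in np.deg2rad([90, 210, 330])]
    )
    det_local = 10.5 * np.array(
        [[np.cos(a), np.sin(a), 0.0] for a in np.deg2rad([45, 135, 225, 315])]
    )
    sources, detectors, src_tile, det_tile = [], [], [], []
    tile = 0
    for r in range(n_tile_rows):
        for c in range(n_tile_cols):
            center = np.array([c * tile_spacing_mm, r * tile_spacing_mm, 0.0])
            for p in src_local:
                sources.append(center + p)
                src_tile.append(tile)
            for p in det_local:
                detectors.append(center + p)
                det_tile.append(tile)
            tile += 1
    src = np.asarray(sources)
    det = np.asarray(detectors)
    s_idx, d_idx = np.meshgrid(np.arange(len(src)), np.arange(len(det)), indexing="ij")
    s_idx, d_idx = s_idx.ravel(), d_idx.ravel()
    dist = np.linalg.norm(src[s_idx] - det[d_idx], axis=1)
    rows = []
    for wl in wavelengths_nm:
        rows.append(
            pd.DataFrame(
                {
                    "source": s_idx,
                    "detector": d_idx,
                    "wavelength_nm": wl,
                    "distance_mm": dist,
                    "tile_source": np.asarray(src_tile)[s_idx],
                    "tile_detector": np.asarray(det_tile)[d_idx],
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return ProbeLayout(sources=src, detectors=det, channels=table, wavelengths_nm=tuple(wavelengths_nm))


@dataclass
class ChannelTimeseries:
    """Channel x time data with its acquisition metadata.

    ``kind`` is one of ``intensity`` (relative detected intensity), ``od``
    (optical density change) or ``hb`` (hemoglobin concentration change, uM).
    For ``hb`` the channel table carries a ``chromophore`` column (HbO/HbR)
    instead of ``wavelength_nm``.
    """

    data: np.ndarray  # (n_channels, n_times)
    rate_hz: float
    channels: pd.DataFrame
    kind: str = "od"
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x timepoints)")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel table length must match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_times) / self.rate_hz

    def copy_with(self, **kw) -> "ChannelTimeseries":
        out = replace(self)
        out.data = self.data.copy()
        out.channels = self.channels.copy()
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclass
class MotionMask:
    """Per-channel artifact segments, as (start_s, end_s) tuples."""

    segments: list[list[tuple[float, float]]]

    @staticmethod
    def merge(segs: list[tuple[float, float]]) -> list[tuple[float, float]]:
        if not segs:
            return []
        segs = sorted(segs)
        out = [segs[0]]
        for s, e in segs[1:]:
            if s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    def merged(self) -> "MotionMask":
        return MotionMask([MotionMask.merge(s) for s in self.segments])

    def sample_mask(self, channel: int, times: np.ndarray) -> np.ndarray:
        """Boolean array: True where the sample falls inside an artifact."""
        bad = np.zeros(len(times), dtype=bool)
        for s, e in self.segments[channel]:
            bad |= (times >= s) & (times <= e)
        return bad

    def masked_seconds(self, channel: int) -> float:
        return float(sum(e - s for s, e in MotionMask.merge(self.segments[channel])))


@dataclass
class EpochSet:
    """Baseline-corrected epochs: condition -> (trials, channels, timepoints).

    The window is (-2, +7) s around outcome onset (9 s total) and the mean of
    the 2 s pre-onset interval is subtracted per epoch and channel.
    """

    epochs: dict[str, np.ndarray]
    rate_hz: float
    window_s: tuple[float, float] = (-2.0, 7.0)
    baseline_s: tuple[float, float] = (-2.0, 0.0)
    channels: pd.DataFrame | None = None
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def epoch_times(self) -> np.ndarray:
        n = int(round((self.window_s[1] - self.window_s[0]) * self.rate_hz))
        return self.window_s[0] + np.arange(n) / self.rate_hz

    def condition_mean(self, condition: str) -> np.ndarray:
        return self.epochs[condition].mean(axis=0)
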