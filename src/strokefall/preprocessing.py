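"""Signal filtering, impact detection, and lead-time-anchored windowing.

The evaluation window for a fall is a fixed 250-frame (500 ms) segment
ending ``lead_time`` before the detected impact ``t_p``::

    t_s = t_p - t_l - w          t_e = t_p - t_l

with frames 0-based and windows half-open ``[t_s, t_e)``.  Lead times are
given in ms and converted at 500 Hz with a ceiling (``lead_frames =
ceil(t_l / 2)``) so the realized lead is never shorter than requested —
75 ms therefore maps to 38 frames.  Non-fall windows are drawn uniformly
from the latter half of the event region.

Accelerometer channels are band-pass filtered (fourth-order Butterworth,
0.1–50 Hz) zero-phase before impact detection and windowing; gyroscope
channels pass through unfiltered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .synthetic_data import (
    ACCEL_IDX,
    CHANNELS,
    SAMPLING_RATE,
    Dataset,
    EventAnnotation,
    IMURecording,
)

WINDOW_FRAMES = 250  # w: 500 ms at 500 Hz
MIN_LEAD_TIME_MS = 75.0  # shortest lead the intervention hardware allows
BANDPASS_HZ = (0.1, 50.0)
FILTER_ORDER = 4
_MIN_FILTER_LEN = 50

_LOC_ACC = [[CHANNELS.index(f"{loc}_acc_{ax}") for ax in "xyz"] for loc in ("lhip", "rhip", "back")]


class PreprocessingError(ValueError):
    pass


class WindowInfeasibleError(PreprocessingError):
    """The requested window does not fit inside the recording/region."""


class DefectiveDataError(PreprocessingError):
    """The event region carries no usable (non-missing) samples."""


@lru_cache(maxsize=None)
def _design_sos(sampling_rate: int) -> np.ndarray:
    return sps.butter(
        FILTER_ORDER, BANDPASS_HZ, btype="bandpass", fs=sampling_rate, output="sos"
    )


def bandpass_gain(freq_hz: float, sampling_rate: int = SAMPLING_RATE) -> float:
    """Analytic magnitude response of the zero-phase filter at ``freq_hz``.

    Zero-phase (forward-backward) application squares the single-pass
    magnitude response.
    """
    _, h = sps.sosfreqz(_design_sos(sampling_rate), worN=[freq_hz], fs=sampling_rate)
    return float(np.abs(h[0]) ** 2)


def bandpass_filter(series: np.ndarray, sampling_rate: int = SAMPLING_RATE) -> np.ndarray:
    """Zero-phase fourth-order 0.1–50 Hz Butterworth band-pass of one channel."""
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise PreprocessingError("bandpass_filter expects a 1-D series")
    if x.size < _MIN_FILTER_LEN:
        raise PreprocessingError(
            f"series of length {x.size} is shorter than the filter warm-up ({_MIN_FILTER_LEN})"
        )
    if not np.all(np.isfinite(x)):
        raise PreprocessingError("series contains non-finite samples")
    return sps.sosfiltfilt(_design_sos(sampling_rate), x)


def filter_recording(recording: IMURecording) -> IMURecording:
    """Filter the nine accelerometer channels; gyro passes through raw.

    Missing (NaN) stretches from injected defects are preserved: the gap is
    linearly bridged for the filter pass and the NaNs are re-inserted
    afterwards, so missingness stays local to the defective event and
    surfaces again at window extraction, where affected events are excluded.
    """
    data = recording.data.astype(np.float64, copy=True)
    sos = _design_sos(recording.sampling_rate)
    for ci in ACCEL_IDX:
        col = data[:, ci]
        missing = ~np.isfinite(col)
        if missing.all():
            continue
        if missing.any():
            idx = np.arange(col.size)
            col = np.interp(idx, idx[~missing], col[~missing])
        filtered = sps.sosfiltfilt(sos, col)
        filtered[missing] = np.nan
        data[:, ci] = filtered
    return IMURecording(recording.subject_id, data, recording.sampling_rate)


def lead_frames(lead_time_ms: float, sampling_rate: int = SAMPLING_RATE) -> int:
    """Frames of lead time, rounded up so the realized lead is >= requested."""
    if lead_time_ms < 0:
        raise PreprocessingError("lead time must be non-negative")
    return math.ceil(lead_time_ms * sampling_rate / 1000.0)


def detect_impact(recording: IMURecording, event: EventAnnotation) -> int:
    """Impact frame t_p: maximum 3-axis acceleration-vector magnitude,
    maximized over the three sensor locations, within the event region.

    Ties resolve to the earliest frame.  Expects filtered accelerometer
    channels (see :func:`filter_recording`).
    """
    if event.activity_class != "fall":
        raise PreprocessingError(f"detect_impact requires a fall event, got {event.subtype}")
    region = recording.data[event.region_start_frame : event.region_end_frame]
    mags = np.full(region.shape[0], -np.inf)
    for idx in _LOC_ACC:
        mag = np.sqrt(np.nansum(region[:, idx] ** 2, axis=1))
        mag[np.all(np.isnan(region[:, idx]), axis=1)] = -np.inf
        mags = np.maximum(mags, mag)
    if not np.any(np.isfinite(mags)):
        raise DefectiveDataError(f"event {event.event_id}: all accelerometer samples missing")
    return event.region_start_frame + int(np.argmax(mags))


@dataclass
class EventWindow:
    """A 250-frame, 18-channel evaluation window with its anchoring."""

    event_id: str
    subject_id: str
    activity_class: str
    subtype: str
    adl_kind: str | None
    lead_time_ms: float
    start_frame: int
    end_frame: int
    data: np.ndarray  # (250, 18) float64

    def __post_init__(self) -> None:
        if self.end_frame - self.start_frame != WINDOW_FRAMES:
            raise PreprocessingError("window must span exactly 250 frames")
        if self.data.shape != (WINDOW_FRAMES, len(CHANNELS)):
            raise PreprocessingError("window data must be (250, 18)")

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.data).any())


def extract_fall_window(
    recording: IMURecording,
    event: EventAnnotation,
    t_p: int,
    lead_time_ms: float,
) -> EventWindow:
    """Window ``[t_p - lead - w, t_p - lead)`` anchored before the impact."""
    lf = lead_frames(lead_time_ms, recording.sampling_rate)
    t_e = t_p - lf
    t_s = t_e - WINDOW_FRAMES
    if t_s < 0:
        raise WindowInfeasibleError(
            f"event {event.event_id}: window [{t_s}, {t_e}) starts before frame 0"
        )
    return EventWindow(
        event_id=event.event_id,
        subject_id=event.subject_id,
        activity_class=event.activity_class,
        subtype=event.subtype,
        adl_kind=event.adl_kind,
        lead_time_ms=lead_time_ms,
        start_frame=t_s,
        end_frame=t_e,
        data=np.asarray(recording.data[t_s:t_e], dtype=np.float64),
    )


def extract_nonfall_window(
    recording: IMURecording,
    event: EventAnnotation,
    seed: int | np.random.Generator,
) -> EventWindow:
    """Window drawn uniformly within the latter half of the event region.

    The window end is uniform over ``[midpoint, region_end]``; if the
    implied start precedes the region start the draw is repeated (up to 10
    times) and finally clipped to ``[region_start, region_start + 250)``.
    """
    if event.activity_class != "non_fall":
        raise PreprocessingError("extract_nonfall_window requires a non-fall event")
    rs, re = event.region_start_frame, event.region_end_frame
    if re - rs < WINDOW_FRAMES:
        raise WindowInfeasibleError(
            f"event {event.event_id}: region of {re - rs} frames is shorter than the window"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mid = rs + (re - rs) // 2
    for _ in range(10):
        end = int(rng.integers(mid, re + 1))
        if end - WINDOW_FRAMES >= rs:
            break
    else:
        end = rs + WINDOW_FRAMES
    start = end - WINDOW_FRAMES
    return EventWindow(
        event_id=event.event_id,
        subject_id=event.subject_id,
        activity_class=event.activity_class,
        subtype=event.subtype,
        adl_kind=event.adl_kind,
        lead_time_ms=float("nan"),
        start_frame=start,
        end_frame=end,
        data=np.asarray(recording.data[start:end], dtype=np.float64),
    )


def exclude_defective(events: list[EventAnnotation]) -> tuple[list[EventAnnotation], int]:
    """Drop events flagged defective; returns (kept, n_excluded)."""
    kept = [e for e in events if not e.defective]
    return kept, len(events) - len(kept)


@dataclass
class Exclusion:
    event_id: str
    reason: str


@dataclass
class PreprocessedDataset:
    """Filtered recordings plus detected impacts, reusable across lead times."""

    dataset: Dataset
    filtered: dict[str, IMURecording]
    impacts: dict[str, int]  # event_id -> detected t_p (falls only)
    exclusions: list[Exclusion] = field(default_factory=list)


def preprocess_dataset(dataset: Dataset) -> PreprocessedDataset:
    """Filter every recording and detect every fall impact once.

    Defective-flagged events are excluded here (mirroring the flag-and-
    remove rule); falls whose region is entirely missing are excluded as
    defective.
    """
    filtered = {sid: filter_recording(rec) for sid, rec in dataset.recordings.items()}
    impacts: dict[str, int] = {}
    exclusions: list[Exclusion] = []
    for ann in dataset.annotations:
        if ann.defective:
            exclusions.append(Exclusion(ann.event_id, "defective"))
            continue
        if ann.activity_class != "fall":
            continue
        try:
            impacts[ann.event_id] = detect_impact(filtered[ann.subject_id], ann)
        except DefectiveDataError:
            exclusions.append(Exclusion(ann.event_id, "defective"))
    return PreprocessedDataset(dataset, filtered, impacts, exclusions)
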