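"""Statistical feature vectors from 250-frame evaluation windows.

Each window yields 7 statistics per channel — min, median, max,
interquartile range, standard deviation, skew, kurtosis — over 18 channels,
for 126 features total.  Conventions (centralized here so alternates stay
switchable):

* std is the sample standard deviation (n-1 denominator);
* skew is the Fisher-Pearson standardized third moment (biased, g1);
* kurtosis is excess kurtosis (normal -> 0, biased, g2);
* IQR is the 75th minus 25th percentile with linear interpolation;
* zero-variance channels yield skew = 0 and kurtosis = 0 by convention.

Feature columns are named ``{location}_{modality}_{axis}_{stat}`` and
ordered lexicographically so the matrix layout is reproducible.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .preprocessing import (
    Exclusion,
    PreprocessedDataset,
    WindowInfeasibleError,
    extract_fall_window,
    extract_nonfall_window,
)
from .synthetic_data import CHANNELS, Dataset

STATS = ("min", "median", "max", "iqr", "std", "skew", "kurtosis")

#: The 126 feature column names in canonical (lexicographic) order.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    sorted(f"{ch}_{stat}" for ch in CHANNELS for stat in STATS)
)
LABEL_COLUMNS = ("cohort", "activity_class", "subtype", "lead_time_ms")

_VAR_FLOOR = 1e-24


class FeatureError(ValueError):
    pass


def channel_statistics(data: np.ndarray) -> dict[str, np.ndarray]:
    """All 7 statistics, vectorized over the channel axis of (n, 18) data."""
    if np.isnan(data).any():
        raise FeatureError("window contains missing values; exclude it upstream")
    mean = data.mean(axis=0)
    dev = data - mean
    m2 = np.mean(dev**2, axis=0)
    m3 = np.mean(dev**3, axis=0)
    m4 = np.mean(dev**4, axis=0)
    safe = np.where(m2 > _VAR_FLOOR, m2, 1.0)
    skew = np.where(m2 > _VAR_FLOOR, m3 / safe**1.5, 0.0)
    kurt = np.where(m2 > _VAR_FLOOR, m4 / safe**2 - 3.0, 0.0)
    q75, q25 = np.percentile(data, [75, 25], axis=0)
    return {
        "min": data.min(axis=0),
        "median": np.median(data, axis=0),
        "max": data.max(axis=0),
        "iqr": q75 - q25,
        "std": data.std(axis=0, ddof=1),
        "skew": skew,
        "kurtosis": kurt,
    }


def extract_features(window) -> pd.Series:
    """126-element named feature vector for one :class:`EventWindow`."""
    stats = channel_statistics(np.asarray(window.data, dtype=np.float64))
    values = {
        f"{ch}_{stat}": stats[stat][ci]
        for ci, ch in enumerate(CHANNELS)
        for stat in STATS
    }
    vec = pd.Series([values[c] for c in FEATURE_COLUMNS], index=list(FEATURE_COLUMNS))
    if not np.all(np.isfinite(vec.to_numpy())):
        raise FeatureError("non-finite feature value")
    return vec


def _event_seed(master_seed: int, event_id: str) -> int:
    """Stable per-event stream so row values do not depend on event order."""
    digest = hashlib.sha256(f"{master_seed}:{event_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def extract_windows(
    pre: PreprocessedDataset | Dataset,
    lead_time_ms: float,
    nonfall_filter: str = "both",
    seed: int = 0,
    fall_subtype: str = "all",
):
    """Yield the surviving :class:`EventWindow` per event plus exclusions.

    Shared window-selection path for the feature matrix and the windows
    manifest.  Returns ``(windows, exclusions)``.
    """
    from .preprocessing import preprocess_dataset  # local to avoid cycle at import

    if nonfall_filter not in ("adl_only", "nearfall_only", "both"):
        raise FeatureError(f"unknown nonfall_filter {nonfall_filter!r}")
    if fall_subtype not in ("all", "lateral", "ap"):
        raise FeatureError(f"unknown fall_subtype {fall_subtype!r}")
    if isinstance(pre, Dataset):
        pre = preprocess_dataset(pre)

    excluded_ids = {e.event_id for e in pre.exclusions}
    exclusions: list[Exclusion] = list(pre.exclusions)
    windows = []
    for ann in sorted(pre.dataset.annotations, key=lambda a: a.event_id):
        if ann.event_id in excluded_ids:
            continue
        if ann.activity_class == "fall":
            if fall_subtype == "lateral" and ann.subtype != "lateral_fall":
                continue
            if fall_subtype == "ap" and ann.subtype != "ap_fall":
                continue
        else:
            if nonfall_filter == "adl_only" and ann.subtype != "adl":
                continue
            if nonfall_filter == "nearfall_only" and ann.subtype != "near_fall":
                continue
        rec = pre.filtered[ann.subject_id]
        try:
            if ann.activity_class == "fall":
                window = extract_fall_window(rec, ann, pre.impacts[ann.event_id], lead_time_ms)
            else:
                window = extract_nonfall_window(
                    rec, ann, np.random.default_rng(_event_seed(seed, ann.event_id))
                )
        except WindowInfeasibleError:
            exclusions.append(Exclusion(ann.event_id, "window_infeasible"))
            continue
        if window.has_missing:
            exclusions.append(Exclusion(ann.event_id, "missing_data"))
            continue
        windows.append(window)
    return windows, exclusions


def build_feature_matrix(
    pre: PreprocessedDataset | Dataset,
    lead_time_ms: float,
    nonfall_filter: str = "both",
    seed: int = 0,
    fall_subtype: str = "all",
) -> pd.DataFrame:
    """One feature row per surviving event at the given lead time.

    Fall windows are anchored ``lead_time_ms`` before the detected impact;
    non-fall windows are drawn (seeded per event) from the latter half of
    their region.  Defective events, events whose windows would leave the
    recording, and windows containing missing samples are excluded and
    logged on ``df.attrs["exclusions"]``.

    ``nonfall_filter``: ``adl_only`` | ``nearfall_only`` | ``both``;
    ``fall_subtype``: ``all`` | ``lateral`` | ``ap``.
    """
    from .preprocessing import preprocess_dataset  # local to avoid cycle at import

    if isinstance(pre, Dataset):
        pre = preprocess_dataset(pre)
    cohort_of = {p.subject_id: p.cohort for p in pre.dataset.profiles}
    subtype_of = {a.event_id: a for a in pre.dataset.annotations}
    win_list, exclusions = extract_windows(pre, lead_time_ms, nonfall_filter, seed, fall_subtype)
    rows: list[list[float]] = []
    meta: list[tuple] = []
    for window in win_list:
        ann = subtype_of[window.event_id]
        stats = channel_statistics(window.data)
        values = {
            f"{ch}_{stat}": stats[stat][ci]
            for ci, ch in enumerate(CHANNELS)
            for stat in STATS
        }
        rows.append([values[c] for c in FEATURE_COLUMNS])
        meta.append(
            (ann.event_id, ann.subject_id, cohort_of[ann.subject_id], ann.activity_class, ann.subtype)
        )

    if not rows:
        raise FeatureError("no events survive the requested filters")
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    meta_df = pd.DataFrame(
        meta, columns=["event_id", "subject_id", "cohort", "activity_class", "subtype"]
    )
    df = pd.concat([meta_df, df], axis=1)
    df["lead_time_ms"] = float(lead_time_ms)
    df.attrs["lead_time_ms"] = float(lead_time_ms)
    df.attrs["nonfall_filter"] = nonfall_filter
    df.attrs["fall_subtype"] = fall_subtype
    df.attrs["seed"] = seed
    df.attrs["exclusions"] = exclusions
    return df
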