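"""Event-triggered analysis windows and the tagged feature matrix.

Each gait event contributes one analysis window per channel: the 300 ms of
signal ending at the event (300 samples at 1 kHz, 150 at 500 Hz; no
resampling).  The delayed variant shifts the window to span 210 ms before
to 90 ms after the event.

EMG channels yield 10 features: mean absolute value (MAV), waveform length
(WL), zero-crossing count (ZC), slope-sign-change count (SSC) and the six
coefficients of an order-6 autoregressive model.  AR coefficients are
estimated with Burg's method (stable on short windows) in the prediction
convention x_t = sum_i a_i x_{t-i} + e_t, excluding the innovation
variance.  Mechanical channels yield 6 features: mean, standard deviation
(n-1 denominator), maximum, minimum, and the literal first and last window
samples.

A full bilateral suite therefore spans 332 feature columns
(14 EMG x 10 + 28 mechanical x 6) and one side spans 166.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.regression.linear_model import burg

from .suite import (
    LEG_SENSORS,
    SENSOR_MODALITY,
    SIDES,
    ChannelTag,
    GaitEvent,
    TrialRecording,
    features_per_channel,
    sensor_channels,
)
from .preprocess import WARMUP_S

logger = logging.getLogger(__name__)

AR_ORDER = 6
EMG_FEATURE_NAMES = ("mav", "wl", "zc", "ssc", "ar1", "ar2", "ar3", "ar4", "ar5", "ar6")
MECH_FEATURE_NAMES = ("mean", "sd", "max", "min", "first", "last")


@dataclass(frozen=True)
class WindowSpec:
    """Analysis-window geometry relative to the triggering event."""

    length_s: float = 0.300
    end_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError("window length must be positive")


STANDARD_WINDOW = WindowSpec()
DELAYED_WINDOW = WindowSpec(length_s=0.300, end_offset_s=0.090)


class WindowError(ValueError):
    """Raised when an analysis window does not fit inside the trial."""


def extract_window(x: np.ndarray, fs: float, event_time_s: float,
                   spec: WindowSpec = STANDARD_WINDOW) -> np.ndarray:
    """Last ceil(length*fs) samples ending at event_time + end_offset."""
    n = int(np.ceil(spec.length_s * fs))
    i_end = int(round((event_time_s + spec.end_offset_s) * fs))
    i_start = i_end - n + 1
    if i_start < 0 or i_end >= len(x):
        raise WindowError(
            f"window [{i_start}, {i_end}] outside signal of length {len(x)}"
        )
    return np.asarray(x[i_start : i_end + 1], dtype=float)


def emg_features(window: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """[MAV, WL, ZC, SSC, a1..a6] for one EMG window.

    ``eps`` is the Hudgins-style deadband applied to the crossing counts;
    the default of zero suits synthetic data with a known noise floor.
    """
    x = np.asarray(window, dtype=float)
    if x.size < AR_ORDER + 2:
        raise ValueError(f"EMG window too short for AR({AR_ORDER}): {x.size} samples")
    mav = float(np.mean(np.abs(x)))
    dx = np.diff(x)
    wl = float(np.sum(np.abs(dx)))
    zc = int(np.sum((x[1:] * x[:-1] < 0) & (np.abs(x[1:]) > eps) & (np.abs(x[:-1]) > eps)))
    mid, prev, nxt = x[1:-1], x[:-1][:-1], x[2:]
    ssc = int(
        np.sum(
            ((mid - prev) * (mid - nxt) > 0)
            & ((np.abs(mid - prev) > eps) | (np.abs(nxt - mid) > eps))
        )
    )
    if np.ptp(x) == 0.0:  # constant window: AR model undefined
        warnings.warn("constant EMG window; AR coefficients set to 0", stacklevel=2)
        ar = np.zeros(AR_ORDER)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ar, _sigma2 = burg(x, order=AR_ORDER, demean=True)
        if not np.all(np.isfinite(ar)):  # e.g. exactly periodic windows
            warnings.warn("degenerate EMG window; AR coefficients set to 0", stacklevel=2)
            ar = np.zeros(AR_ORDER)
    return np.concatenate(([mav, wl, float(zc), float(ssc)], ar))


def mech_features(window: np.ndarray) -> np.ndarray:
    """[mean, sd, max, min, first, last] for one mechanical window."""
    x = np.asarray(window, dtype=float)
    if x.size < 2:
        raise ValueError("mechanical window needs at least 2 samples")
    return np.array(
        [np.mean(x), np.std(x, ddof=1), np.max(x), np.min(x), x[0], x[-1]]
    )


@dataclass
class FeatureDataset:
    """Event-by-feature matrix with per-column sensor tags.

    ``feature_tags`` columns: side, sensor, channel, modality, feature.
    ``event_meta`` columns: time_s, leg, event_type, incoming_mode,
    outgoing_mode (one row per retained event).
    """

    X: np.ndarray
    feature_tags: pd.DataFrame
    event_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.event_meta), len(self.feature_tags)):
            raise ValueError("matrix shape inconsistent with tags/meta")
        ids = list(map(tuple, self.feature_tags.itertuples(index=False)))
        if len(set(ids)) != len(ids):
            raise ValueError("feature column tags must be unique")

    @property
    def n_events(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select_columns(self, mask: np.ndarray) -> "FeatureDataset":
        return FeatureDataset(
            self.X[:, mask],
            self.feature_tags.loc[mask].reset_index(drop=True),
            self.event_meta.copy(),
        )

    @staticmethod
    def concat(datasets: list["FeatureDataset"]) -> "FeatureDataset":
        if not datasets:
            raise ValueError("nothing to concatenate")
        tags0 = datasets[0].feature_tags
        for ds in datasets[1:]:
            if not ds.feature_tags.equals(tags0):
                raise ValueError("datasets have different feature columns")
        return FeatureDataset(
            np.vstack([ds.X for ds in datasets]),
            tags0.copy(),
            pd.concat([ds.event_meta for ds in datasets], ignore_index=True),
        )


def _ordered_tags(trial: TrialRecording, sensors: list[tuple[str, str]]) -> list[ChannelTag]:
    """Processed channel tags of the requested (side, sensor) pairs, in
    canonical (side, sensor, channel) order."""
    tags: list[ChannelTag] = []
    for side, sensor in sensors:
        modality = SENSOR_MODALITY[sensor]
        rate = 1000 if modality == "emg" else 500
        for channel in sensor_channels(sensor, processed=True):
            tag = ChannelTag(side, sensor, channel, modality, rate)
            if tag not in trial.channels:
                raise ValueError(f"trial is missing channel {tag}")
            tags.append(tag)
    return tags


def default_sensor_list(sides=SIDES) -> list[tuple[str, str]]:
    """All (side, sensor) pairs, left block then right, canonical order."""
    return [(side, sensor) for side in sides for sensor in LEG_SENSORS]


def build_dataset(
    trial: TrialRecording,
    events: list[GaitEvent],
    spec: WindowSpec = STANDARD_WINDOW,
    sensors: list[tuple[str, str]] | None = None,
    warmup_s: float = WARMUP_S,
    eps: float = 0.0,
) -> FeatureDataset:
    """One feature row per labeled event over the selected sensors.

    Events whose window would reach before ``warmup_s`` (filter transient)
    or outside the trial are skipped with a logged reason.
    """
    if sensors is not None and len(sensors) == 0:
        raise ValueError("empty sensor subset")
    sensors = sensors if sensors is not None else default_sensor_list(trial.sides())
    tags = _ordered_tags(trial, sensors)

    tag_rows = []
    for tag in tags:
        names = EMG_FEATURE_NAMES if tag.modality == "emg" else MECH_FEATURE_NAMES
        for name in names:
            tag_rows.append((tag.side, tag.sensor, tag.channel, tag.modality, name))
    feature_tags = pd.DataFrame(
        tag_rows, columns=["side", "sensor", "channel", "modality", "feature"]
    )

    rows, meta_rows = [], []
    for e in sorted(events, key=lambda ev: (ev.time_s, ev.leg)):
        earliest = (e.time_s + spec.end_offset_s) - spec.length_s
        if earliest < warmup_s:
            logger.info("skipping event at %.3fs: window inside warm-up", e.time_s)
            continue
        try:
            feats = []
            for tag in tags:
                w = extract_window(trial.channels[tag], tag.rate, e.time_s, spec)
                if tag.modality == "emg":
                    feats.append(emg_features(w, eps=eps))
                else:
                    feats.append(mech_features(w))
        except WindowError as err:
            logger.info("skipping event at %.3fs: %s", e.time_s, err)
            continue
        rows.append(np.concatenate(feats))
        meta_rows.append(
            (e.time_s, e.leg, e.event_type, e.incoming_mode, e.outgoing_mode)
        )

    X = np.array(rows, dtype=float) if rows else np.empty((0, len(feature_tags)))
    event_meta = pd.DataFrame(
        meta_rows,
        columns=["time_s", "leg", "event_type", "incoming_mode", "outgoing_mode"],
    )
    return FeatureDataset(X, feature_tags, event_meta)


# --------------------------------------------------------------------------
# laterality / modality views
# --------------------------------------------------------------------------

_OTHER_SIDE = {"left": "right", "right": "left"}


def modality_sensors(modality: str) -> list[str]:
    """Per-leg sensor names of one modality ('all' for every sensor)."""
    if modality == "all":
        return list(LEG_SENSORS)
    sensors = [s for s in LEG_SENSORS if SENSOR_MODALITY[s] == modality]
    if not sensors:
        raise ValueError(f"unknown modality: {modality!r}")
    return sensors


def relative_view(
    dataset: FeatureDataset,
    ipsi_sensors: list[str] | None = None,
    contra_sensors: list[str] | None = None,
) -> FeatureDataset:
    """Re-express a bilateral dataset in event-relative laterality.

    The ipsilateral side of a row is the side on which its triggering gait
    event was detected.  ``ipsi_sensors`` / ``contra_sensors`` are per-leg
    sensor-name lists (None selects all 11; pass [] to exclude the side).
    Columns are ordered ipsi block then contra block, each in canonical
    sensor order, and tagged side='ipsi'/'contra'.
    """
    ipsi = list(LEG_SENSORS) if ipsi_sensors is None else list(ipsi_sensors)
    contra = list(LEG_SENSORS) if contra_sensors is None else list(contra_sensors)
    if not ipsi and not contra:
        raise ValueError("empty sensor subset")

    tags = dataset.feature_tags
    col_of: dict[tuple, int] = {
        (t.side, t.sensor, t.channel, t.feature): i
        for i, t in enumerate(tags.itertuples(index=False))
    }

    def side_block(side: str, sensors: list[str], rel: str):
        idx, rows = [], []
        for sensor in sensors:
            names = (
                EMG_FEATURE_NAMES
                if SENSOR_MODALITY[sensor] == "emg"
                else MECH_FEATURE_NAMES
            )
            for channel in sensor_channels(sensor, processed=True):
                for name in names:
                    key = (side, sensor, channel, name)
                    if key not in col_of:
                        raise ValueError(f"dataset lacks column for {key}")
                    idx.append(col_of[key])
                    rows.append((rel, sensor, channel, SENSOR_MODALITY[sensor], name))
        return idx, rows

    view_tags = None
    index_by_leg: dict[str, np.ndarray] = {}
    for leg in SIDES:
        other = _OTHER_SIDE[leg]
        idx_i, rows_i = side_block(leg, ipsi, "ipsi")
        idx_c, rows_c = side_block(other, contra, "contra")
        index_by_leg[leg] = np.array(idx_i + idx_c, dtype=int)
        if view_tags is None:
            view_tags = pd.DataFrame(
                rows_i + rows_c,
                columns=["side", "sensor", "channel", "modality", "feature"],
            )

    X = np.empty((dataset.n_events, len(view_tags)))
    legs = dataset.event_meta["leg"].to_numpy()
    for leg in SIDES:
        mask = legs == leg
        if np.any(mask):
            X[mask] = dataset.X[np.ix_(mask, index_by_leg[leg])]
    return FeatureDataset(X, view_tags, dataset.event_meta.copy())


def laterality_view(
    dataset: FeatureDataset, laterality: str, modality: str = "all"
) -> FeatureDataset:
    """Standard ipsilateral (I) / contralateral (C) / bilateral (B) slices
    of one modality group, as used in the classifier comparison grid."""
    sensors = modality_sensors(modality)
    if laterality == "I":
        return relative_view(dataset, ipsi_sensors=sensors, contra_sensors=[])
    if laterality == "C":
        return relative_view(dataset, ipsi_sensors=[], contra_sensors=sensors)
    if laterality == "B":
        return relative_view(dataset, ipsi_sensors=sensors, contra_sensors=sensors)
    raise ValueError(f"laterality must be I, C or B, got {laterality!r}")


def prosthesis_channel_count() -> tuple[int, int]:
    """(channels, features) of the powered-prosthesis sensor variant.

    Seventeen mechanical channels embedded in the device, two 6-axis IMUs
    on the sound side, and two computed inclination angles give 31
    channels; with 6 summary features per mechanical channel the feature
    dimensionality is 186.
    """
    channels = 17 + 2 * 6 + 2
    return channels, channels * features_per_channel("imu")
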