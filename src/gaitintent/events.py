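"""Gait-event detection from shank angular velocity (dual-minima method).

Mid-swing is the dominant positive peak of the sagittal-plane shank
gyroscope within each stride.  Toe off is the signed minimum of the
low-pass-filtered signal in a bounded window before the mid-swing peak;
heel contact is the minimum in the window after it.  Segmentation is an
offline step, so the 1st-order 6 Hz Butterworth pre-detection filter is
applied zero-phase (forward-backward) to keep detected times unbiased;
the feature-path filters in :mod:`gaitintent.preprocess` remain causal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .suite import (
    SIDES,
    GaitEvent,
    TrialRecording,
    shank_gyro_tag,
)


@dataclass(frozen=True)
class DetectorConfig:
    """Dual-minima detector parameters.

    Defaults (50 deg/s peak height, 0.5 s stride separation, 0.4 s search
    window) suit self-selected walking speeds around one stride per second
    and are deliberately not tuned per subject.
    """

    lp_order: int = 1
    lp_hz: float = 6.0
    min_peak_height: float = 50.0
    min_stride_s: float = 0.5
    search_window_s: float = 0.4

    def __post_init__(self) -> None:
        for name in ("lp_order", "lp_hz", "min_peak_height", "min_stride_s", "search_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EventTriple:
    """One detected stride: toe off < mid-swing < heel contact (seconds)."""

    mid_swing_s: float
    to_s: float
    hc_s: float


def detect_events(
    gyro_sagittal: np.ndarray,
    fs: float = 500.0,
    cfg: DetectorConfig = DetectorConfig(),
) -> list[EventTriple]:
    """Detect (mid-swing, TO, HC) triples from one leg's shank gyro.

    Mid-swing peaks lacking a full search window on either side are
    dropped; a signal with no qualifying peaks yields an empty list.
    """
    x = np.asarray(gyro_sagittal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("gyro signal contains non-finite samples")
    if x.size < 2:
        return []

    sos = sps.butter(cfg.lp_order, cfg.lp_hz, btype="lowpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)

    distance = max(int(round(cfg.min_stride_s * fs)), 1)
    peaks, _ = sps.find_peaks(y, height=cfg.min_peak_height, distance=distance)

    w = int(round(cfg.search_window_s * fs))
    triples: list[EventTriple] = []
    for p in peaks:
        if p - w < 0 or p + w >= len(y):
            continue  # boundary mid-swing without a full search window
        i_to = p - w + int(np.argmin(y[p - w : p]))
        i_hc = p + 1 + int(np.argmin(y[p + 1 : p + w + 1]))
        triples.append(EventTriple(p / fs, i_to / fs, i_hc / fs))

    # enforce non-overlapping consecutive triples
    out: list[EventTriple] = []
    for tr in sorted(triples, key=lambda t: t.mid_swing_s):
        if out and tr.to_s <= out[-1].hc_s:
            continue
        out.append(tr)
    return out


def triples_to_events(triples: list[EventTriple], leg: str) -> list[GaitEvent]:
    """Flatten detected triples into a chronological TO/HC event list."""
    events: list[GaitEvent] = []
    for tr in triples:
        events.append(GaitEvent(tr.to_s, leg, "TO"))
        events.append(GaitEvent(tr.hc_s, leg, "HC"))
    return sorted(events, key=lambda e: e.time_s)


def detect_trial_events(
    trial: TrialRecording,
    cfg: DetectorConfig = DetectorConfig(),
) -> list[GaitEvent]:
    """Run the detector on each leg's shank sagittal gyro channel."""
    events: list[GaitEvent] = []
    for leg in SIDES:
        tag = shank_gyro_tag(leg)
        if tag not in trial.channels:
            continue
        triples = detect_events(trial.channels[tag], fs=tag.rate, cfg=cfg)
        events.extend(triples_to_events(triples, leg))
    return sorted(events, key=lambda e: e.time_s)


def label_events(
    events: list[GaitEvent],
    mode_timeline: dict[str, list[tuple[float, str]]],
    tol_s: float = 0.05,
    drop_straddling: bool = True,
) -> list[GaitEvent]:
    """Fill incoming/outgoing modes from per-leg label timelines.

    The outgoing mode of an event is the timeline label of the step the
    event begins — evaluated ``tol_s`` after the event time so that
    detector timing jitter around a label switch cannot push the
    transitional label onto the neighboring step; the incoming mode is the
    outgoing mode of the leg's previous event.  The first event at or
    after a label switch is therefore the transitional one.

    Because each leg enters a new activity on its own step, there is a
    short span per transition during which the two legs' labels disagree:
    one leg's step has begun in the new mode while the other leg is still
    completing its last old-mode step.  Decisions whose step begins inside
    that span (other than the transitional decision itself) are ill-defined
    under per-leg labeling — the body is mid-transition — and with
    ``drop_straddling`` (default) they are excluded, in the spirit of
    excluding ambiguous strides from offline evaluation.
    """
    legs = sorted({e.leg for e in events})
    switch_arrays = {}
    for leg in legs:
        if leg not in mode_timeline:
            raise ValueError(f"no label timeline for leg {leg!r}")
        switch_arrays[leg] = np.array([t for t, _ in mode_timeline[leg]])

    def timeline_index(leg: str, t: float) -> int:
        return max(int(np.searchsorted(switch_arrays[leg], t + tol_s, side="right")) - 1, 0)

    labeled: list[GaitEvent] = []
    for leg in legs:
        labels = [m for _, m in mode_timeline[leg]]
        other_legs = [l for l in mode_timeline if l != leg]
        prev_out: str | None = None
        for e in sorted((e for e in events if e.leg == leg), key=lambda e: e.time_s):
            if e.time_s + tol_s < switch_arrays[leg][0]:
                raise ValueError(f"event at {e.time_s:.3f}s precedes the labeled span")
            idx = timeline_index(leg, e.time_s)
            out = labels[idx]
            inc = prev_out if prev_out is not None else out
            prev_out = out  # the step still advances the leg's own history
            if drop_straddling and any(
                timeline_index(other, e.time_s) != idx for other in other_legs
            ):
                # keep the leg's own transitional decision, drop the rest of
                # the disagreement span
                own_switch = switch_arrays[leg][idx]
                if not (inc != out and abs(e.time_s - own_switch) <= 2 * tol_s):
                    continue
            labeled.append(GaitEvent(e.time_s, leg, e.event_type, inc, out))
    return sorted(labeled, key=lambda e: e.time_s)


def match_events(
    detected_s: np.ndarray,
    truth_s: np.ndarray,
    window_s: float = 0.1,
) -> tuple[int, np.ndarray]:
    """Greedy one-to-one matching of detected to ground-truth event times.

    Returns the number of matched truth events and the signed timing errors
    (detected - truth, seconds) of the matches.
    """
    detected = np.sort(np.asarray(detected_s, dtype=float))
    truth = np.sort(np.asarray(truth_s, dtype=float))
    used = np.zeros(len(detected), dtype=bool)
    errors = []
    for t in truth:
        if len(detected) == 0:
            break
        i = int(np.argmin(np.where(used, np.inf, np.abs(detected - t))))
        if not used[i] and abs(detected[i] - t) <= window_s:
            used[i] = True
            errors.append(detected[i] - t)
    return len(errors), np.asarray(errors)
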