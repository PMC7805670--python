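"""Sensor-suite layout and shared domain types.

The bilateral wearable suite carries, per leg: seven surface-EMG channels
(tibialis anterior, medial gastrocnemius, soleus, vastus lateralis, rectus
femoris, biceps femoris, semitendinosus) sampled at 1 kHz; knee and ankle
electrogoniometers (sagittal angle, deg) at 500 Hz; and two 6-axis IMUs
(thigh and shank; accelerometer in g, gyroscope in deg/s) at 500 Hz.

That makes 11 sensors and 21 raw channels per leg (22 sensors / 42 raw
channels bilaterally).  Preprocessing appends a numerically derived velocity
channel per goniometer, bringing the analysis channel count to 23 per leg
(46 bilaterally: 14 EMG, 8 goniometer, 24 IMU).

Locomotor modes are level walking (LW), ramp ascent/descent (RA/RD) and
stair ascent/descent (SA/SD).  From any non-level mode the only legal
outgoing modes are staying in that mode or returning to level walking; from
level walking every mode is reachable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

MODES: tuple[str, ...] = ("LW", "RA", "RD", "SA", "SD")
MODE_INDEX: dict[str, int] = {m: i for i, m in enumerate(MODES)}

#: incoming mode -> legal outgoing modes (mode-specific classifier scheme)
ALLOWED_TRANSITIONS: dict[str, tuple[str, ...]] = {
    "LW": ("LW", "RA", "RD", "SA", "SD"),
    "RA": ("RA", "LW"),
    "RD": ("RD", "LW"),
    "SA": ("SA", "LW"),
    "SD": ("SD", "LW"),
}

SIDES: tuple[str, str] = ("left", "right")
EVENT_TYPES: tuple[str, str] = ("HC", "TO")

EMG_RATE = 1000
MECH_RATE = 500

EMG_SENSORS: tuple[str, ...] = (
    "emg_ta", "emg_mg", "emg_sol", "emg_vl", "emg_rf", "emg_bf", "emg_st",
)
GONIO_SENSORS: tuple[str, ...] = ("gonio_knee", "gonio_ankle")
IMU_SENSORS: tuple[str, ...] = ("imu_thigh", "imu_shank")
IMU_AXES: tuple[str, ...] = (
    "accel_x", "accel_y", "accel_z", "gyro_x", "gyro_y", "gyro_z",
)

#: canonical per-leg sensor order (used for deterministic tie-breaking)
LEG_SENSORS: tuple[str, ...] = EMG_SENSORS + GONIO_SENSORS + IMU_SENSORS

SENSOR_MODALITY: dict[str, str] = {
    **{s: "emg" for s in EMG_SENSORS},
    **{s: "gonio" for s in GONIO_SENSORS},
    **{s: "imu" for s in IMU_SENSORS},
}

MODALITIES: tuple[str, ...] = ("emg", "gonio", "imu")


def allowed_transitions(mode: str) -> tuple[str, ...]:
    """Legal outgoing modes for a given incoming mode."""
    try:
        return ALLOWED_TRANSITIONS[mode]
    except KeyError:
        raise ValueError(f"unknown locomotor mode: {mode!r}") from None


@dataclass(frozen=True, order=True)
class ChannelTag:
    """Identity of one recorded (or derived) channel."""

    side: str
    sensor: str
    channel: str
    modality: str
    rate: int

    def __str__(self) -> str:  # compact id used in file columns
        return f"{self.side}.{self.sensor}.{self.channel}"


def sensor_channels(sensor: str, processed: bool = False) -> tuple[str, ...]:
    """Channel names carried by one sensor.

    With ``processed=True`` the goniometer's derived velocity channel is
    included (it exists only after preprocessing).
    """
    modality = SENSOR_MODALITY[sensor]
    if modality == "emg":
        return ("emg",)
    if modality == "gonio":
        return ("angle", "velocity") if processed else ("angle",)
    return IMU_AXES


def leg_channels(side: str, processed: bool = False) -> list[ChannelTag]:
    """Canonically ordered channel tags for one leg."""
    if side not in SIDES:
        raise ValueError(f"unknown side: {side!r}")
    tags = []
    for sensor in LEG_SENSORS:
        modality = SENSOR_MODALITY[sensor]
        rate = EMG_RATE if modality == "emg" else MECH_RATE
        for channel in sensor_channels(sensor, processed=processed):
            tags.append(ChannelTag(side, sensor, channel, modality, rate))
    return tags


def suite_channels(sides: Iterable[str] = SIDES, processed: bool = False) -> list[ChannelTag]:
    return [t for side in sides for t in leg_channels(side, processed=processed)]


def shank_gyro_tag(side: str) -> ChannelTag:
    """Sagittal-plane shank angular velocity (gyro Y), the segmentation input."""
    return ChannelTag(side, "imu_shank", "gyro_y", "imu", MECH_RATE)


def features_per_channel(modality: str) -> int:
    """10 time-domain+AR features per EMG channel, 6 summary features otherwise."""
    if modality == "emg":
        return 10
    if modality in ("gonio", "imu"):
        return 6
    raise ValueError(f"unknown modality: {modality!r}")


@dataclass
class GaitEvent:
    """A heel-contact or toe-off decision instant on one leg."""

    time_s: float
    leg: str
    event_type: str  # "HC" or "TO"
    incoming_mode: str | None = None
    outgoing_mode: str | None = None

    @property
    def transitional(self) -> bool:
        return self.incoming_mode != self.outgoing_mode


@dataclass
class GroundTruth:
    """Generator-exact events and per-leg mode timelines.

    ``mode_timeline[leg]`` is a piecewise-constant label timeline given as
    ``[(start_time_s, mode), ...]`` sorted by time; the label at time t is the
    mode of the last breakpoint with start_time <= t.
    """

    events: list[GaitEvent] = field(default_factory=list)
    mode_timeline: dict[str, list[tuple[float, str]]] = field(default_factory=dict)

    def leg_events(self, leg: str) -> list[GaitEvent]:
        return sorted((e for e in self.events if e.leg == leg), key=lambda e: e.time_s)

    def step_labels(self, leg: str) -> list[tuple[float, str]]:
        """Mode of the step beginning at each of the leg's events."""
        return [(e.time_s, e.outgoing_mode) for e in self.leg_events(leg)]


@dataclass
class TrialRecording:
    """Multi-rate labeled signal container."""

    channels: dict[ChannelTag, np.ndarray]
    ground_truth: GroundTruth | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        durations = {round(len(x) / tag.rate, 6) for tag, x in self.channels.items()}
        return max(durations)

    def sides(self) -> tuple[str, ...]:
        return tuple(sorted({tag.side for tag in self.channels}))

    def get(self, tag: ChannelTag) -> np.ndarray:
        return self.channels[tag]
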