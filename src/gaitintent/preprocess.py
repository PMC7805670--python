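"""Filter stack and derived joint velocities.

EMG (1 kHz): 6th-order Butterworth high-pass at 20 Hz (motion-artifact
rejection) followed by three 6th-order Butterworth band-stops, 6 Hz wide,
centered at 60/180/300 Hz (ambient interference).  Goniometer and IMU
(500 Hz): 6th-order Butterworth low-pass at 10 and 25 Hz respectively.
Knee/ankle joint velocities are the centered-difference derivative of the
low-pass-filtered joint angles and are appended as goniometer channels.

All analysis-path filtering is causal (forward-only), emulating a real-time
intent-recognition pipeline in which future samples are unavailable.  Every
filter is realized as second-order sections for numerical stability.  The
band-stop "6 Hz width" is interpreted as stopband edges at +/-3 Hz around
the center frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .suite import ChannelTag, GroundTruth, TrialRecording

#: first part of every trial excluded from event windows (filter warm-up)
WARMUP_S = 0.5


@dataclass(frozen=True)
class FilterSpec:
    """A single Butterworth filter stage."""

    kind: str  # highpass | lowpass | bandstop
    order: int
    corner_hz: tuple[float, ...]
    family: str = "butterworth"

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass", "bandstop"):
            raise ValueError(f"unknown filter kind: {self.kind!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        for c in self.corner_hz:
            if not 0.0 < c < fs / 2:
                raise ValueError(f"corner {c} Hz outside (0, Nyquist) at fs={fs}")
        if self.kind == "bandstop":
            # scipy's N is the prototype order: N=order/2 pole-pairs per side
            n = self.order // 2
            return signal.butter(n, self.corner_hz, btype="bandstop", fs=fs, output="sos")
        return signal.butter(self.order, self.corner_hz[0], btype=self.kind, fs=fs, output="sos")


EMG_FILTERS: tuple[FilterSpec, ...] = (
    FilterSpec("highpass", 6, (20.0,)),
    FilterSpec("bandstop", 6, (57.0, 63.0)),
    FilterSpec("bandstop", 6, (177.0, 183.0)),
    FilterSpec("bandstop", 6, (297.0, 303.0)),
)
GONIO_FILTER = FilterSpec("lowpass", 6, (10.0,))
IMU_FILTER = FilterSpec("lowpass", 6, (25.0,))


def cascade_response(specs, freqs_hz, fs: float) -> np.ndarray:
    """|H(f)| of a filter cascade, for validating attenuation levels."""
    h = np.ones(len(freqs_hz), dtype=complex)
    for spec in specs:
        _, resp = signal.sosfreqz(spec.sos(fs), worN=np.asarray(freqs_hz), fs=fs)
        h *= resp
    return np.abs(h)


def filter_emg(x: np.ndarray, fs: float = 1000.0) -> np.ndarray:
    """Causal EMG conditioning cascade (high-pass + triple notch)."""
    if fs != 1000.0:
        raise ValueError(f"EMG channels are sampled at 1 kHz, got {fs}")
    y = np.asarray(x, dtype=float)
    for spec in EMG_FILTERS:
        y = signal.sosfilt(spec.sos(fs), y)
    return y


def filter_mech(x: np.ndarray, modality: str, fs: float = 500.0) -> np.ndarray:
    """Causal low-pass for mechanical channels (10 Hz gonio, 25 Hz IMU)."""
    if modality == "gonio":
        spec = GONIO_FILTER
    elif modality == "imu":
        spec = IMU_FILTER
    else:
        raise ValueError(f"unknown mechanical modality: {modality!r}")
    return signal.sosfilt(spec.sos(fs), np.asarray(x, dtype=float))


def joint_velocity(position: np.ndarray, fs: float = 500.0) -> np.ndarray:
    """Centered-difference derivative (deg/s); one-sided at the endpoints."""
    p = np.asarray(position, dtype=float)
    if p.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    v = np.empty_like(p)
    v[1:-1] = (p[2:] - p[:-2]) * (fs / 2.0)
    v[0] = (p[1] - p[0]) * fs
    v[-1] = (p[-1] - p[-2]) * fs
    return v


@dataclass
class ProcessedTrial(TrialRecording):
    """TrialRecording after filtering, with derived velocity channels and a
    per-channel record of the filters applied."""

    provenance: dict[ChannelTag, tuple[FilterSpec, ...]] = field(default_factory=dict)


def preprocess_trial(trial: TrialRecording) -> ProcessedTrial:
    """Filter every channel by modality and append joint velocities.

    Works on bilateral or unilateral trials; a bilateral full-suite trial
    yields 46 channels (14 EMG, 8 goniometer, 24 IMU), a unilateral one 23.
    """
    channels: dict[ChannelTag, np.ndarray] = {}
    provenance: dict[ChannelTag, tuple[FilterSpec, ...]] = {}
    for tag, x in trial.channels.items():
        if tag.modality == "emg":
            channels[tag] = filter_emg(x, fs=tag.rate)
            provenance[tag] = EMG_FILTERS
        elif tag.modality in ("gonio", "imu"):
            channels[tag] = filter_mech(x, tag.modality, fs=tag.rate)
            provenance[tag] = (GONIO_FILTER if tag.modality == "gonio" else IMU_FILTER,)
        else:
            raise ValueError(f"channel {tag} has unknown modality {tag.modality!r}")

    # derived joint velocities from the filtered angles
    for tag in list(channels):
        if tag.modality == "gonio" and tag.channel == "angle":
            vtag = ChannelTag(tag.side, tag.sensor, "velocity", "gonio", tag.rate)
            channels[vtag] = joint_velocity(channels[tag], fs=tag.rate)
            provenance[vtag] = provenance[tag]

    return ProcessedTrial(
        channels=channels,
        ground_truth=trial.ground_truth,
        seed=trial.seed,
        meta=dict(trial.meta),
        provenance=provenance,
    )
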