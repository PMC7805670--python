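"""Synthetic bilateral gait-signal generator.

Generates multi-rate neuromechanical recordings (EMG, goniometer, IMU) for
circuits of level walking, ramps and stairs, with exact ground-truth gait
events and per-leg mode labels.  The generator emulates the statistical
structure the downstream analysis assumes rather than musculoskeletal
physiology:

* each channel has a smooth, periodic gait-cycle template expressed as a
  low-order harmonic series of gait phase; locomotor modes share a base
  template and differ by mode-specific harmonic perturbations whose size is
  controlled by a single separation scale ``delta``;
* the sagittal shank gyroscope template has the mid-swing positive peak
  flanked by toe-off and heel-contact minima that the dual-minima
  segmentation method relies on (forward swing rotation positive);
* EMG channels are band-limited broadband carriers (20-450 Hz, matching the
  hardware band-pass of typical surface-EMG front ends) amplitude-modulated
  by a non-negative phase/mode envelope;
* the two legs walk in antiphase (half a stride apart); at every mode
  transition one leg leads: its signals adopt the new mode's template
  ``transition_lead`` strides before the trailing leg's, and both legs blend
  smoothly toward the new template over an anticipation window before their
  own first new-mode step, so the upcoming mode is in principle readable
  from either leg but is carried much more strongly by the leading
  (contralateral, from the trailing leg's viewpoint) side.

Stochastic realism knobs: stride-period jitter (``cadence_sd``), slow
multiplicative amplitude drift per channel (``drift_sd``, emulating wearable
sensor drift), per-transition randomization of which leg leads, of the
within-stride instant the terrain change falls on, and of the strength of
the anticipatory cue.  Additive white measurement noise is scaled per
channel by ``noise_sd`` times the channel's template standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .suite import (
    ALLOWED_TRANSITIONS,
    EMG_RATE,
    MECH_RATE,
    MODES,
    SENSOR_MODALITY,
    SIDES,
    ChannelTag,
    GaitEvent,
    GroundTruth,
    TrialRecording,
    allowed_transitions,
    leg_channels,
)

N_HARMONICS = 6
_PHASE_GRID = np.linspace(0.0, 1.0, 1024, endpoint=False)


# --------------------------------------------------------------------------
# templates
# --------------------------------------------------------------------------

@dataclass
class ChannelTemplate:
    """Periodic trajectory of one channel as a function of gait phase."""

    mean: float
    cos: np.ndarray  # harmonic cosine coefficients, k = 1..K
    sin: np.ndarray
    floor: float | None = None  # lower clip (EMG envelopes must stay >= 0)

    def __call__(self, phase: np.ndarray) -> np.ndarray:
        phase = np.asarray(phase, dtype=float)
        k = np.arange(1, len(self.cos) + 1)
        ang = 2.0 * np.pi * np.multiply.outer(phase, k)
        out = self.mean + np.cos(ang) @ self.cos + np.sin(ang) @ self.sin
        if self.floor is not None:
            out = np.maximum(out, self.floor)
        return out


@dataclass
class GaitCycleTemplate:
    """All channel templates of one locomotor mode (side-agnostic)."""

    mode: str
    channels: dict[tuple[str, str], ChannelTemplate]  # (sensor, channel) ->
    cadence_mean: float = 1.0  # strides / s
    cadence_sd: float = 0.05  # fractional stride-period jitter


# per-(sensor-kind, channel) base scales: (mean, harmonic amp, mode pert sd, floor)
def _channel_spec(sensor: str, channel: str) -> tuple[float, float, float, float | None]:
    modality = SENSOR_MODALITY[sensor]
    if modality == "emg":
        return 1.0, 0.45, 0.30, 0.0
    if sensor == "gonio_knee":
        return 30.0, 22.0, 5.0, None
    if sensor == "gonio_ankle":
        return 0.0, 12.0, 3.0, None
    # IMU
    if channel.startswith("accel"):
        mean = 1.0 if channel == "accel_z" else 0.0
        return mean, 0.5, 0.15, None
    if sensor == "imu_shank" and channel == "gyro_y":
        # base handled specially; perturbation kept small so the dual-minima
        # morphology (and event timing) survives mode separation
        return 0.0, 0.0, 10.0, None
    if channel == "gyro_y":
        return 0.0, 150.0, 25.0, None
    return 0.0, 60.0, 20.0, None


def _shank_gyro_waveform(phase: np.ndarray) -> np.ndarray:
    """Designed sagittal shank angular velocity over one stride (deg/s).

    Phase 0 is heel contact.  Toe off near phase 0.6 and the next heel
    contact near phase 1.0 are deep minima; mid-swing (phase 0.8) is the
    single dominant positive peak; stance carries only small oscillation.
    """

    def bump(center: float, width: float) -> np.ndarray:
        out = np.zeros_like(phase, dtype=float)
        for off in (-1.0, 0.0, 1.0):  # periodic extension
            out += np.exp(-0.5 * ((phase - center - off) / width) ** 2)
        return out

    return (
        -150.0 * bump(0.60, 0.06)
        + 300.0 * bump(0.80, 0.06)
        - 200.0 * bump(1.00, 0.07)
        + 35.0 * bump(0.30, 0.12)
    )


def _project_harmonics(values: np.ndarray, n_harmonics: int = N_HARMONICS):
    """Least-squares harmonic fit on a regular phase grid (via FFT)."""
    spec = np.fft.rfft(values) / len(values)
    mean = spec[0].real
    cos = 2.0 * spec[1 : n_harmonics + 1].real
    sin = -2.0 * spec[1 : n_harmonics + 1].imag
    return mean, cos, sin


_SHANK_GYRO_BASE = _project_harmonics(_shank_gyro_waveform(_PHASE_GRID))


def reference_event_phases() -> tuple[float, float]:
    """(toe-off, heel-contact) phases of the harmonic-truncated base shank
    gyro template, located numerically so ground-truth events coincide with
    the waveform minima the detector searches for."""
    mean, cos, sin = _SHANK_GYRO_BASE
    tmpl = ChannelTemplate(mean, cos, sin)
    grid = np.linspace(0.35, 0.75, 2000)
    phi_to = float(grid[np.argmin(tmpl(grid))])
    grid = np.linspace(0.8, 1.2, 2000)
    phi_hc = float(grid[np.argmin(tmpl(grid))])
    return phi_to, phi_hc


def _base_channel_keys() -> list[tuple[str, str]]:
    # side-agnostic raw channel keys in canonical order
    return [(t.sensor, t.channel) for t in leg_channels("left", processed=False)]


def make_default_templates(
    separation: float = 1.0,
    seed: int = 0,
    cadence_mean: float = 1.0,
    cadence_sd: float = 0.05,
) -> dict[str, GaitCycleTemplate]:
    """Build the five mode templates at a given separation scale.

    Base harmonic coefficients are drawn once from ``seed``; each mode adds
    ``separation`` times a mode-specific perturbation drawn from the same
    stream.  At ``separation=0`` the five templates are identical; the mean
    pairwise template distance grows linearly with ``separation``.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    keys = _base_channel_keys()

    base: dict[tuple[str, str], tuple[float, np.ndarray, np.ndarray]] = {}
    decay = 1.0 / np.arange(1, N_HARMONICS + 1)
    for key in keys:
        sensor, channel = key
        mean, amp, _, _ = _channel_spec(sensor, channel)
        if sensor == "imu_shank" and channel == "gyro_y":
            base[key] = _SHANK_GYRO_BASE
        else:
            cos = amp * decay * rng.standard_normal(N_HARMONICS)
            sin = amp * decay * rng.standard_normal(N_HARMONICS)
            base[key] = (mean, cos, sin)

    templates: dict[str, GaitCycleTemplate] = {}
    for mode in MODES:
        channels = {}
        for key in keys:
            sensor, channel = key
            _, _, pert_sd, floor = _channel_spec(sensor, channel)
            mean, cos, sin = base[key]
            dcos = pert_sd * decay * rng.standard_normal(N_HARMONICS)
            dsin = pert_sd * decay * rng.standard_normal(N_HARMONICS)
            channels[key] = ChannelTemplate(
                mean=mean,
                cos=cos + separation * dcos,
                sin=sin + separation * dsin,
                floor=floor,
            )
        templates[mode] = GaitCycleTemplate(
            mode=mode, channels=channels,
            cadence_mean=cadence_mean, cadence_sd=cadence_sd,
        )
    return templates


def template_distance(a: GaitCycleTemplate, b: GaitCycleTemplate) -> float:
    """RMS distance over phase, averaged over channels."""
    dists = []
    for key, ta in a.channels.items():
        tb = b.channels[key]
        dists.append(float(np.sqrt(np.mean((ta(_PHASE_GRID) - tb(_PHASE_GRID)) ** 2))))
    return float(np.mean(dists))


def mean_pairwise_distance(templates: dict[str, GaitCycleTemplate]) -> float:
    modes = list(templates)
    dists = [
        template_distance(templates[m1], templates[m2])
        for i, m1 in enumerate(modes)
        for m2 in modes[i + 1 :]
    ]
    return float(np.mean(dists))


# --------------------------------------------------------------------------
# circuits
# --------------------------------------------------------------------------

@dataclass
class CircuitSpec:
    """Ordered activity segments of one walking circuit.

    ``transition_lead`` is the fraction of a stride by which the leading
    leg's template switches mode before the trailing leg's at each
    transition; it encodes the distinct biomechanical roles of leading and
    trailing legs when the terrain changes.
    """

    segments: list[tuple[str, int]]
    transition_lead: float = 0.5

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("circuit must contain at least one segment")
        for mode, n in self.segments:
            if mode not in MODES:
                raise ValueError(f"unknown mode in circuit: {mode!r}")
            if n < 1:
                raise ValueError("each segment needs n_strides >= 1")
        if self.segments[0][0] != "LW" or self.segments[-1][0] != "LW":
            raise ValueError("circuits must start and end in level walking")
        for (m1, _), (m2, _) in zip(self.segments, self.segments[1:]):
            if m2 != m1 and m2 not in allowed_transitions(m1):
                raise ValueError(f"illegal circuit transition {m1}->{m2}")
        if not 0.0 <= self.transition_lead <= 1.0:
            raise ValueError("transition_lead must be in [0, 1]")

    @property
    def total_strides(self) -> int:
        return sum(n for _, n in self.segments)

    @property
    def modes(self) -> list[str]:
        return [m for m, _ in self.segments]


def make_standard_circuits(n_strides_per_segment: int = 4, transition_lead: float = 0.5) -> list[CircuitSpec]:
    """The two canonical circuits covering all five modes and all eight
    to/from-level transition types: LW-SA-LW-RD-LW and LW-RA-LW-SD-LW."""
    n = int(n_strides_per_segment)
    if n < 2:
        raise ValueError("n_strides_per_segment must be >= 2")
    return [
        CircuitSpec([("LW", n), ("SA", n), ("LW", n), ("RD", n), ("LW", n)], transition_lead),
        CircuitSpec([("LW", n), ("RA", n), ("LW", n), ("SD", n), ("LW", n)], transition_lead),
    ]


# --------------------------------------------------------------------------
# trial simulation
# --------------------------------------------------------------------------

_LEG_OFFSET = {"right": 0.0, "left": 0.5}  # legs walk in antiphase

#: anticipatory-blend strength at the leg's own transitional event.  The
#: leading leg is about to step onto the new terrain, so its own signals
#: carry a strong cue; the trailing leg keeps walking the old terrain and
#: its own anticipatory cue is weak — its upcoming transition is mainly
#: readable from the contralateral (leading) leg, which committed half a
#: stride earlier.
WMAX_LEAD_RANGE: tuple[float, float] = (0.85, 1.00)
WMAX_TRAIL_RANGE: tuple[float, float] = (0.25, 0.40)
#: strength of the trailing leg's postural-adjustment bump while the
#: leading leg steps onto the new terrain; it decays again before the
#: trailing leg's own transition, so it is informative contralaterally
#: without strengthening the trailing leg's own pre-event window
PRECUE_RANGE: tuple[float, float] = (0.70, 0.90)


@dataclass
class _Transition:
    boundary_clock: float
    old_mode: str
    new_mode: str
    leading: str  # leg name
    # per-leg resolved quantities (filled during simulation)
    event_time: dict[str, float] = field(default_factory=dict)
    w_max_lead: float = 0.7
    w_max_trail: float = 0.3
    precue: float = 0.3


def _band_limited_carrier(rng: np.random.Generator, n: int, fs: int,
                          band: tuple[float, float] = (20.0, 450.0)) -> np.ndarray:
    """Unit-variance broadband EMG carrier (band-pass filtered white noise)."""
    hi = min(band[1], 0.49 * fs)
    sos = signal.butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = float(np.std(x))
    return x / sd if sd > 0 else x


N_DRIFT_LATENTS = 3


def _drift_latents(rng: np.random.Generator, duration: float,
                   grids: list[np.ndarray]) -> list[np.ndarray]:
    """Shared slow drift processes (unit sd, ~1 Hz knots) sampled on each
    time grid.  Amplitude drift in wearable recordings (speed changes,
    electrode impedance, temperature) is low-rank: a few latent processes
    modulate many channels coherently, so each channel's gain is a random
    loading onto these latents rather than an independent walk."""
    knots = np.arange(-1.0, duration + 2.0, 1.0)
    values = rng.standard_normal((N_DRIFT_LATENTS, len(knots)))
    return [
        np.stack([np.interp(t, knots, values[j]) for j in range(N_DRIFT_LATENTS)])
        for t in grids
    ]


def simulate_trial(
    circuit: CircuitSpec,
    templates: dict[str, GaitCycleTemplate],
    noise_sd: float = 0.25,
    seed: int = 0,
    anticipation: float = 0.2,
    drift_sd: float = 0.10,
) -> TrialRecording:
    """Simulate one bilateral trial of a circuit.

    Parameters
    ----------
    circuit : CircuitSpec
        Activity segments and the leading-leg transition lead (strides).
    templates : dict
        Mode templates from :func:`make_default_templates`.
    noise_sd : float
        Additive white measurement noise, as a fraction of each channel's
        template standard deviation over the gait cycle.
    seed : int
        Seeds every random draw; identical arguments reproduce the trial
        bitwise.
    anticipation : float
        Fraction of a stride over which a leg's signals ramp from the old
        to the new mode template before its own first new-mode step.
    drift_sd : float
        Standard deviation of the slow multiplicative amplitude drift.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for mode in circuit.modes:
        if mode not in templates:
            raise ValueError(f"no template for mode {mode!r}")

    rng = np.random.default_rng(seed)
    rng_timing, rng_trans, rng_noise = rng.spawn(3)

    cadence = templates[circuit.modes[0]].cadence_mean
    cadence_sd = templates[circuit.modes[0]].cadence_sd
    stride_nominal = 1.0 / cadence

    total = circuit.total_strides
    # stride-clock -> time warp shared by both legs (clock unit = 1 stride);
    # the knot range extends past the enumerated event clocks on both sides
    clock_knots = np.arange(-3.0, total + 4.0)
    durations = stride_nominal * np.clip(
        1.0 + cadence_sd * rng_timing.standard_normal(len(clock_knots) - 1), 0.5, 1.5
    )
    t_knots = np.concatenate([[0.0], np.cumsum(durations)])
    t_knots -= np.interp(0.0, clock_knots, t_knots)  # anchor t(clock=0) = 0

    def clock_to_time(c):
        return np.interp(c, clock_knots, t_knots)

    def time_to_clock(t):
        return np.interp(t, t_knots, clock_knots)

    duration = float(clock_to_time(total))

    phi_to, phi_hc = reference_event_phases()
    hc_off = phi_hc - 1.0  # HC minimum sits just before/after the stride boundary

    # per-leg raw event tables: (clock, time, type), chronological
    leg_event_clocks: dict[str, list[tuple[float, str]]] = {}
    for leg in SIDES:
        off = _LEG_OFFSET[leg]
        evts: list[tuple[float, str]] = []
        for k in range(-2, total + 2):
            evts.append((k + hc_off - off + 1.0, "HC"))  # HC ending stride k
            evts.append((k + phi_to - off, "TO"))
        evts = sorted(e for e in evts if 0.0 <= float(clock_to_time(e[0])) <= duration)
        leg_event_clocks[leg] = evts

    # transitions; the within-stride instant the terrain change falls on is
    # randomized but alternates between the early-stance and late-stance
    # halves so that both HC- and TO-triggered transitions occur
    boundaries = np.cumsum([n for _, n in circuit.segments])[:-1]
    transitions: list[_Transition] = []
    parity = int(rng_trans.integers(2))
    t_index = 0
    for i, b in enumerate(boundaries):
        old_mode = circuit.modes[i]
        new_mode = circuit.modes[i + 1]
        if new_mode == old_mode:
            continue
        tr = _Transition(
            boundary_clock=float(b),
            old_mode=old_mode,
            new_mode=new_mode,
            leading=SIDES[int(rng_trans.integers(len(SIDES)))],
        )
        if (t_index + parity) % 2 == 0:
            delta0 = float(rng_trans.uniform(0.02, 0.34))  # lands on an HC
        else:
            delta0 = float(rng_trans.uniform(0.42, 0.88))  # lands on a TO
        t_index += 1
        tr.w_max_lead = float(rng_trans.uniform(*WMAX_LEAD_RANGE))
        tr.w_max_trail = float(rng_trans.uniform(*WMAX_TRAIL_RANGE))
        tr.precue = float(rng_trans.uniform(*PRECUE_RANGE))
        for leg in SIDES:
            lead = circuit.transition_lead if leg == tr.leading else 0.0
            switch_clock = tr.boundary_clock - delta0 - lead
            later = [c for c, _ in leg_event_clocks[leg] if c >= switch_clock]
            if not later:
                raise ValueError("circuit too short to place a transition")
            tr.event_time[leg] = float(clock_to_time(later[0]))
        transitions.append(tr)

    # per-leg mode timelines: switch exactly at the transitional event
    mode_timeline: dict[str, list[tuple[float, str]]] = {}
    for leg in SIDES:
        timeline = [(0.0, circuit.modes[0])]
        for tr in transitions:
            timeline.append((tr.event_time[leg], tr.new_mode))
        mode_timeline[leg] = timeline

    # ground-truth events with incoming/outgoing labels
    events: list[GaitEvent] = []
    for leg in SIDES:
        switch_times = np.array([t for t, _ in mode_timeline[leg]])
        labels = [m for _, m in mode_timeline[leg]]

        def label_at(t: float) -> str:
            idx = int(np.searchsorted(switch_times, t, side="right")) - 1
            return labels[max(idx, 0)]

        prev_out: str | None = None
        for c, etype in leg_event_clocks[leg]:
            t = float(clock_to_time(c))
            out = label_at(t)
            inc = prev_out if prev_out is not None else label_at(t)
            events.append(GaitEvent(t, leg, etype, inc, out))
            prev_out = out
    events.sort(key=lambda e: e.time_s)

    # ------------------------------------------------------------------
    # signal synthesis
    # ------------------------------------------------------------------
    stride_s = stride_nominal
    n_mech = int(round(duration * MECH_RATE))
    n_emg = int(round(duration * EMG_RATE))
    t_mech = np.arange(n_mech) / MECH_RATE
    t_emg = np.arange(n_emg) / EMG_RATE
    clock_mech = time_to_clock(t_mech)
    clock_emg = time_to_clock(t_emg)

    def blend_weight(leg: str, t: np.ndarray, tr: _Transition) -> np.ndarray:
        """Ramp toward tr.new_mode: anticipation before the leg's own
        transitional step plus a weak precue once the leading leg commits."""
        a = anticipation * stride_s
        settle = 0.15 * stride_s
        t_own = tr.event_time[leg]
        t_lead = tr.event_time[tr.leading]
        if leg == tr.leading:
            xp = [t_own - a, t_own, t_own + settle]
            fp = [0.0, tr.w_max_lead, 1.0]
        else:
            # short postural precue bump while the leading leg steps onto
            # the new terrain, decaying before the trailing leg's own
            # (weaker) anticipation ramp
            bump = 0.15 * stride_s
            residual = 0.25 * tr.precue
            xp = [t_lead - bump, t_lead, t_own - a, t_own, t_own + settle]
            fp = [0.0, tr.precue, residual, tr.w_max_trail, 1.0]
            xp, fp = zip(*sorted(zip(xp, fp)))
        return np.interp(t, xp, fp, left=0.0, right=1.0)

    def mode_mix(leg: str, t: np.ndarray, phase: np.ndarray,
                 tmpl_of: dict[str, ChannelTemplate]) -> np.ndarray:
        x = tmpl_of[circuit.modes[0]](phase)
        for tr in transitions:
            t_lead = tr.event_time[tr.leading]
            start = t_lead - anticipation * stride_s
            m = t >= start
            if not np.any(m):
                continue
            w = blend_weight(leg, t[m], tr)
            x[m] = (1.0 - w) * tmpl_of[tr.old_mode](phase[m]) + w * tmpl_of[tr.new_mode](phase[m])
        return x

    latents_mech, latents_emg = _drift_latents(rng_noise, duration, [t_mech, t_emg])
    loading_sd = drift_sd / math.sqrt(N_DRIFT_LATENTS)

    channels: dict[ChannelTag, np.ndarray] = {}
    for leg in SIDES:
        off = _LEG_OFFSET[leg]
        phase_mech = clock_mech + off
        phase_emg = clock_emg + off
        for tag in leg_channels(leg, processed=False):
            key = (tag.sensor, tag.channel)
            tmpl_of = {m: templates[m].channels[key] for m in set(circuit.modes)}
            scale = float(np.std(templates[circuit.modes[0]].channels[key](_PHASE_GRID)))
            scale = max(scale, 1e-6)
            loadings = loading_sd * rng_noise.standard_normal(N_DRIFT_LATENTS)
            if tag.modality == "emg":
                env = mode_mix(leg, t_emg, phase_emg, tmpl_of)
                env = np.maximum(env, 0.0)
                carrier = _band_limited_carrier(rng_noise.spawn(1)[0], n_emg, EMG_RATE)
                x = carrier * env * (1.0 + loadings @ latents_emg)
                x = x + noise_sd * scale * rng_noise.standard_normal(n_emg)
            else:
                x = mode_mix(leg, t_mech, phase_mech, tmpl_of)
                x = x * (1.0 + loadings @ latents_mech)
                x = x + noise_sd * scale * rng_noise.standard_normal(n_mech)
            channels[tag] = x.astype(np.float64)

    gt = GroundTruth(events=events, mode_timeline=mode_timeline)
    meta = {
        "circuit": list(circuit.segments),
        "transition_lead": circuit.transition_lead,
        "noise_sd": noise_sd,
        "anticipation": anticipation,
        "drift_sd": drift_sd,
        "duration_s": duration,
    }
    return TrialRecording(channels=channels, ground_truth=gt, seed=seed, meta=meta)
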