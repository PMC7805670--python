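"""Dual-minima gait segmentation and event labeling."""

import numpy as np
import pytest
from scipy import signal as sps

from gaitintent.events import (
    DetectorConfig,
    detect_events,
    detect_trial_events,
    label_events,
    match_events,
    triples_to_events,
)
from gaitintent.suite import SIDES, GaitEvent, shank_gyro_tag
from gaitintent.synth import CircuitSpec, simulate_trial


def brute_force_triples(x, fs, cfg):
    """Independent oracle: exhaustive local-extrema scan with the same
    height/distance/search-window rules as the detector."""
    sos = sps.butter(cfg.lp_order, cfg.lp_hz, btype="lowpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, np.asarray(x, dtype=float))
    # all strict local maxima above the height threshold
    cand = [
        i
        for i in range(1, len(y) - 1)
        if y[i] > y[i - 1] and y[i] >= y[i + 1] and y[i] >= cfg.min_peak_height
    ]
    # greedy distance pruning, highest peaks first (find_peaks semantics)
    distance = max(int(round(cfg.min_stride_s * fs)), 1)
    keep = []
    removed = set()
    for i in sorted(cand, key=lambda i: -y[i]):
        if i in removed:
            continue
        keep.append(i)
        for j in cand:
            if j != i and abs(j - i) < distance:
                removed.add(j)
    w = int(round(cfg.search_window_s * fs))
    triples = []
    for p in sorted(keep):
        if p - w < 0 or p + w >= len(y):
            continue
        i_to = p - w + int(np.argmin(y[p - w : p]))
        i_hc = p + 1 + int(np.argmin(y[p + 1 : p + w + 1]))
        triples.append((p / fs, i_to / fs, i_hc / fs))
    out = []
    for tr in triples:
        if out and tr[1] <= out[-1][2]:
            continue
        out.append(tr)
    return out


class TestDetectEvents:
    def test_zero_signal_empty(self):
        assert detect_events(np.zeros(5000)) == []

    def test_nonfinite_rejected(self):
        x = np.zeros(5000)
        x[10] = np.nan
        with pytest.raises(ValueError):
            detect_events(x)

    def test_noiseless_lw_timing(self, lw_trial_noiseless):
        """10 noiseless strides: 10 triples/leg, each within 30 ms of truth."""
        trial = lw_trial_noiseless
        gt = trial.ground_truth
        for leg in SIDES:
            triples = detect_events(trial.channels[shank_gyro_tag(leg)], fs=500)
            assert 9 <= len(triples) <= 10  # boundary mid-swing may be dropped
            det = np.sort(
                np.array([t.to_s for t in triples] + [t.hc_s for t in triples])
            )
            truth = np.array(
                [
                    e.time_s
                    for e in gt.leg_events(leg)
                    if det.min() - 0.05 <= e.time_s <= det.max() + 0.05
                ]
            )
            m, errs = match_events(det, truth, window_s=0.03)
            assert m == len(truth)

    def test_oracle_equivalence(self, templates):
        """Detector output equals the exhaustive-extrema oracle."""
        cfg = DetectorConfig()
        for seed in range(5):
            trial = simulate_trial(
                CircuitSpec([("LW", 5)]), templates, noise_sd=0.2, seed=seed
            )
            x = trial.channels[shank_gyro_tag("right")]
            got = [(t.mid_swing_s, t.to_s, t.hc_s) for t in detect_events(x, 500, cfg)]
            assert got == pytest.approx(brute_force_triples(x, 500, cfg))

    def test_triples_ordered_nonoverlapping(self, circuit_trial):
        for leg in SIDES:
            triples = detect_events(circuit_trial.channels[shank_gyro_tag(leg)], 500)
            for t in triples:
                assert t.to_s < t.mid_swing_s < t.hc_s
            for a, b in zip(triples, triples[1:]):
                assert a.hc_s < b.to_s

    def test_recall_precision_under_noise(self, templates):
        """>=99% of interior truth events recovered within 30 ms at noise up
        to 10% of the peak gyro amplitude; median timing error < 20 ms."""
        tmpl = templates["LW"].channels[("imu_shank", "gyro_y")]
        grid = np.linspace(0, 1, 2000, endpoint=False)
        peak = tmpl(grid).max()
        scale = tmpl(grid).std()
        circuit = CircuitSpec([("LW", 6), ("SA", 5), ("LW", 6)])
        for frac in (0.05, 0.10):
            n_truth = n_match = 0
            all_errs = []
            for seed in (0, 1, 2):
                trial = simulate_trial(
                    circuit, templates, noise_sd=frac * peak / scale, seed=seed
                )
                detected = detect_trial_events(trial)
                dur = trial.duration_s
                for leg in SIDES:
                    det = np.array(
                        [e.time_s for e in detected if e.leg == leg]
                    )
                    truth = np.array(
                        [
                            e.time_s
                            for e in trial.ground_truth.leg_events(leg)
                            if 0.9 <= e.time_s <= dur - 0.9
                        ]
                    )
                    m, errs = match_events(det, truth, window_s=0.1)
                    within = np.sum(np.abs(errs) <= 0.03)
                    n_truth += len(truth)
                    n_match += within
                    all_errs.extend(np.abs(errs))
            assert n_match / n_truth >= 0.99
            assert np.median(all_errs) < 0.02


class TestLabelEvents:
    @staticmethod
    def _events(times, leg="left", start="TO"):
        types = [start if i % 2 == 0 else ("HC" if start == "TO" else "TO") for i in range(len(times))]
        return [GaitEvent(t, leg, ty) for t, ty in zip(times, types)]

    def test_all_lw(self):
        events = self._events([1.0, 1.5, 2.0, 2.5])
        labeled = label_events(events, {"left": [(0.0, "LW")]})
        assert all(e.incoming_mode == e.outgoing_mode == "LW" for e in labeled)

    def test_switch_at_tstar(self):
        """The first event at/after the switch is the transitional one."""
        events = self._events([1.0, 1.5, 2.0, 2.5, 3.0])
        labeled = label_events(events, {"left": [(0.0, "LW"), (2.2, "SA")]})
        flags = [(e.time_s, e.incoming_mode, e.outgoing_mode) for e in labeled]
        assert flags == [
            (1.0, "LW", "LW"),
            (1.5, "LW", "LW"),
            (2.0, "LW", "LW"),
            (2.5, "LW", "SA"),
            (3.0, "SA", "SA"),
        ]

    def test_event_before_span_rejected(self):
        with pytest.raises(ValueError):
            label_events(self._events([0.2]), {"left": [(1.0, "LW")]})

    def test_transitional_count_matches_ground_truth(self, circuit_trial):
        """Per leg, labeled transitional events = mode switches crossed."""
        gt = circuit_trial.ground_truth
        detected = detect_trial_events(circuit_trial)
        labeled = label_events(detected, gt.mode_timeline)
        for leg in SIDES:
            n_switch = len(gt.mode_timeline[leg]) - 1
            n_trans = sum(
                1 for e in labeled if e.leg == leg and e.incoming_mode != e.outgoing_mode
            )
            assert n_trans == n_switch

    def test_straddling_events_dropped(self):
        """A decision inside the legs' label-disagreement span is excluded."""
        events = self._events([1.0, 2.0, 2.3, 3.0], leg="left") + self._events(
            [1.5, 2.5, 3.5], leg="right", start="HC"
        )
        timeline = {"left": [(0.0, "LW"), (2.9, "SA")], "right": [(0.0, "LW"), (2.2, "SA")]}
        labeled = label_events(events, timeline)
        left_times = [e.time_s for e in labeled if e.leg == "left"]
        assert 2.3 not in left_times  # straddles right's earlier switch
        kept = label_events(events, timeline, drop_straddling=False)
        assert 2.3 in [e.time_s for e in kept if e.leg == "left"]
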