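"""Shared fixtures: small synthetic sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gaitintent.events import detect_trial_events, label_events
from gaitintent.features import FeatureDataset, build_dataset, default_sensor_list
from gaitintent.features import EMG_FEATURE_NAMES, MECH_FEATURE_NAMES
from gaitintent.preprocess import preprocess_trial
from gaitintent.suite import MODES, SENSOR_MODALITY, sensor_channels
from gaitintent.synth import (
    CircuitSpec,
    make_default_templates,
    make_standard_circuits,
    simulate_trial,
)


@pytest.fixture(scope="session")
def templates():
    return make_default_templates(separation=1.0, seed=0)


@pytest.fixture(scope="session")
def lw_trial_noiseless(templates):
    """Noiseless 10-stride level-walking trial (event-detection oracle)."""
    circuit = CircuitSpec([("LW", 10)])
    return simulate_trial(circuit, templates, noise_sd=0.0, seed=11, drift_sd=0.0)


@pytest.fixture(scope="session")
def circuit_trial(templates):
    """One default-noise trial of the first standard circuit."""
    circuit = make_standard_circuits(4)[0]
    return simulate_trial(circuit, templates, noise_sd=0.25, seed=3)


@pytest.fixture(scope="session")
def processed_trial(circuit_trial):
    return preprocess_trial(circuit_trial)


@pytest.fixture(scope="session")
def labeled_events(circuit_trial):
    detected = detect_trial_events(circuit_trial)
    return label_events(detected, circuit_trial.ground_truth.mode_timeline)


@pytest.fixture(scope="session")
def small_dataset(processed_trial, labeled_events):
    """Feature dataset from one circuit trial (full bilateral suite)."""
    return build_dataset(processed_trial, labeled_events)


@pytest.fixture(scope="session")
def session_dataset(templates):
    """Both standard circuits x 3 repetitions at default study noise."""
    datasets = []
    for rep in range(3):
        for ci, circuit in enumerate(make_standard_circuits(4)):
            trial = simulate_trial(circuit, templates, noise_sd=0.25, seed=500 + 10 * rep + ci)
            labeled = label_events(
                detect_trial_events(trial), trial.ground_truth.mode_timeline
            )
            datasets.append(build_dataset(preprocess_trial(trial), labeled))
    return FeatureDataset.concat(datasets)


def full_bilateral_tags() -> pd.DataFrame:
    """The canonical 332-column tag frame of the full bilateral suite."""
    rows = []
    for side, sensor in default_sensor_list():
        modality = SENSOR_MODALITY[sensor]
        names = EMG_FEATURE_NAMES if modality == "emg" else MECH_FEATURE_NAMES
        for channel in sensor_channels(sensor, processed=True):
            for name in names:
                rows.append((side, sensor, channel, modality, name))
    return pd.DataFrame(rows, columns=["side", "sensor", "channel", "modality", "feature"])


def make_random_dataset(
    n_rows: int,
    rng: np.random.Generator,
    incoming: str = "RA",
    legs=("left", "right"),
    event_types=("HC", "TO"),
) -> FeatureDataset:
    """Full-suite tagged dataset with iid noise features and legal labels.

    Rows are events with the given incoming mode and outgoing modes drawn
    uniformly from its legal transitions — a scaffold for planted-signal
    and chance-level tests.
    """
    from gaitintent.suite import allowed_transitions

    tags = full_bilateral_tags()
    X = rng.standard_normal((n_rows, len(tags)))
    out = rng.choice(list(allowed_transitions(incoming)), size=n_rows)
    meta = pd.DataFrame(
        {
            "time_s": np.arange(n_rows, dtype=float),
            "leg": rng.choice(legs, size=n_rows),
            "event_type": rng.choice(event_types, size=n_rows),
            "incoming_mode": incoming,
            "outgoing_mode": out,
        }
    )
    return FeatureDataset(X, tags, meta)
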