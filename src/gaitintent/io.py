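"""Trial and feature-set persistence.

A trial is stored as a directory: one Parquet table per sampling rate
(columns named ``side.sensor.channel``), a YAML sidecar with channel tags,
rates, seed and circuit metadata, and the ground truth as a flat CSV event
table (time_s, leg, event_type, incoming_mode, outgoing_mode).  Feature
datasets use the same pattern (features.parquet + tags/meta CSVs).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import FeatureDataset
from .suite import ChannelTag, GaitEvent, GroundTruth, TrialRecording

_EVENT_COLUMNS = ["time_s", "leg", "event_type", "incoming_mode", "outgoing_mode"]


def events_to_frame(events: list[GaitEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.time_s, e.leg, e.event_type, e.incoming_mode, e.outgoing_mode) for e in events],
        columns=_EVENT_COLUMNS,
    )


def frame_to_events(df: pd.DataFrame) -> list[GaitEvent]:
    return [
        GaitEvent(r.time_s, r.leg, r.event_type, r.incoming_mode, r.outgoing_mode)
        for r in df.itertuples(index=False)
    ]


def save_trial(trial: TrialRecording, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rates = sorted({tag.rate for tag in trial.channels})
    tag_meta = []
    for rate in rates:
        cols = {}
        for tag, x in sorted(trial.channels.items()):
            if tag.rate != rate:
                continue
            cols[str(tag)] = x
            tag_meta.append(
                {
                    "id": str(tag),
                    "side": tag.side,
                    "sensor": tag.sensor,
                    "channel": tag.channel,
                    "modality": tag.modality,
                    "rate": tag.rate,
                }
            )
        pd.DataFrame(cols).to_parquet(path / f"channels_{rate}hz.parquet")
    meta = {
        "seed": trial.seed,
        "rates": rates,
        "channels": tag_meta,
        "meta": _plain(trial.meta),
    }
    gt = trial.ground_truth
    if gt is not None:
        events_to_frame(gt.events).to_csv(path / "ground_truth_events.csv", index=False)
        meta["mode_timeline"] = {
            leg: [[float(t), m] for t, m in tl] for leg, tl in gt.mode_timeline.items()
        }
    with open(path / "trial.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def load_trial(path: str | Path) -> TrialRecording:
    path = Path(path)
    with open(path / "trial.yaml") as fh:
        meta = yaml.safe_load(fh)
    channels: dict[ChannelTag, np.ndarray] = {}
    frames = {
        rate: pd.read_parquet(path / f"channels_{rate}hz.parquet")
        for rate in meta["rates"]
    }
    for entry in meta["channels"]:
        tag = ChannelTag(
            entry["side"], entry["sensor"], entry["channel"], entry["modality"], entry["rate"]
        )
        channels[tag] = frames[tag.rate][entry["id"]].to_numpy()
    gt = None
    events_path = path / "ground_truth_events.csv"
    if events_path.exists():
        gt = GroundTruth(
            events=frame_to_events(pd.read_csv(events_path)),
            mode_timeline={
                leg: [(float(t), m) for t, m in tl]
                for leg, tl in meta.get("mode_timeline", {}).items()
            },
        )
    return TrialRecording(
        channels=channels, ground_truth=gt, seed=meta.get("seed"), meta=meta.get("meta", {})
    )


def save_dataset(dataset: FeatureDataset, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(dataset.X).rename(columns=str).to_parquet(path / "features.parquet")
    dataset.feature_tags.to_csv(path / "feature_tags.csv", index=False)
    dataset.event_meta.to_csv(path / "event_meta.csv", index=False)
    return path


def load_dataset(path: str | Path) -> FeatureDataset:
    path = Path(path)
    X = pd.read_parquet(path / "features.parquet").to_numpy(dtype=float)
    tags = pd.read_csv(path / "feature_tags.csv")
    meta = pd.read_csv(path / "event_meta.csv")
    return FeatureDataset(X, tags, meta)


def _plain(obj):
    """Recursively convert to YAML-safe builtin types."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
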