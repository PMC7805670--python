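"""Sequential forward selection of contralateral sensors.

Starting from all 11 ipsilateral sensors as the baseline, each iteration
evaluates every remaining contralateral sensor by cross-validated overall
error of the mode-specific bank on (current set + candidate) and adds the
arg-min sensor; all of a sensor's features enter together.  Ties resolve to
the earlier sensor in the canonical per-leg order.  The same fold partition
(same seed) is reused for every candidate so the arg-min is not dominated
by partition noise.  Errors may rise in later iterations; the trace records
them but never prunes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassifierConfig, ErrorReport, cross_validate
from .features import FeatureDataset, relative_view
from .suite import LEG_SENSORS, SENSOR_MODALITY, features_per_channel, sensor_channels


def sensor_feature_count(sensor: str) -> int:
    """Features contributed by one sensor (incl. derived velocity channels)."""
    return sum(
        features_per_channel(SENSOR_MODALITY[sensor])
        for _ in sensor_channels(sensor, processed=True)
    )


@dataclass
class SelectionTrace:
    """Greedy selection path and the per-iteration cross-validated errors."""

    baseline: dict  # all-ipsilateral ErrorReport summary
    iterations: pd.DataFrame  # sensor, overall, steady_state, transitional, n_features
    reports: list[ErrorReport] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return list(self.iterations["sensor"])


def forward_select(
    dataset: FeatureDataset,
    cfg: ClassifierConfig = ClassifierConfig(),
    k: int = 10,
    seed: int = 0,
    max_iters: int | None = None,
) -> SelectionTrace:
    """Greedy contralateral sensor addition minimizing overall CV error.

    ``dataset`` must be a bilateral feature set (both sides' columns).
    ``max_iters`` truncates the trace (None runs to all 11 sensors).
    """
    baseline_report = cross_validate(
        relative_view(dataset, contra_sensors=[]), cfg, k=k, seed=seed
    )
    remaining = list(LEG_SENSORS)
    chosen: list[str] = []
    rows = []
    reports: list[ErrorReport] = []
    n_iters = len(remaining) if max_iters is None else min(max_iters, len(remaining))
    for _ in range(n_iters):
        scores = []
        for cand in remaining:
            view = relative_view(dataset, contra_sensors=chosen + [cand])
            rep = cross_validate(view, cfg, k=k, seed=seed)
            scores.append((rep.overall, cand, rep))
        best_err = min(s[0] for s in scores)
        # tie-break: first sensor in canonical order achieving the minimum
        _, best, best_rep = next(s for s in scores if s[0] == best_err)
        chosen.append(best)
        remaining.remove(best)
        reports.append(best_rep)
        rows.append(
            {
                "sensor": best,
                "modality": SENSOR_MODALITY[best],
                "overall": best_rep.overall,
                "steady_state": best_rep.steady_state,
                "transitional": best_rep.transitional,
                "n_features": 166 + sum(sensor_feature_count(s) for s in chosen),
            }
        )
    return SelectionTrace(
        baseline=baseline_report.summary(),
        iterations=pd.DataFrame(rows),
        reports=reports,
    )


def summarize_traces(traces: list[SelectionTrace]) -> pd.DataFrame:
    """Per-iteration mean +/- SE errors and cumulative modality composition.

    The modality composition is the proportion of the current feature set
    (ipsilateral baseline plus sensors chosen so far) contributed by each
    modality, averaged across traces.
    """
    if not traces:
        raise ValueError("need at least one trace")
    n_iter = min(len(t.iterations) for t in traces)
    ipsi_counts = {
        mod: sum(
            sensor_feature_count(s) for s in LEG_SENSORS if SENSOR_MODALITY[s] == mod
        )
        for mod in ("emg", "gonio", "imu")
    }
    rows = []
    for i in range(n_iter):
        errs = np.array([t.iterations["overall"].iloc[i] for t in traces])
        trans = np.array([t.iterations["transitional"].iloc[i] for t in traces])
        props = {mod: [] for mod in ipsi_counts}
        for t in traces:
            counts = dict(ipsi_counts)
            for s in t.iterations["sensor"].iloc[: i + 1]:
                counts[SENSOR_MODALITY[s]] += sensor_feature_count(s)
            total = sum(counts.values())
            for mod in counts:
                props[mod].append(counts[mod] / total)
        row = {
            "iteration": i + 1,
            "overall_mean": float(np.mean(errs)),
            "overall_se": float(np.std(errs, ddof=1) / np.sqrt(len(errs))) if len(errs) > 1 else 0.0,
            "transitional_mean": float(np.nanmean(trans)),
        }
        for mod in props:
            row[f"prop_{mod}"] = float(np.mean(props[mod]))
        rows.append(row)
    return pd.DataFrame(rows)
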