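"""Experiment orchestration: sensor-set grid, replicates, paired statistics.

A "session" is one simulated subject: mode templates drawn from a seed
(per-subject template jitter), repetitions of the two standard circuits,
causal preprocessing, dual-minima event detection, labeling from the
ground-truth timeline, and feature extraction — yielding one
:class:`~gaitintent.features.FeatureDataset` plus segmentation diagnostics.

The comparison grid mirrors the offline benchmark: four modality groups
(EMG, GONIO, IMU, ALL) x three lateralities (I, C, B) with LDA, plus SVM
and ANN for the fused (ALL) sets — 18 sensor-set/classifier cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassifierConfig, cross_validate
from .events import DetectorConfig, detect_trial_events, label_events, match_events
from .features import (
    FeatureDataset,
    STANDARD_WINDOW,
    WindowSpec,
    build_dataset,
    laterality_view,
)
from .preprocess import preprocess_trial
from .synth import CircuitSpec, make_default_templates, make_standard_circuits, simulate_trial

MODALITY_GROUPS = ("emg", "gonio", "imu", "all")
LATERALITIES = ("I", "C", "B")


@dataclass(frozen=True)
class GridCell:
    modality: str
    laterality: str
    backend: str = "LDA"


def default_grid() -> list[GridCell]:
    """12 LDA sensor-set cells plus SVM/ANN on the fused sets (18 total)."""
    cells = [GridCell(m, l, "LDA") for m in MODALITY_GROUPS for l in LATERALITIES]
    cells += [GridCell("all", l, b) for b in ("SVM", "ANN") for l in LATERALITIES]
    return cells


@dataclass
class SessionResult:
    """One simulated subject's feature data and segmentation diagnostics."""

    dataset: FeatureDataset
    n_truth_events: int = 0
    n_detected_events: int = 0
    n_matched_events: int = 0
    timing_errors_s: np.ndarray = field(default_factory=lambda: np.empty(0))


def run_session(
    seed: int,
    n_strides: int = 4,
    reps: int = 8,
    separation: float = 1.0,
    noise_sd: float = 0.25,
    drift_sd: float = 0.10,
    transition_lead: float = 0.5,
    window: WindowSpec = STANDARD_WINDOW,
    detector: DetectorConfig = DetectorConfig(),
    circuits: Sequence[CircuitSpec] | None = None,
    use_detected_events: bool = True,
) -> SessionResult:
    """Simulate and featurize one subject-session.

    Each repetition simulates both standard circuits with fresh stride
    timing and noise; the per-subject templates are shared.  With
    ``use_detected_events`` (the default) the analysis windows are anchored
    on detector output labeled from the ground-truth timeline, exactly as
    the offline pipeline would run on real recordings.
    """
    templates = make_default_templates(separation=separation, seed=seed)
    if circuits is None:
        circuits = make_standard_circuits(n_strides, transition_lead=transition_lead)
    datasets = []
    n_truth = n_det = n_match = 0
    errors = []
    trial_seed = 10_000 * (seed + 1)
    for rep in range(reps):
        for ci, circuit in enumerate(circuits):
            trial = simulate_trial(
                circuit, templates, noise_sd=noise_sd, drift_sd=drift_sd,
                seed=(trial_seed + 97 * rep + ci) % (2**31),
            )
            processed = preprocess_trial(trial)
            # detection runs on the raw gyro: the detector applies its own
            # zero-phase pre-filter, so event times carry no causal lag
            detected = detect_trial_events(trial, cfg=detector)
            gt = trial.ground_truth
            truth_times = np.array([e.time_s for e in gt.events])
            det_times = np.array([e.time_s for e in detected])
            m, errs = match_events(det_times, truth_times, window_s=0.1)
            n_truth += len(truth_times)
            n_det += len(det_times)
            n_match += m
            errors.append(errs)
            events = detected if use_detected_events else gt.events
            labeled = label_events(events, gt.mode_timeline)
            datasets.append(build_dataset(processed, labeled, spec=window))
    return SessionResult(
        dataset=FeatureDataset.concat(datasets),
        n_truth_events=n_truth,
        n_detected_events=n_det,
        n_matched_events=n_match,
        timing_errors_s=np.concatenate(errors) if errors else np.empty(0),
    )


def run_grid(
    datasets: dict[int, FeatureDataset],
    cells: Sequence[GridCell] | None = None,
    k: int = 10,
    base_config: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Cross-validate every grid cell on every replicate dataset.

    Returns a long-format table with one row per (cell x seed):
    seed, modality, laterality, backend, n_features, overall,
    steady_state, transitional, n_decisions.
    """
    cells = list(cells) if cells is not None else default_grid()
    rows = []
    for seed, dataset in datasets.items():
        for cell in cells:
            view = laterality_view(dataset, cell.laterality, cell.modality)
            cfg = ClassifierConfig(
                backend=cell.backend,
                reduction=base_config.reduction if cell.backend == "LDA" else None,
                merge_lw_ra=base_config.merge_lw_ra,
                window=base_config.window,
                seed=seed,
            )
            try:
                rep = cross_validate(view, cfg, k=k, seed=seed)
            except Exception as err:  # identify the failing cell
                raise RuntimeError(f"grid cell {cell} failed on seed {seed}") from err
            rows.append(
                {
                    "seed": seed,
                    "modality": cell.modality,
                    "laterality": cell.laterality,
                    "backend": cell.backend,
                    "n_features": view.n_features,
                    "overall": rep.overall,
                    "steady_state": rep.steady_state,
                    "transitional": rep.transitional,
                    "n_decisions": rep.n_decisions,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# paired statistics
# --------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Paired t comparison with Bonferroni family-wise control."""

    mean_diff: float
    t_stat: float
    p_value: float
    family_size: int
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def adjusted_alpha(self) -> float:
        return self.alpha / self.family_size

    @property
    def significant_raw(self) -> bool:
        return (not self.degenerate) and self.p_value < self.alpha

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < self.adjusted_alpha


def paired_compare(
    rates_a: Sequence[float],
    rates_b: Sequence[float],
    family_size: int = 1,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Classical paired t-test on a - b with Bonferroni-adjusted alpha."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-d and of equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        degenerate = True
        t_stat = 0.0 if np.mean(d) == 0 else float(np.sign(np.mean(d)) * np.inf)
        p = 1.0 if np.mean(d) == 0 else 0.0
    else:
        degenerate = False
        t_stat, p = stats.ttest_rel(a, b)
    return ComparisonResult(
        mean_diff=float(np.mean(d)),
        t_stat=float(t_stat),
        p_value=float(p),
        family_size=family_size,
        alpha=alpha,
        degenerate=degenerate,
    )


@dataclass
class StudyResult:
    """Multi-seed laterality comparison plus first-iteration sensor search."""

    laterality: pd.DataFrame  # per (seed, laterality): error rates
    sfs: pd.DataFrame  # per seed: baseline vs first added contralateral sensor
    n_decisions: int
    n_truth_events: int
    n_matched_events: int
    timing_errors_s: np.ndarray


def bilateral_benefit_study(
    seeds: Sequence[int] = tuple(range(10)),
    n_strides: int = 4,
    reps: int = 8,
    k: int = 10,
    include_sfs: bool = True,
    **session_kwargs,
) -> StudyResult:
    """Replicate-seeded test of the bilateral-fusion benefit.

    For each seed (a simulated subject) the full pipeline runs end to end;
    ipsilateral and bilateral fused sensor sets are cross-validated, and
    optionally the first sequential-forward-selection iteration over the 11
    contralateral sensors is performed.  Pooled decision counts and
    segmentation diagnostics are returned for auditing.
    """
    from .select import forward_select

    lat_rows, sfs_rows = [], []
    n_decisions = n_truth = n_matched = 0
    timing = []
    for seed in seeds:
        res = run_session(seed, n_strides=n_strides, reps=reps, **session_kwargs)
        n_truth += res.n_truth_events
        n_matched += res.n_matched_events
        timing.append(res.timing_errors_s)
        cfg = ClassifierConfig(seed=seed)
        for lat in ("I", "B"):
            view = laterality_view(res.dataset, lat, "all")
            rep = cross_validate(view, cfg, k=k, seed=seed)
            n_decisions += rep.n_decisions
            lat_rows.append(
                {
                    "seed": seed,
                    "laterality": lat,
                    "overall": rep.overall,
                    "steady_state": rep.steady_state,
                    "transitional": rep.transitional,
                    "n_decisions": rep.n_decisions,
                }
            )
        if include_sfs:
            trace = forward_select(res.dataset, cfg, k=k, seed=seed, max_iters=1)
            n_decisions += 12 * res.dataset.n_events  # baseline + 11 candidates
            sfs_rows.append(
                {
                    "seed": seed,
                    "baseline_overall": trace.baseline["overall"],
                    "first_overall": trace.iterations["overall"].iloc[0],
                    "first_sensor": trace.selected[0],
                    "first_modality": trace.iterations["modality"].iloc[0],
                }
            )
    return StudyResult(
        laterality=pd.DataFrame(lat_rows),
        sfs=pd.DataFrame(sfs_rows),
        n_decisions=n_decisions,
        n_truth_events=n_truth,
        n_matched_events=n_matched,
        timing_errors_s=np.concatenate(timing) if timing else np.empty(0),
    )


def segmentation_study(
    noise_fractions: Sequence[float] = (0.05, 0.10),
    seeds: Sequence[int] = (0, 1, 2),
    tolerance_s: float = 0.03,
    margin_s: float = 0.9,
) -> pd.DataFrame:
    """Event-detection recovery at noise levels relative to the gyro peak.

    For each noise level (fraction of the peak shank angular velocity) the
    detector runs on fresh trials; recall counts ground-truth events in the
    trial interior (``margin_s`` from either end, where a full dual-minima
    search window exists) recovered within ``tolerance_s``.
    """
    from .events import detect_trial_events, match_events
    from .suite import SIDES

    rows = []
    for frac in noise_fractions:
        n_truth = n_within = n_det = 0
        abs_errs = []
        for seed in seeds:
            templates = make_default_templates(separation=1.0, seed=seed)
            tmpl = templates["LW"].channels[("imu_shank", "gyro_y")]
            grid = np.linspace(0, 1, 2000, endpoint=False)
            noise_sd = frac * tmpl(grid).max() / tmpl(grid).std()
            circuit = CircuitSpec([("LW", 6), ("SA", 5), ("LW", 6)])
            trial = simulate_trial(circuit, templates, noise_sd=noise_sd, seed=100 + seed)
            detected = detect_trial_events(trial)
            dur = trial.duration_s
            for leg in SIDES:
                det = np.array([e.time_s for e in detected if e.leg == leg])
                truth = np.array(
                    [
                        e.time_s
                        for e in trial.ground_truth.leg_events(leg)
                        if margin_s <= e.time_s <= dur - margin_s
                    ]
                )
                _, errs = match_events(det, truth, window_s=0.1)
                n_truth += len(truth)
                n_within += int(np.sum(np.abs(errs) <= tolerance_s))
                n_det += len(det)
                abs_errs.extend(np.abs(errs))
        rows.append(
            {
                "noise_fraction": frac,
                "n_truth": n_truth,
                "n_within_tolerance": n_within,
                "recall": n_within / n_truth,
                "median_abs_error_ms": 1000.0 * float(np.median(abs_errs)),
            }
        )
    return pd.DataFrame(rows)


def paired_sign_test(
    rates_a: Sequence[float], rates_b: Sequence[float], alternative: str = "greater"
) -> float:
    """Exact sign-test p-value that a > b (ties dropped)."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    diff = a - b
    n = int(np.sum(diff != 0))
    if n == 0:
        return 1.0
    wins = int(np.sum(diff > 0))
    return float(stats.binomtest(wins, n, 0.5, alternative=alternative).pvalue)
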