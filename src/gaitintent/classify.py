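"""Mode-specific classifier bank with transition constraints.

One classifier is trained per (leg, gait event, incoming mode) cell —
2 legs x {HC, TO} x 5 modes = 20 for the bilateral able-bodied design.
Each cell's classes are restricted to the legal outgoing modes of its
incoming mode, so a prediction can never be an illegal transition.  Every
cell carries its own normalization (z-score) and optional PCA transform,
fitted on that cell's training rows only.

Backends: LDA (equiprobable priors, PCA to 95% variance by default), a
linear one-vs-one SVM (C=10), and a small MLP (one hidden layer of 10 tanh
units, SGD with momentum and an adaptive step initialized at 0.1).  Ties
between equally scored classes resolve to the lowest class index in the
fixed mode order LW, RA, RD, SA, SD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureDataset
from .suite import EVENT_TYPES, MODE_INDEX, MODES, SIDES, allowed_transitions

logger = logging.getLogger(__name__)

BACKENDS = ("LDA", "SVM", "ANN")


@dataclass(frozen=True)
class ClassifierConfig:
    """Backend and preprocessing options for the bank.

    ``reduction``: 'pca95' keeps the smallest number of principal
    components preserving >= 95% of training variance (the LDA default),
    'pca50' projects to at most 50 dimensions (powered-prosthesis
    variant), None disables reduction.  ``merge_lw_ra`` merges the level
    walking and ramp ascent classes (and their incoming cells) before
    training.
    """

    backend: str = "LDA"
    reduction: str | None = "pca95"
    merge_lw_ra: bool = False
    window: str = "standard"  # bookkeeping: which WindowSpec produced the data
    svm_c: float = 10.0
    ann_hidden: int = 10
    ann_max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"backend must be one of {BACKENDS}")
        if self.reduction not in ("pca95", "pca50", None):
            raise ValueError("reduction must be 'pca95', 'pca50' or None")


class _ConstantClassifier:
    """Degenerate cell: a single outgoing class was seen in training."""

    def __init__(self, label: int):
        self.label = label

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(len(X), self.label, dtype=int)


def _make_estimator(cfg: ClassifierConfig, n_classes: int, cell_seed: int):
    if cfg.backend == "LDA":
        return LinearDiscriminantAnalysis(priors=np.full(n_classes, 1.0 / n_classes))
    if cfg.backend == "SVM":
        return SVC(kernel="linear", C=cfg.svm_c, decision_function_shape="ovo")
    return MLPClassifier(
        hidden_layer_sizes=(cfg.ann_hidden,),
        activation="tanh",
        solver="sgd",
        learning_rate="adaptive",
        learning_rate_init=0.1,
        momentum=0.9,
        max_iter=cfg.ann_max_iter,
        random_state=cell_seed,
    )


@dataclass
class _Cell:
    scaler: StandardScaler
    pca: PCA | None
    estimator: object
    classes: list[int]  # mode codes seen in training

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler.transform(X)
        if self.pca is not None:
            Z = self.pca.transform(Z)
        return np.asarray(self.estimator.predict(Z), dtype=int)


@dataclass
class ModeSpecificBank:
    """Trained transition-constrained classifier bank."""

    cells: dict[tuple[str, str, str], _Cell]
    config: ClassifierConfig
    n_features: int

    def __len__(self) -> int:
        return len(self.cells)

    def route(self, leg: str, event_type: str, incoming_mode: str) -> tuple[str, str, str]:
        inc = _merge_mode(incoming_mode, self.config)
        return (leg, event_type, inc)

    def predict(self, X: np.ndarray, leg: str, event_type: str, incoming_mode: str) -> np.ndarray:
        """Predict outgoing modes for rows routed through one cell."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} != fitted {self.n_features}"
            )
        key = self.route(leg, event_type, incoming_mode)
        if key not in self.cells:
            logger.warning("no classifier for cell %s; predicting incoming mode", key)
            codes = np.full(len(X), MODE_INDEX[key[2]])
        else:
            codes = self.cells[key].predict(X)
        preds = [MODES[c] for c in codes]
        legal = set(allowed_transitions(key[2]))
        for p in preds:  # constraint soundness is a hard guarantee
            assert p in legal, f"illegal prediction {p} from incoming {incoming_mode}"
        return np.array(preds)


def _merge_mode(mode: str, cfg: ClassifierConfig) -> str:
    return "LW" if (cfg.merge_lw_ra and mode == "RA") else mode


def _fit_cell(X: np.ndarray, y_codes: np.ndarray, cfg: ClassifierConfig, cell_seed: int) -> _Cell:
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    pca = None
    classes = sorted(set(int(c) for c in y_codes))
    if len(classes) > 1 and cfg.reduction is not None and Z.shape[0] > 2:
        limit = min(Z.shape[0] - 1, Z.shape[1])
        if cfg.reduction == "pca95":
            # smallest component count preserving >= 95% of the variance
            full = PCA(n_components=limit, svd_solver="full").fit(Z)
            ratio = np.cumsum(full.explained_variance_ratio_)
            n_comp = int(np.searchsorted(ratio, 0.95) + 1)
            pca = PCA(n_components=min(n_comp, limit), svd_solver="full").fit(Z)
        else:  # pca50
            pca = PCA(n_components=min(50, limit), svd_solver="full").fit(Z)
        Z = pca.transform(Z)
    if len(classes) == 1 or len(y_codes) <= len(classes):
        # degenerate cell: a single class, or too few rows to fit a model;
        # predict the majority (first-in-mode-order on ties)
        counts = {c: int(np.sum(y_codes == c)) for c in classes}
        majority = min(classes, key=lambda c: (-counts[c], c))
        estimator = _ConstantClassifier(majority)
    else:
        estimator = _make_estimator(cfg, len(classes), cell_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            estimator.fit(Z, y_codes)
    return _Cell(scaler=scaler, pca=pca, estimator=estimator, classes=classes)


def train_bank(dataset: FeatureDataset, cfg: ClassifierConfig = ClassifierConfig()) -> ModeSpecificBank:
    """Fit one classifier per populated (leg, event, incoming-mode) cell."""
    if dataset.n_events == 0:
        raise ValueError("empty dataset")
    meta = dataset.event_meta
    incoming = meta["incoming_mode"].map(lambda m: _merge_mode(m, cfg))
    outgoing = meta["outgoing_mode"].map(lambda m: _merge_mode(m, cfg))
    y = outgoing.map(MODE_INDEX).to_numpy()

    cells: dict[tuple[str, str, str], _Cell] = {}
    expected = [
        (leg, et, _merge_mode(m, cfg))
        for leg in SIDES
        for et in EVENT_TYPES
        for m in MODES
        if _merge_mode(m, cfg) == m
    ]
    for key in expected:
        leg, et, inc = key
        mask = (
            (meta["leg"] == leg).to_numpy()
            & (meta["event_type"] == et).to_numpy()
            & (incoming == inc).to_numpy()
        )
        if not np.any(mask):
            logger.warning("no training rows for cell %s", key)
            continue
        cell_seed = (
            cfg.seed * 127
            + SIDES.index(leg) * 31
            + EVENT_TYPES.index(et) * 17
            + MODE_INDEX[inc]
        ) % (2**31)
        cells[key] = _fit_cell(dataset.X[mask], y[mask], cfg, cell_seed)
    return ModeSpecificBank(cells=cells, config=cfg, n_features=dataset.n_features)


def predict_dataset(bank: ModeSpecificBank, dataset: FeatureDataset) -> np.ndarray:
    """Route every row through its cell; returns predicted outgoing modes."""
    meta = dataset.event_meta
    preds = np.empty(dataset.n_events, dtype=object)
    groups = meta.groupby(["leg", "event_type", "incoming_mode"], sort=False)
    for (leg, et, inc), idx in groups.groups.items():
        rows = np.asarray(idx, dtype=int)
        preds[rows] = bank.predict(dataset.X[rows], leg, et, inc)
    return preds.astype(str)


# --------------------------------------------------------------------------
# error reporting
# --------------------------------------------------------------------------

@dataclass
class ErrorReport:
    """Per-(leg x event-type) and aggregate error proportions.

    ``cells`` is indexed by (leg, event_type) with decision/error counts
    split into steady-state (incoming == true outgoing) and transitional
    decisions.  Aggregates are unweighted means of the per-cell rates.
    """

    cells: pd.DataFrame
    config: ClassifierConfig | None = None

    @staticmethod
    def from_predictions(event_meta: pd.DataFrame, y_pred: np.ndarray,
                         config: ClassifierConfig | None = None) -> "ErrorReport":
        df = event_meta.copy()
        merge = config.merge_lw_ra if config is not None else False

        def canon(m):
            return "LW" if (merge and m == "RA") else m

        truth = df["outgoing_mode"].map(canon)
        pred = pd.Series(y_pred, index=df.index).map(canon)
        df["error"] = (pred != truth).to_numpy()
        df["transitional"] = (
            df["incoming_mode"].map(canon) != truth
        ).to_numpy()
        rows = []
        for (leg, et), g in df.groupby(["leg", "event_type"], sort=True):
            ss = g[~g["transitional"]]
            tr = g[g["transitional"]]
            rows.append(
                {
                    "leg": leg,
                    "event_type": et,
                    "n": len(g),
                    "n_err": int(g["error"].sum()),
                    "n_ss": len(ss),
                    "n_ss_err": int(ss["error"].sum()),
                    "n_trans": len(tr),
                    "n_trans_err": int(tr["error"].sum()),
                }
            )
        cells = pd.DataFrame(rows).set_index(["leg", "event_type"])
        cells["overall"] = cells["n_err"] / cells["n"]
        cells["steady_state"] = np.where(
            cells["n_ss"] > 0, cells["n_ss_err"] / cells["n_ss"].replace(0, 1), np.nan
        )
        cells["transitional"] = np.where(
            cells["n_trans"] > 0,
            cells["n_trans_err"] / cells["n_trans"].replace(0, 1),
            np.nan,
        )
        return ErrorReport(cells=cells, config=config)

    def _agg(self, col: str) -> float:
        vals = self.cells[col].to_numpy(dtype=float)
        return float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan")

    @property
    def overall(self) -> float:
        return self._agg("overall")

    @property
    def steady_state(self) -> float:
        return self._agg("steady_state")

    @property
    def transitional(self) -> float:
        return self._agg("transitional")

    @property
    def n_decisions(self) -> int:
        return int(self.cells["n"].sum())

    def summary(self) -> dict:
        return {
            "overall": self.overall,
            "steady_state": self.steady_state,
            "transitional": self.transitional,
            "n_decisions": self.n_decisions,
            "n_errors": int(self.cells["n_err"].sum()),
        }


def cross_validate(
    dataset: FeatureDataset,
    cfg: ClassifierConfig = ClassifierConfig(),
    k: int = 10,
    seed: int | None = 0,
    collect_banks: bool = False,
):
    """Randomized k-fold cross-validation of the bank on event rows.

    Rows are partitioned at random (``seed``; None disables shuffling).
    Transforms and classifiers are fitted on training folds only; errors
    are pooled over folds and reported per cell.  With
    ``collect_banks=True`` the per-fold banks are returned as well.
    """
    n = dataset.n_events
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"dataset has {n} rows < k={k}")
    kf = KFold(n_splits=k, shuffle=seed is not None, random_state=seed)
    y_pred = np.empty(n, dtype=object)
    banks = []
    row_mask = np.zeros(n, dtype=bool)
    for train_idx, test_idx in kf.split(np.arange(n)):
        train = _subset(dataset, train_idx)
        test = _subset(dataset, test_idx)
        bank = train_bank(train, cfg)
        y_pred[test_idx] = predict_dataset(bank, test)
        row_mask[test_idx] = True
        if collect_banks:
            banks.append(bank)
    assert row_mask.all()
    report = ErrorReport.from_predictions(dataset.event_meta, y_pred.astype(str), cfg)
    return (report, banks) if collect_banks else report


def leave_one_out(dataset: FeatureDataset, cfg: ClassifierConfig = ClassifierConfig()) -> ErrorReport:
    """Leave-one-out cross-validation (k = n, deterministic partition)."""
    return cross_validate(dataset, cfg, k=dataset.n_events, seed=None)


def _subset(dataset: FeatureDataset, idx: np.ndarray) -> FeatureDataset:
    return FeatureDataset(
        dataset.X[idx],
        dataset.feature_tags.copy(),
        dataset.event_meta.iloc[idx].reset_index(drop=True),
    )
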