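"""Mode-specific bank: constraints, cross-validation, error accounting."""

import numpy as np
import pandas as pd
import pytest

from gaitintent.classify import (
    ClassifierConfig,
    ErrorReport,
    cross_validate,
    leave_one_out,
    predict_dataset,
    train_bank,
)
from gaitintent.features import FeatureDataset, laterality_view
from gaitintent.suite import MODES, allowed_transitions

from conftest import full_bilateral_tags, make_random_dataset

MECH_NAMES = ("mean", "sd", "max", "min", "first", "last")


def blob_dataset(rng, n_per_class, incoming, outgoing_modes, sep=8.0, leg="left",
                 event="HC", n_features=24):
    """Well-separated Gaussian blobs in a small tagged feature space.

    Dimensionality stays below the row count so the classifiers operate in
    their regular (full-rank) regime.
    """
    tags = pd.DataFrame(
        {
            "side": "left",
            "sensor": [f"s{i // 6}" for i in range(n_features)],
            "channel": "c",
            "modality": "imu",
            "feature": [MECH_NAMES[i % 6] for i in range(n_features)],
        }
    )
    rows, meta = [], []
    for ci, out in enumerate(outgoing_modes):
        center = np.zeros(len(tags))
        center[ci * 3 : ci * 3 + 3] = sep
        for _ in range(n_per_class):
            rows.append(center + rng.standard_normal(len(tags)))
            meta.append((float(len(meta)), leg, event, incoming, out))
    meta = pd.DataFrame(
        meta, columns=["time_s", "leg", "event_type", "incoming_mode", "outgoing_mode"]
    )
    return FeatureDataset(np.array(rows), tags, meta)


class TestTransitionMap:
    def test_map_contents(self):
        assert set(allowed_transitions("LW")) == set(MODES)
        for m in ("RA", "RD", "SA", "SD"):
            assert set(allowed_transitions(m)) == {m, "LW"}
        for m in MODES:
            assert m in allowed_transitions(m)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            allowed_transitions("WALK")


class TestTrainBank:
    def test_bank_size_20(self, session_dataset):
        bank = train_bank(session_dataset, ClassifierConfig())
        assert len(bank) == 20

    def test_merge_lw_ra(self, session_dataset):
        bank = train_bank(session_dataset, ClassifierConfig(merge_lw_ra=True))
        assert len(bank) == 16  # RA cells merged into LW
        assert all(key[2] != "RA" for key in bank.cells)
        # the merged LW cells contain no separate RA class
        for key, cell in bank.cells.items():
            assert 1 not in cell.classes  # MODE_INDEX["RA"] == 1

    def test_single_class_cell_constant(self):
        rng = np.random.default_rng(0)
        ds = blob_dataset(rng, 10, "RA", ["RA"])
        bank = train_bank(ds, ClassifierConfig())
        preds = predict_dataset(bank, ds)
        assert (preds == "RA").all()

    def test_empty_dataset_rejected(self):
        tags = full_bilateral_tags()
        ds = FeatureDataset(
            np.empty((0, len(tags))),
            tags,
            pd.DataFrame(columns=["time_s", "leg", "event_type", "incoming_mode", "outgoing_mode"]),
        )
        with pytest.raises(ValueError):
            train_bank(ds)


class TestPredict:
    def test_constraint_soundness(self, session_dataset):
        """No prediction is ever outside the incoming mode's legal set."""
        bank = train_bank(session_dataset, ClassifierConfig())
        preds = predict_dataset(bank, session_dataset)
        incoming = session_dataset.event_meta["incoming_mode"].to_numpy()
        for inc, p in zip(incoming, preds):
            assert p in allowed_transitions(inc)

    def test_missing_cell_falls_back_to_incoming(self):
        rng = np.random.default_rng(1)
        ds = blob_dataset(rng, 8, "SA", ["SA", "LW"])
        bank = train_bank(ds, ClassifierConfig())
        out = bank.predict(ds.X[:3], "right", "TO", "RD")  # untrained cell
        assert (out == "RD").all()

    def test_dimension_mismatch_rejected(self, session_dataset):
        bank = train_bank(session_dataset, ClassifierConfig())
        with pytest.raises(ValueError):
            bank.predict(np.zeros((2, 10)), "left", "HC", "LW")

    @pytest.mark.parametrize("backend", ["LDA", "SVM", "ANN"])
    def test_backend_parity_on_separable_cell(self, backend):
        """All backends reach zero training error on separable 2-class data."""
        rng = np.random.default_rng(2)
        ds = blob_dataset(rng, 15, "SA", ["SA", "LW"], sep=10.0)
        cfg = ClassifierConfig(backend=backend, reduction=None, seed=0)
        bank = train_bank(ds, cfg)
        preds = predict_dataset(bank, ds)
        assert (preds == ds.event_meta["outgoing_mode"].to_numpy()).all()


class TestCrossValidate:
    def test_separable_dataset_zero_error(self):
        rng = np.random.default_rng(3)
        parts = [
            blob_dataset(rng, 12, "LW", ["LW", "SA", "RD"], sep=12.0, leg=leg, event=ev)
            for leg in ("left", "right")
            for ev in ("HC", "TO")
        ]
        ds = FeatureDataset.concat(parts)
        report = cross_validate(ds, ClassifierConfig(seed=0), k=6, seed=0)
        assert report.overall == 0.0

    def test_chance_level_on_permuted_labels(self):
        """Random labels in 2-class cells give ~50% cell error."""
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            ds = make_random_dataset(80, rng, incoming="RA")
            cfg = ClassifierConfig(reduction=None, seed=seed)
            report = cross_validate(ds, cfg, k=5, seed=seed)
            errors.append(report.overall)
        assert 0.4 <= float(np.mean(errors)) <= 0.6

    def test_error_counts_partition(self, session_dataset):
        report = cross_validate(session_dataset, ClassifierConfig(seed=0), k=5, seed=0)
        cells = report.cells
        assert (cells["n_err"] == cells["n_ss_err"] + cells["n_trans_err"]).all()
        assert (cells["n"] == cells["n_ss"] + cells["n_trans"]).all()
        assert report.n_decisions == session_dataset.n_events

    def test_no_leakage_from_test_fold(self, session_dataset):
        """Perturbing a test-fold row leaves that fold's fitted transforms
        and all other predictions unchanged."""
        ds = session_dataset
        cfg = ClassifierConfig(seed=0)
        rep1, banks1 = cross_validate(ds, cfg, k=5, seed=0, collect_banks=True)

        from sklearn.model_selection import KFold

        folds = list(KFold(5, shuffle=True, random_state=0).split(np.arange(ds.n_events)))
        victim = folds[0][1][0]  # a row tested in fold 0
        X2 = ds.X.copy()
        X2[victim] += 1e6
        ds2 = FeatureDataset(X2, ds.feature_tags.copy(), ds.event_meta.copy())
        rep2, banks2 = cross_validate(ds2, cfg, k=5, seed=0, collect_banks=True)

        cell_key = next(iter(banks1[0].cells))
        s1 = banks1[0].cells[cell_key].scaler.mean_
        s2 = banks2[0].cells[cell_key].scaler.mean_
        assert np.array_equal(s1, s2)

    def test_invalid_k(self, session_dataset):
        with pytest.raises(ValueError):
            cross_validate(session_dataset, k=1)

    def test_reproducible(self, small_dataset):
        r1 = cross_validate(small_dataset, ClassifierConfig(seed=1), k=4, seed=7)
        r2 = cross_validate(small_dataset, ClassifierConfig(seed=1), k=4, seed=7)
        pd.testing.assert_frame_equal(r1.cells, r2.cells)


class TestLeaveOneOut:
    def test_separable_zero_error(self):
        rng = np.random.default_rng(4)
        ds = blob_dataset(rng, 5, "SA", ["SA", "LW"], sep=12.0)
        assert leave_one_out(ds, ClassifierConfig(seed=0)).overall == 0.0

    def test_equals_cv_with_k_n(self):
        rng = np.random.default_rng(5)
        ds = blob_dataset(rng, 6, "RD", ["RD", "LW"], sep=3.0)
        a = leave_one_out(ds, ClassifierConfig(seed=0))
        b = cross_validate(ds, ClassifierConfig(seed=0), k=ds.n_events, seed=None)
        pd.testing.assert_frame_equal(a.cells, b.cells)


class TestLateralityRecovery:
    def test_bilateral_not_worse_than_ipsilateral(self, session_dataset):
        """Smoke-scale analogue of the bilateral-benefit finding; the full
        multi-seed sign test runs in the acceptance suite."""
        cfg = ClassifierConfig(seed=0)
        rep_i = cross_validate(laterality_view(session_dataset, "I"), cfg, k=10, seed=0)
        rep_b = cross_validate(laterality_view(session_dataset, "B"), cfg, k=10, seed=0)
        assert rep_b.transitional <= rep_i.transitional + 0.05


class TestProsthesisVariantConfig:
    def test_pca50_with_merge_and_delay(self, session_dataset):
        """The powered-prosthesis configuration (PCA to 50 dims, merged
        LW/RA classes) trains and stays within its constraint set."""
        cfg = ClassifierConfig(reduction="pca50", merge_lw_ra=True, window="delayed", seed=0)
        report = cross_validate(session_dataset, cfg, k=5, seed=0)
        assert 0.0 <= report.overall <= 1.0
        bank = train_bank(session_dataset, cfg)
        for key, cell in bank.cells.items():
            if cell.pca is not None:
                assert cell.pca.n_components_ <= 50
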