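"""Training protocol, detection metrics, ROC, threshold, evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import ccecg
from ccecg.exceptions import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedMetricError,
)
from ccecg.sim import Dataset
from ccecg.training import (
    TrainConfig,
    balanced_accuracy,
    evaluate,
    oversample_balance,
    roc,
    select_threshold,
    sensitivity_specificity,
    train,
)


def replicate_dataset(n_sh, n_nsh):
    """Dataset of repeated strips with the requested class counts."""
    vf = ccecg.gen_vf(10, 0)
    asys = ccecg.gen_asystole(10, 0)
    strips = [vf] * n_sh + [asys] * n_nsh
    return Dataset(strips=strips, ids=[f"s{i}" for i in range(len(strips))])


class TestOversample:
    def test_study_ratio_counts(self):
        """408 Sh vs 2593 NSh at factor 6 gives 2448 Sh and untouched NSh."""
        ds = oversample_balance(replicate_dataset(408, 2593), factor=6, seed=0)
        y = ds.labels()
        assert int((y == 1).sum()) == 2448
        assert int((y == 0).sum()) == 2593
        assert len(ds) == 2593 + 6 * 408

    def test_factor_one_only_reorders(self):
        base = replicate_dataset(3, 7)
        ds = oversample_balance(base, factor=1, seed=1)
        assert sorted(ds.ids) == sorted(base.ids)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            oversample_balance(replicate_dataset(0, 5), factor=6)


class TestDetectionMetrics:
    def test_published_confusion_counts(self):
        """Se and Sp reproduce the printed test-set worked example."""
        se, _ = sensitivity_specificity(268, 33, 1, 0)
        _, sp = sensitivity_specificity(1, 0, 4830, 460)
        assert round(100 * se, 1) == 89.0
        assert round(100 * sp, 1) == 91.3
        assert round(100 * balanced_accuracy(se, sp), 1) == 90.2

    def test_limits(self):
        se, sp = sensitivity_specificity(5, 0, 0, 3)
        assert se == 1.0 and sp == 0.0
        assert balanced_accuracy(1, 0) == 0.5
        assert balanced_accuracy(1, 1) == 1.0

    def test_empty_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity_specificity(0, 0, 5, 5)

    def test_constant_classifier_bac_is_half(self):
        """A classifier that always answers NSh has BAC exactly 0.5."""
        scores = np.full(40, 0.2)
        labels = np.r_[np.ones(10), np.zeros(30)].astype(int)
        pred = scores >= 0.5
        tp, fn = int((pred & (labels == 1)).sum()), int((~pred & (labels == 1)).sum())
        tn, fp = int((~pred & (labels == 0)).sum()), int((pred & (labels == 0)).sum())
        assert balanced_accuracy(*sensitivity_specificity(tp, fn, tn, fp)) == 0.5


def bruteforce_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


def bruteforce_best_threshold(scores, labels):
    cands = np.unique(np.r_[scores, scores.max() + 1])
    best = None
    for thr in cands:
        pred = scores >= thr
        se = (pred & (labels == 1)).sum() / (labels == 1).sum()
        sp = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        key = ((se + sp) / 2, se, -thr)
        if best is None or key > best[0]:
            best = (key, thr)
    return best[1]


class TestRoc:
    def test_perfect_separation(self):
        curve = roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert curve.auc == pytest.approx(1.0)

    def test_all_tied_scores(self):
        curve = roc([0.5] * 10, [1, 0] * 5)
        assert curve.auc == pytest.approx(0.5)

    def test_small_example(self):
        curve = roc([0.9, 0.8, 0.4, 0.1], [1, 0, 1, 0])
        assert curve.auc == pytest.approx(0.75)

    def test_matches_pair_statistic_and_sklearn(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.random(n), 2)  # rounding induces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            curve = roc(scores, labels)
            assert curve.auc == pytest.approx(bruteforce_auc(scores, labels), abs=1e-9)
            assert curve.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)

    def test_threshold_selection_matches_bruteforce(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 30))
            scores = np.round(rng.random(n), 1)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert select_threshold(roc(scores, labels)) == pytest.approx(
                bruteforce_best_threshold(scores, labels)
            )

    def test_degenerate_scores_use_tie_rule(self):
        """All-equal scores: both operating points give BAC 0.5; the rule
        (higher Se, then lower threshold) picks the all-shock threshold."""
        curve = roc([0.4, 0.4, 0.4], [1, 0, 1])
        assert select_threshold(curve) == pytest.approx(0.4)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc([0.1, 0.9], [1, 1])


class TestTrain:
    def test_constant_label_training_early_stops_to_majority(self, tiny_val_ds):
        train_ds = replicate_dataset(0, 12)
        model = ccecg.build_model(ccecg.cnn3_preset(), init_seed=0)
        cfg = TrainConfig(max_epochs=30, early_stop_patience=3, seed=0)
        result = train(model, train_ds, tiny_val_ds, cfg)
        assert result.stopped_early or len(result.history) <= 30
        p = model.predict_proba(tiny_val_ds.waveforms())
        assert np.all(p < 0.5)  # everything called non-shockable

    def test_history_contract(self, tiny_train_ds, tiny_val_ds):
        model = ccecg.build_model(ccecg.cnn3_preset(), init_seed=1)
        cfg = TrainConfig(max_epochs=4, early_stop_patience=3, seed=1)
        result = train(model, tiny_train_ds, tiny_val_ds, cfg)
        hist = result.history
        assert len(hist) <= 4
        assert list(hist.columns) == [
            "epoch", "train_loss", "train_bac", "val_loss", "val_bac",
        ]
        assert 1 <= result.best_epoch <= len(hist)
        assert result.best_val_bac == pytest.approx(hist["val_bac"].max())

    def test_empty_dataset_rejected(self, tiny_val_ds):
        model = ccecg.build_model(ccecg.cnn3_preset(), init_seed=0)
        with pytest.raises(InvalidInputError):
            train(model, Dataset(strips=[]), tiny_val_ds)

    def test_patience_must_fit_schedule(self):
        with pytest.raises(InvalidParameterError):
            TrainConfig(max_epochs=100, early_stop_patience=150)


class TestEvaluate:
    def test_counts_match_manual_tally(self, tiny_train_ds):
        model = ccecg.build_model(ccecg.cnn3_preset(), init_seed=2)
        scores = model.predict_proba(tiny_train_ds.waveforms())
        y = tiny_train_ds.labels()
        pthr = float(np.median(scores))
        pthr = min(max(pthr, 1e-6), 1 - 1e-6)
        report = evaluate(model, tiny_train_ds, pthr)
        pred = scores >= pthr
        assert report.tp == int((pred & (y == 1)).sum())
        assert report.fn == int((~pred & (y == 1)).sum())
        assert report.tn == int((~pred & (y == 0)).sum())
        assert report.fp == int((pred & (y == 0)).sum())
        assert report.tp + report.fn == int((y == 1).sum())
        assert report.tn + report.fp == int((y == 0).sum())
        assert report.bac == pytest.approx((report.se + report.sp) / 2)

    def test_strata_counts_sum_to_totals(self, tiny_train_ds):
        model = ccecg.build_model(ccecg.cnn3_preset(), init_seed=2)
        report = evaluate(model, tiny_train_ds, 0.5)
        assert report.by_snr["n"].sum() == len(tiny_train_ds)
        assert report.by_cc_rate["n"].sum() == len(tiny_train_ds)
        # per-rhythm specificity counts cover all non-shockable strips
        n_nsh = sum(d["n"] for d in report.per_rhythm_sp.values())
        assert n_nsh == report.tn + report.fp

    def test_all_correct_has_unit_rates_and_ci_at_one(self):
        ds = replicate_dataset(4, 6)
        model = ccecg.build_model(ccecg.cnn3_preset(), init_seed=0)
        scores = model.predict_proba(ds.waveforms())
        y = ds.labels()
        # choose a threshold that separates the two replicated score values
        lo = scores[y == 0].max()
        hi = scores[y == 1].min()
        if lo >= hi:  # force separation by flipping the sign of dense weights
            model.dense_w[:] = -model.dense_w
            scores = model.predict_proba(ds.waveforms())
            lo, hi = scores[y == 0].max(), scores[y == 1].min()
        assert hi > lo
        report = evaluate(model, ds, (lo + hi) / 2)
        assert report.se == 1.0 and report.sp == 1.0 and report.bac == 1.0
        assert report.se_ci[1] == pytest.approx(1.0)
        assert report.sp_ci[1] == pytest.approx(1.0)

    def test_missing_strata_are_absent_not_zero(self):
        ds = replicate_dataset(3, 3)  # clean strips: no SNR, no CC rate
        model = ccecg.build_model(ccecg.cnn3_preset(), init_seed=0)
        report = evaluate(model, ds, 0.5)
        assert report.by_snr.empty
        assert report.by_cc_rate.empty
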