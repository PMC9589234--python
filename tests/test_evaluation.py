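"""Splits, confusion counts, metric formulas, and the AUC oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegdep.evaluation import (
    ConfusionMatrix,
    auc_mann_whitney,
    confusion,
    make_splits,
    metrics,
    roc_auc,
    task_labels,
)


def cohort_manifest(n_healthy=30, n_nonmajor=16, n_major=16, windows=60):
    rows = []
    for group, n in (("healthy", n_healthy), ("non_major", n_nonmajor),
                     ("major", n_major)):
        for i in range(n):
            sid = f"{group[0]}{i:03d}"
            for w in range(windows):
                rows.append(
                    {"subject_id": sid, "group": group,
                     "window_index": w, "path": f"{sid}_{w}.png"}
                )
    return pd.DataFrame(rows)


def brute_force_auc(labels, scores):
    """All-pairs concordance count; ties count one half."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestSplits:
    def test_diagnosis_split_reproduces_reference_counts(self):
        manifest = cohort_manifest()
        plans = make_splits(manifest, "diagnosis", unit="image", seed=3)
        assert len(plans) == 10
        _, labels = task_labels(manifest, "diagnosis")
        for plan in plans:
            trainval, test = plan.trainval_idx, plan.test_idx
            assert (labels[trainval] == 0).sum() == 1440
            assert (labels[trainval] == 1).sum() == 1536
            assert (labels[test] == 0).sum() == 360
            assert (labels[test] == 1).sum() == 384

    def test_severity_split_reproduces_reference_counts(self):
        manifest = cohort_manifest()
        plans = make_splits(manifest, "severity", unit="image", seed=3)
        _, labels = task_labels(manifest, "severity")
        for plan in plans:
            assert (labels[plan.trainval_idx] == 0).sum() == 768
            assert (labels[plan.trainval_idx] == 1).sum() == 768
            assert (labels[plan.test_idx] == 0).sum() == 192
            assert (labels[plan.test_idx] == 1).sum() == 192

    def test_partitions_disjoint_and_exhaustive(self):
        manifest = cohort_manifest(4, 3, 3, windows=5)
        for plan in make_splits(manifest, "diagnosis", seed=0):
            parts = np.concatenate([plan.train_idx, plan.val_idx, plan.test_idx])
            assert len(parts) == len(set(parts)) == 50

    def test_inner_split_yields_64_16_20(self):
        manifest = cohort_manifest()
        plan = make_splits(manifest, "diagnosis", seed=1)[0]
        n = 3720
        assert abs(len(plan.train_idx) - 0.64 * n) <= 2
        assert abs(len(plan.val_idx) - 0.16 * n) <= 2
        assert len(plan.test_idx) == 744

    def test_subject_level_split_has_no_subject_overlap(self):
        manifest = cohort_manifest(6, 4, 4, windows=6)
        sid = manifest["subject_id"].to_numpy()
        for plan in make_splits(manifest, "diagnosis", unit="subject", seed=2):
            train_s = set(sid[plan.trainval_idx])
            test_s = set(sid[plan.test_idx])
            assert not train_s & test_s

    def test_image_level_split_shares_subjects(self):
        # the documented leakage property of image-level splitting
        manifest = cohort_manifest(6, 4, 4, windows=6)
        sid = manifest["subject_id"].to_numpy()
        plan = make_splits(manifest, "diagnosis", unit="image", seed=2)[0]
        assert set(sid[plan.trainval_idx]) & set(sid[plan.test_idx])

    def test_unknown_labels_rejected(self):
        manifest = cohort_manifest(2, 1, 1, windows=2)
        manifest.loc[0, "group"] = "mystery"
        with pytest.raises(ValueError):
            make_splits(manifest, "diagnosis", seed=0)


class TestConfusion:
    def test_simple_counts(self):
        cm = confusion([1, 0], [0.9, 0.1])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 1, 0, 0)

    def test_threshold_tie_counts_positive(self):
        cm = confusion([1, 0, 1], [0.5, 0.5, 0.5])
        assert cm.tp == 2 and cm.fp == 1 and cm.tn == 0

    def test_row_sums_match_fold_composition(self):
        # 744-image test fold composition: 384 positive, 360 negative
        cm = ConfusionMatrix(tp=166, fn=218, fp=32, tn=328)
        assert cm.tp + cm.fn == 384
        assert cm.fp + cm.tn == 360
        assert cm.n == 744

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [])


class TestMetrics:
    def test_diagnosis_fold_metrics(self):
        rep = metrics(ConfusionMatrix(tp=166, fn=218, fp=32, tn=328))
        assert rep.accuracy * 100 == pytest.approx(66.40, abs=0.005)
        assert rep.precision * 100 == pytest.approx(83.84, abs=0.005)
        assert rep.recall * 100 == pytest.approx(43.23, abs=0.005)
        assert rep.f1 * 100 == pytest.approx(57.04, abs=0.005)

    def test_perfect_classifier(self):
        rep = metrics(ConfusionMatrix(tp=50, tn=50, fp=0, fn=0))
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (1, 1, 1, 1)

    def test_f1_is_harmonic_mean_of_precision_recall(self):
        p, r = 0.6349, 0.7969
        f1 = 2 * p * r / (p + r)
        assert f1 * 100 == pytest.approx(70.67, abs=0.005)

    def test_zero_matrix_yields_nan_not_exception(self):
        rep = metrics(ConfusionMatrix(0, 0, 0, 0))
        assert np.isnan(rep.accuracy) and np.isnan(rep.precision)

    @given(
        tp=st.integers(0, 50), tn=st.integers(0, 50),
        fp=st.integers(0, 50), fn=st.integers(0, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_f1_identity_property(self, tp, tn, fp, fn):
        rep = metrics(ConfusionMatrix(tp, tn, fp, fn))
        if not (np.isnan(rep.precision) or np.isnan(rep.recall)):
            p, r = rep.precision, rep.recall
            if p + r > 0:
                assert rep.f1 == pytest.approx(2 * p * r / (p + r))


class TestAUC:
    def test_hand_counted_example(self):
        labels = [1, 1, 0, 0]
        scores = [0.9, 0.6, 0.7, 0.2]
        assert auc_mann_whitney(labels, scores) == 0.75

    def test_perfect_separation(self):
        assert auc_mann_whitney([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_equals_brute_force_pair_counting(self, rng):
        for n in (5, 20, 77, 200):
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # ties likely
            assert auc_mann_whitney(labels, scores) == pytest.approx(
                brute_force_auc(labels, scores)
            )

    def test_independent_scores_near_half(self, rng):
        labels = rng.integers(0, 2, size=1000)
        scores = rng.random(1000)
        assert 0.45 < auc_mann_whitney(labels, scores) < 0.55

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([1, 1], [0.5, 0.6])

    def test_bootstrap_ci_brackets_point_estimate(self, rng):
        labels = np.array([1] * 40 + [0] * 40)
        scores = np.concatenate(
            [rng.normal(0.6, 0.2, 40), rng.normal(0.4, 0.2, 40)]
        )
        auc, (lo, hi) = roc_auc(labels, scores, n_boot=500, seed=1)
        assert lo <= auc <= hi
        assert 0 <= lo and hi <= 1

    def test_bootstrap_ci_deterministic_given_seed(self, rng):
        labels = np.array([1] * 20 + [0] * 20)
        scores = rng.random(40)
        assert roc_auc(labels, scores, seed=9) == roc_auc(labels, scores, seed=9)
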