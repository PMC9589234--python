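"""Cross-validated evaluation: splits, confusion counts, metrics, ROC/AUC.

The dataset is divided ten times into stratified train/test sets at an
8:2 ratio; inside each training set a further 8:2 train/validation
split yields the 64/16/20 partition. Splitting can operate at the
image level (reproducing the reference cohort's image counts, but sharing
subjects across sets) or at the subject level (no within-subject
leakage).

Metrics follow the standard confusion-matrix definitions:
AC = (TP+TN)/(TP+FN+TN+FP), Precision = TP/(TP+FP),
Recall = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN). AUC is the Mann-Whitney
pair-concordance statistic with ties counted one half; its 95% CI comes
from a seeded stratified bootstrap.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from .cnn import CNNConfig, CNNModel

TASKS = ("diagnosis", "severity")
N_FOLDS_DEFAULT = 10

_POSITIVE = {"diagnosis": ("non_major", "major"), "severity": ("major",)}


@dataclass
class SplitPlan:
    """One fold's image-index partition into train/validation/test."""

    task: str
    fold_id: int  # 1-based
    unit: str  # "image" or "subject"
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    @property
    def trainval_idx(self) -> np.ndarray:
        return np.concatenate([self.train_idx, self.val_idx])


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float = float("nan")
    auc_ci: tuple[float, float] = (float("nan"), float("nan"))
    confusion: ConfusionMatrix | None = None
    per_fold: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["auc_ci"] = list(self.auc_ci)
        return d

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, allow_nan=True))
        return path


def task_labels(manifest: pd.DataFrame, task: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Restrict the manifest to the task's rows and return binary labels.

    diagnosis: healthy (0) vs any depression (1) on all images;
    severity: non-major (0) vs major (1) on depression images only.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    groups = manifest["group"].to_numpy()
    known = {"healthy", "non_major", "major"}
    bad = set(groups) - known
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}")
    if task == "severity":
        sub = manifest[manifest["group"] != "healthy"].reset_index(drop=True)
    else:
        sub = manifest.reset_index(drop=True)
    labels = sub["group"].isin(_POSITIVE[task]).to_numpy(dtype=int)
    return sub, labels


def make_splits(
    manifest: pd.DataFrame,
    task: str,
    unit: str = "image",
    seed: int = 0,
    n_folds: int = N_FOLDS_DEFAULT,
) -> list[SplitPlan]:
    """Ten stratified 64/16/20 train/validation/test partitions."""
    if unit not in ("image", "subject"):
        raise ValueError(f"unknown split unit {unit!r}")
    sub, labels = task_labels(manifest, task)
    if np.unique(labels).size < 2:
        raise ValueError("need both classes present to split")
    plans = []
    if unit == "image":
        outer = StratifiedShuffleSplit(
            n_splits=n_folds, test_size=0.2, random_state=seed & 0x7FFFFFFF
        )
        folds = list(outer.split(np.zeros(len(labels)), labels))
    else:
        subj = sub.groupby("subject_id", sort=True)["group"].first()
        sids = subj.index.to_numpy()
        s_lab = subj.isin(_POSITIVE[task]).to_numpy(dtype=int)
        outer = StratifiedShuffleSplit(
            n_splits=n_folds, test_size=0.2, random_state=seed & 0x7FFFFFFF
        )
        folds = []
        sid_of = sub["subject_id"].to_numpy()
        for tr_s, te_s in outer.split(np.zeros(len(sids)), s_lab):
            tr = np.flatnonzero(np.isin(sid_of, sids[tr_s]))
            te = np.flatnonzero(np.isin(sid_of, sids[te_s]))
            folds.append((tr, te))
    for fold_id, (trainval, test) in enumerate(folds, start=1):
        inner = StratifiedShuffleSplit(
            n_splits=1, test_size=0.2,
            random_state=(seed + 1000 * fold_id) & 0x7FFFFFFF,
        )
        if unit == "image":
            tr_i, va_i = next(
                inner.split(np.zeros(len(trainval)), labels[trainval])
            )
            train_idx, val_idx = trainval[tr_i], trainval[va_i]
        else:
            sid_of = sub["subject_id"].to_numpy()
            tv_sids = np.unique(sid_of[trainval])
            tv_lab = (
                sub.set_index("subject_id")["group"]
                .groupby(level=0).first()
                .loc[tv_sids].isin(_POSITIVE[task]).to_numpy(dtype=int)
            )
            tr_s, va_s = next(inner.split(np.zeros(len(tv_sids)), tv_lab))
            train_idx = np.flatnonzero(np.isin(sid_of, tv_sids[tr_s]))
            val_idx = np.flatnonzero(np.isin(sid_of, tv_sids[va_s]))
        plans.append(
            SplitPlan(
                task=task,
                fold_id=fold_id,
                unit=unit,
                train_idx=np.sort(train_idx),
                val_idx=np.sort(val_idx),
                test_idx=np.sort(test),
            )
        )
    return plans


def confusion(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> ConfusionMatrix:
    """Confusion counts at a threshold; score >= threshold is positive."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall, F1 from confusion counts.

    A zero denominator yields NaN (undefined) rather than an exception.
    """

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return MetricsReport(
        accuracy=ratio(cm.tp + cm.tn, cm.n),
        precision=ratio(cm.tp, cm.tp + cm.fp),
        recall=ratio(cm.tp, cm.tp + cm.fn),
        f1=ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
        confusion=cm,
    )


def auc_mann_whitney(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney rank-sum (ties count 1/2)."""
    from scipy.stats import rankdata

    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for AUC")
    ranks = rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_auc(
    labels: np.ndarray,
    scores: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """AUC with a 95% CI from a seeded stratified bootstrap (percentile)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    auc = auc_mann_whitney(labels, scores)
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos, size=pos.size, replace=True)
        ni = rng.choice(neg, size=neg.size, replace=True)
        idx = np.concatenate([pi, ni])
        boots[b] = auc_mann_whitney(labels[idx], scores[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, (float(lo), float(hi))


def roc_points(labels: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    """FPR/TPR pairs over all score thresholds."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def evaluate_task(
    manifest: pd.DataFrame,
    images: np.ndarray,
    task: str,
    config: CNNConfig,
    seed: int = 0,
    unit: str = "image",
    n_folds: int = N_FOLDS_DEFAULT,
    threshold: float = 0.5,
) -> tuple[MetricsReport, pd.DataFrame]:
    """Train one model per fold and pool test-set scores.

    ``images`` must be aligned with ``manifest`` rows (same order).
    Returns the pooled report (per-fold metrics inside) and a frame of
    pooled test-set scores (fold, image row, subject, label, score).
    """
    sub, labels = task_labels(manifest, task)
    if task == "severity":
        keep = manifest["group"].to_numpy() != "healthy"
        imgs = images[keep]
    else:
        imgs = images
    plans = make_splits(manifest, task, unit=unit, seed=seed, n_folds=n_folds)
    pooled_rows = []
    per_fold = []
    for plan in plans:
        cfg = CNNConfig(**{**config.to_dict(), "seed": (config.seed + plan.fold_id)})
        model = CNNModel(cfg)
        model.fit(
            imgs[plan.train_idx], labels[plan.train_idx],
            imgs[plan.val_idx], labels[plan.val_idx],
        )
        scores = model.predict_scores(imgs[plan.test_idx])
        y = labels[plan.test_idx]
        cm = confusion(y, scores, threshold)
        rep = metrics(cm)
        fold_auc = auc_mann_whitney(y, scores)
        per_fold.append(
            {
                "fold": plan.fold_id,
                "n_test": int(cm.n),
                "accuracy": rep.accuracy,
                "precision": rep.precision,
                "recall": rep.recall,
                "f1": rep.f1,
                "auc": fold_auc,
                "best_epoch": model.best_epoch,
            }
        )
        for row, yy, ss in zip(plan.test_idx, y, scores):
            pooled_rows.append(
                {
                    "fold": plan.fold_id,
                    "row": int(row),
                    "subject_id": sub["subject_id"].iloc[row],
                    "label": int(yy),
                    "score": float(ss),
                }
            )
    pooled = pd.DataFrame(pooled_rows)
    cm = confusion(pooled["label"].to_numpy(), pooled["score"].to_numpy(), threshold)
    report = metrics(cm)
    report.auc, report.auc_ci = roc_auc(
        pooled["label"].to_numpy(), pooled["score"].to_numpy(), seed=seed
    )
    report.per_fold = per_fold
    return report, pooled
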