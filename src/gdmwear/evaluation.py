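"""Leave-one-subject-out evaluation of the GDM detector.

Each subject is held out in turn; of the remaining subjects, 10% (at least
one, chosen subject-wise by a seeded RNG) form a validation set used for
early stopping and threshold selection, and the rest train the model.  The
normalizer is refitted on each split's training windows, so no statistic
ever leaks from the held-out subject.

Reported per split: AUC (rank-based, ties averaged), balanced accuracy,
sensitivity, specificity and F1 at the validation-selected threshold.
Split metrics are aggregated as unweighted means; pooled per-window
metrics over all held-out predictions are reported alongside for
transparency.  A per-task accuracy table stratified by group and limb role
mirrors the usual per-activity breakdown.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import detector as det
from .segmentation import WindowSet, apply_normalizer, fit_normalizer
from .synthcohort import SubjectSpec

logger = logging.getLogger(__name__)

VALIDATION_FRACTION = 0.1


@dataclass(frozen=True)
class SplitPlan:
    test_subject: str
    validation_subjects: frozenset[str]
    train_subjects: frozenset[str]


@dataclass
class SplitMetrics:
    auc: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
        }


def loso_splits(subject_ids: Sequence[str], seed: int) -> list[SplitPlan]:
    """One split per subject; validation = ceil(10% of the rest), seeded."""
    ids = list(subject_ids)
    if len(ids) < 3:
        raise ValueError("LOSO needs at least 3 subjects")
    rng = np.random.default_rng(seed)
    plans = []
    for test in ids:
        rest = [s for s in ids if s != test]
        n_val = max(1, math.ceil(VALIDATION_FRACTION * len(rest)))
        val = rng.choice(rest, size=n_val, replace=False)
        plans.append(SplitPlan(
            test_subject=test,
            validation_subjects=frozenset(val.tolist()),
            train_subjects=frozenset(set(rest) - set(val.tolist())),
        ))
    return plans


def compute_metrics(y_true: np.ndarray, scores: np.ndarray, threshold: float) -> SplitMetrics:
    """Threshold metrics plus rank-based AUC.

    With a single-class ``y_true`` the AUC is undefined and reported as
    NaN (with a warning); sensitivity or specificity is likewise NaN for
    the absent class.  Balanced accuracy is the mean of the two rates.
    """
    y_true = np.asarray(y_true, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    pred = scores >= threshold
    n_pos = int(y_true.sum())
    n_neg = int((~y_true).sum())
    if n_pos and n_neg:
        auc = float(roc_auc_score(y_true, scores))
    else:
        logger.warning("single-class y_true: AUC undefined")
        auc = math.nan
    tp = int((pred & y_true).sum())
    tn = int((~pred & ~y_true).sum())
    fp = n_neg - tn
    fn = n_pos - tp
    sens = tp / n_pos if n_pos else math.nan
    spec = tn / n_neg if n_neg else math.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else math.nan
    return SplitMetrics(
        auc=auc,
        balanced_accuracy=(sens + spec) / 2,
        sensitivity=sens,
        specificity=spec,
        f1=f1,
    )


def per_task_accuracy(meta: pd.DataFrame, pred: np.ndarray) -> pd.DataFrame:
    """Accuracy per (group, side_role, task_context) cell.

    ``meta`` must carry columns group, side_role, task_context and the true
    window label ``gdm_true``.  Cells with no windows are omitted.
    """
    df = meta.copy()
    df["correct"] = np.asarray(pred, dtype=bool) == df["gdm_true"].to_numpy(dtype=bool)
    table = (
        df.groupby(["group", "side_role", "task_context"], observed=True)["correct"]
        .agg(accuracy="mean", n_windows="size")
        .reset_index()
    )
    return table


@dataclass
class LosoResult:
    per_split: dict[str, SplitMetrics]
    thresholds: dict[str, float]
    mean: dict[str, float]
    pooled: SplitMetrics
    per_task: pd.DataFrame
    predictions: pd.DataFrame  # one row per held-out window

    def to_report(self) -> dict:
        return {
            "mean": self.mean,
            "pooled": self.pooled.as_dict(),
            "per_split": {k: v.as_dict() for k, v in self.per_split.items()},
            "thresholds": self.thresholds,
            "per_task": self.per_task.to_dict(orient="records"),
            "n_windows": int(len(self.predictions)),
            "gdm_window_fraction": float(self.predictions["gdm_true"].mean()),
        }


def _side_role(subject: SubjectSpec, side: str) -> str:
    return "affected" if side == subject.affected_side else "unaffected"


def stack_windows(window_sets: Sequence[WindowSet]) -> tuple[np.ndarray, pd.DataFrame]:
    """Concatenate window sets into one array + per-window metadata frame."""
    nonempty = [w for w in window_sets if len(w)]
    data = np.concatenate([w.data for w in nonempty], axis=0)
    meta = pd.concat(
        [
            pd.DataFrame({
                "subject_id": w.subject_id,
                "side": w.side,
                "start": w.start,
                "gdm_true": w.gdm_label,
                "task_context": w.task_context.astype(str),
            })
            for w in nonempty
        ],
        ignore_index=True,
    )
    return data, meta


def run_loso(
    subjects: Sequence[SubjectSpec],
    window_sets: Sequence[WindowSet],
    seed: int,
    fs: float = 25.0,
    detector_kwargs: dict | None = None,
) -> LosoResult:
    """Full LOSO evaluation of the detector over a cohort's windows."""
    detector_kwargs = detector_kwargs or {}
    by_id = {s.subject_id: s for s in subjects}
    data, meta = stack_windows(window_sets)
    ids_with_windows = [s.subject_id for s in subjects
                        if s.subject_id in set(meta["subject_id"])]
    if len(ids_with_windows) < 3:
        raise ValueError("LOSO needs windows from at least 3 subjects")
    plans = loso_splits(ids_with_windows, seed)
    subject_col = meta["subject_id"].to_numpy()
    labels = meta["gdm_true"].to_numpy(dtype=bool)

    per_split: dict[str, SplitMetrics] = {}
    thresholds: dict[str, float] = {}
    pred_frames: list[pd.DataFrame] = []
    for plan in plans:
        tr = np.isin(subject_col, list(plan.train_subjects))
        va = np.isin(subject_col, list(plan.validation_subjects))
        te = subject_col == plan.test_subject
        norm = fit_normalizer(data[tr])
        weights = det.compute_class_weights(labels[tr])
        model = det.train_detector(
            apply_normalizer(norm, data[tr]), labels[tr], weights,
            apply_normalizer(norm, data[va]), labels[va],
            normalizer=norm, fs=fs, seed=seed, **detector_kwargs,
        )
        scores = det.predict(model, apply_normalizer(norm, data[te]))
        metrics = compute_metrics(labels[te], scores, model.threshold)
        if math.isnan(metrics.auc):
            logger.warning(
                "test subject %s has a single window class; reporting "
                "threshold-based metrics only", plan.test_subject,
            )
        per_split[plan.test_subject] = metrics
        thresholds[plan.test_subject] = model.threshold
        frame = meta.loc[te].copy()
        frame["score"] = scores
        frame["pred"] = det.classify(scores, model.threshold)
        pred_frames.append(frame)
        logger.info(
            "split %s: %d train / %d val / %d test windows, AUC=%.3f",
            plan.test_subject, tr.sum(), va.sum(), te.sum(), metrics.auc,
        )

    predictions = pd.concat(pred_frames, ignore_index=True)
    mean = {
        k: float(np.nanmean([m.as_dict()[k] for m in per_split.values()]))
        for k in ("auc", "balanced_accuracy", "sensitivity", "specificity", "f1")
    }
    # pooled per-window metrics use each split's own threshold via `pred`
    pooled_pred = predictions["pred"].to_numpy(dtype=bool)
    pooled_true = predictions["gdm_true"].to_numpy(dtype=bool)
    pooled = compute_metrics(
        pooled_true, predictions["score"].to_numpy(), threshold=math.inf
    )
    tp = int((pooled_pred & pooled_true).sum())
    tn = int((~pooled_pred & ~pooled_true).sum())
    n_pos, n_neg = int(pooled_true.sum()), int((~pooled_true).sum())
    pooled.sensitivity = tp / n_pos if n_pos else math.nan
    pooled.specificity = tn / n_neg if n_neg else math.nan
    pooled.balanced_accuracy = (pooled.sensitivity + pooled.specificity) / 2
    denom = 2 * tp + (n_neg - tn) + (n_pos - tp)
    pooled.f1 = 2 * tp / denom if denom else math.nan

    task_meta = predictions.copy()
    task_meta["group"] = [by_id[s].group for s in task_meta["subject_id"]]
    task_meta["side_role"] = [
        _side_role(by_id[s], side)
        for s, side in zip(task_meta["subject_id"], task_meta["side"])
    ]
    per_task = per_task_accuracy(task_meta, task_meta["pred"].to_numpy())
    return LosoResult(
        per_split=per_split, thresholds=thresholds, mean=mean,
        pooled=pooled, per_task=per_task, predictions=predictions,
    )
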