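"""Windowed GDM / non-GDM classifier.

The reference backend is gradient-boosted trees (XGBoost) over a summary
representation of each normalized window: the 28-value movement descriptor
computed window-wise.  Training uses per-sample class weights (each class
weighted by the other class's training proportion, so the minority class
counts more) and early stopping on a validation split.  The operating
threshold is chosen on validation scores by maximizing the geometric mean
of sensitivity and specificity.

An optional compact convolutional backend would slot in behind the same
interface; the tree backend is the deterministic default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import xgboost
from xgboost import XGBClassifier

from .features import window_feature_matrix
from .segmentation import Normalizer

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights; each class weighted by the other's share."""

    w_gdm: float
    w_non: float

    def __post_init__(self) -> None:
        if not (self.w_gdm > 0 and self.w_non > 0):
            raise ValueError("class weights must be positive")
        if abs(self.w_gdm + self.w_non - 1.0) > 1e-9:
            raise ValueError("class weights must sum to 1")


@dataclass
class DetectorModel:
    backend: str
    booster: "XGBClassifier | xgboost.Booster"
    threshold: float
    normalizer: Normalizer
    fs: float

    def score(self, features: np.ndarray) -> np.ndarray:
        """GDM probability from a window feature matrix."""
        if isinstance(self.booster, xgboost.Booster):
            return self.booster.inplace_predict(features)
        return self.booster.predict_proba(features)[:, 1]


def compute_class_weights(labels: np.ndarray) -> ClassWeights:
    """w_gdm = non-GDM proportion, w_non = GDM proportion of the labels."""
    labels = np.asarray(labels, dtype=bool)
    n = len(labels)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == n:
        raise ValueError("both classes must be present to compute weights")
    return ClassWeights(w_gdm=(n - n_pos) / n, w_non=n_pos / n)


def _featurize(windows: np.ndarray, fs: float) -> np.ndarray:
    return window_feature_matrix(windows, fs)


def train_detector(
    train_windows: np.ndarray,
    train_labels: np.ndarray,
    weights: ClassWeights,
    val_windows: np.ndarray,
    val_labels: np.ndarray,
    normalizer: Normalizer,
    fs: float,
    seed: int = 0,
    backend: str = "gbt",
    n_estimators: int = 300,
    early_stopping_rounds: int = 20,
) -> DetectorModel:
    """Fit the detector with weighted loss and validation early stopping.

    Windows must already be normalized with ``normalizer`` (fitted on the
    training split).  Deterministic given ``seed`` for the gbt backend.
    """
    if backend != "gbt":
        raise ValueError(f"unsupported backend: {backend!r}")
    train_labels = np.asarray(train_labels, dtype=bool)
    val_labels = np.asarray(val_labels, dtype=bool)
    if len(val_windows) == 0:
        raise ValueError("empty validation set: early stopping undefined")
    if train_labels.all() or not train_labels.any():
        raise ValueError("training labels must contain both classes")
    x_train = _featurize(train_windows, fs)
    x_val = _featurize(val_windows, fs)
    sample_weight = np.where(train_labels, weights.w_gdm, weights.w_non)
    clf = XGBClassifier(
        n_estimators=n_estimators,
        max_depth=4,
        learning_rate=0.1,
        subsample=0.9,
        colsample_bytree=0.9,
        tree_method="hist",
        eval_metric="auc",
        early_stopping_rounds=early_stopping_rounds,
        n_jobs=1,
        random_state=seed,
    )
    clf.fit(
        x_train, train_labels.astype(int),
        sample_weight=sample_weight,
        eval_set=[(x_val, val_labels.astype(int))],
        verbose=False,
    )
    val_scores = clf.predict_proba(x_val)[:, 1]
    threshold = select_threshold(val_scores, val_labels)
    return DetectorModel(
        backend=backend, booster=clf, threshold=threshold,
        normalizer=normalizer, fs=fs,
    )


def gmean_tpr_tnr(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    pred = scores >= threshold
    labels = np.asarray(labels, dtype=bool)
    tpr = (pred & labels).sum() / max(labels.sum(), 1)
    tnr = (~pred & ~labels).sum() / max((~labels).sum(), 1)
    return float(np.sqrt(tpr * tnr))


def select_threshold(val_scores: np.ndarray, val_labels: np.ndarray) -> float:
    """Threshold maximizing sqrt(TPR * TNR) on the validation split.

    Candidates are the sorted unique scores and the midpoints between
    consecutive unique scores (the exact optimum of the stepwise TPR/TNR
    curves lies on this grid); ties break toward the lower threshold.
    """
    val_labels = np.asarray(val_labels, dtype=bool)
    if val_labels.all() or not val_labels.any():
        raise ValueError("validation labels must contain both classes")
    uniq = np.unique(np.asarray(val_scores, dtype=float))
    candidates = np.sort(np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2]))
    best_t, best_g = candidates[0], -1.0
    for t in candidates:
        g = gmean_tpr_tnr(val_scores, val_labels, t)
        if g > best_g + 1e-12:
            best_g, best_t = g, t
    return float(best_t)


def predict(model: DetectorModel, windows: np.ndarray) -> np.ndarray:
    """GDM probability per window; expects normalized windows."""
    windows = np.asarray(windows, dtype=float)
    if len(windows):
        sd = windows.reshape(-1, windows.shape[2]).std(axis=0)
        if np.any(sd > 5) or np.any(sd < 0.02):
            logger.warning(
                "window channel SDs far from 1 (%s): input may not be normalized",
                np.round(sd, 3),
            )
    return model.score(_featurize(windows, model.fs))


def classify(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Binary decision: score >= threshold."""
    return np.asarray(scores, dtype=float) >= threshold


def save_detector(model: DetectorModel, path: str) -> None:
    """Serialize backend name, booster, threshold and normalizer.

    Writes ``<path>`` (JSON metadata) and ``<path>.booster.json``
    (the XGBoost model in its JSON format).
    """
    import json
    from pathlib import Path

    booster_path = Path(str(path) + ".booster.json")
    if isinstance(model.booster, xgboost.Booster):
        booster = model.booster
    else:
        booster = model.booster.get_booster()
        best = getattr(model.booster, "best_iteration", None)
        if best is not None and best + 1 < booster.num_boosted_rounds():
            booster = booster[: best + 1]  # keep the early-stopped model
    booster.save_model(booster_path)
    Path(path).write_text(json.dumps({
        "backend": model.backend,
        "threshold": model.threshold,
        "fs": model.fs,
        "normalizer_mean": model.normalizer.mean.tolist(),
        "normalizer_std": model.normalizer.std.tolist(),
        "booster_file": booster_path.name,
    }, indent=2) + "\n")


def load_detector(path: str) -> DetectorModel:
    import json
    from pathlib import Path

    meta = json.loads(Path(path).read_text())
    booster = xgboost.Booster()
    booster.load_model(str(Path(path).parent / meta["booster_file"]))
    return DetectorModel(
        backend=meta["backend"],
        booster=booster,
        threshold=float(meta["threshold"]),
        normalizer=Normalizer(
            mean=np.array(meta["normalizer_mean"]),
            std=np.array(meta["normalizer_std"]),
        ),
        fs=float(meta["fs"]),
    )
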