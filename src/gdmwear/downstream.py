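"""Subject-level impairment markers from detected GDM periods.

Window-level detector decisions are converted to a per-sample GDM mask
(majority vote over the overlapping windows covering each sample).  The
masked samples from both wrists are pooled into one epoch per subject and
summarized with the 28-value movement descriptor; the same is done for the
entire recording as a comparison condition.  Subject descriptors feed
three analyses:

* elastic-net logistic regression classifying stroke vs control (LOSO);
* elastic-net linear regression predicting the Fugl-Meyer score within the
  stroke group (LOSO), reported as MAE and explained variance;
* per-feature group statistics: means, SDs, pooled-SD Cohen's d
  (stroke minus control) and a two-sided pooled-variance t-test.

Elastic-net hyperparameters (mixing ratio in {0.1, 0.5, 0.9}, logarithmic
regularization grid) are chosen by inner cross-validation inside each
training fold; features are standardized per fold.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.linear_model import ElasticNetCV, LogisticRegressionCV
from sklearn.preprocessing import StandardScaler

from .features import FEATURE_NAMES, extract_features
from .preprocess import KinematicsPair
from .segmentation import WindowSet
from .synthcohort import SubjectSpec

logger = logging.getLogger(__name__)

L1_RATIOS = (0.1, 0.5, 0.9)
MIN_MASKED_SAMPLES = 8

Source = Literal["gdm_periods", "entire_recording"]


def gdm_sample_mask(
    n_samples: int,
    starts: np.ndarray,
    win_len: int,
    predictions: np.ndarray,
    rule: str = "majority",
) -> np.ndarray:
    """Per-sample GDM mask from overlapping window predictions.

    ``majority``: a sample is GDM iff more than half of the windows
    covering it are predicted GDM; samples covered by no window are
    non-GDM.  ``any``: one positive covering window suffices.
    """
    if rule not in ("majority", "any"):
        raise ValueError(f"unknown voting rule: {rule!r}")
    starts = np.asarray(starts, dtype=int)
    predictions = np.asarray(predictions, dtype=bool)
    cover = np.zeros(n_samples + 1)
    pos = np.zeros(n_samples + 1)
    np.add.at(cover, starts, 1)
    np.add.at(cover, np.minimum(starts + win_len, n_samples), -1)
    np.add.at(pos, starts[predictions], 1)
    np.add.at(pos, np.minimum(starts[predictions] + win_len, n_samples), -1)
    cover = np.cumsum(cover[:-1])
    pos = np.cumsum(pos[:-1])
    if rule == "majority":
        return 2 * pos > cover
    return pos >= 1


def subject_features(
    kin_by_side: Mapping[str, KinematicsPair],
    mask_by_side: Mapping[str, np.ndarray] | None,
    fs: float = 25.0,
) -> dict[str, float]:
    """28-value descriptor of one subject's pooled (masked) epochs.

    Both wrists are required; masked samples are concatenated across
    wrists into a single epoch per signal.  With ``mask_by_side=None`` the
    entire recording is used.  Fewer than 8 pooled samples raises, so the
    caller can flag and exclude the subject.
    """
    for side in ("left", "right"):
        if side not in kin_by_side:
            raise ValueError(f"missing session for side: {side}")
    acc_parts, vel_parts = [], []
    for side in ("left", "right"):
        kin = kin_by_side[side]
        if mask_by_side is None:
            mask = np.ones(len(kin.acc), dtype=bool)
        else:
            mask = np.asarray(mask_by_side[side], dtype=bool)
        acc_parts.append(kin.acc[mask])
        vel_parts.append(kin.vel[mask])
    acc = np.concatenate(acc_parts)
    vel = np.concatenate(vel_parts)
    if len(acc) < MIN_MASKED_SAMPLES:
        raise ValueError(
            f"only {len(acc)} masked samples (< {MIN_MASKED_SAMPLES})"
        )
    return extract_features(acc, vel, fs)


def build_subject_feature_table(
    subjects: Sequence[SubjectSpec],
    kinematics: Mapping[tuple[str, str], KinematicsPair],
    masks: Mapping[tuple[str, str], np.ndarray] | None,
    fs: float = 25.0,
) -> pd.DataFrame:
    """One descriptor row per subject; subjects with too little detected
    GDM signal are logged and excluded."""
    rows = {}
    for subject in subjects:
        kin = {s: kinematics[(subject.subject_id, s)] for s in ("left", "right")
               if (subject.subject_id, s) in kinematics}
        mask = None if masks is None else {
            s: masks[(subject.subject_id, s)] for s in kin
        }
        try:
            rows[subject.subject_id] = subject_features(kin, mask, fs)
        except ValueError as exc:
            logger.warning("excluding subject %s: %s", subject.subject_id, exc)
    return pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_NAMES)]


@dataclass
class ClassificationReport:
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    coefficients: pd.Series  # mean |coefficient| per feature over folds
    predictions: pd.Series | None = None  # held-out prediction per subject

    def as_dict(self) -> dict:
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "coefficients": self.coefficients.to_dict(),
        }


@dataclass
class RegressionReport:
    mae: float
    explained_variance: float
    coefficients: pd.Series

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "explained_variance": self.explained_variance,
            "coefficients": self.coefficients.to_dict(),
        }


def classify_groups(
    features: pd.DataFrame, groups: pd.Series, seed: int = 0
) -> ClassificationReport:
    """LOSO elastic-net logistic regression, stroke as the positive class."""
    groups = groups.loc[features.index]
    y = (groups == "stroke").to_numpy()
    if y.sum() < 3 or (~y).sum() < 3:
        raise ValueError("need at least 3 subjects per group")
    x = features.to_numpy(dtype=float)
    preds = np.zeros(len(y), dtype=bool)
    coefs = []
    for i in range(len(y)):
        tr = np.ones(len(y), dtype=bool)
        tr[i] = False
        scaler = StandardScaler().fit(x[tr])
        clf = LogisticRegressionCV(
            Cs=10, cv=3, solver="saga", l1_ratios=list(L1_RATIOS),
            max_iter=5000, random_state=seed,
            scoring="balanced_accuracy", n_jobs=1,
        )
        with warnings.catch_warnings():
            # separable folds legitimately stop at max_iter
            warnings.simplefilter("ignore")
            clf.fit(scaler.transform(x[tr]), y[tr])
        preds[i] = clf.predict(scaler.transform(x[[i]]))[0]
        coefs.append(np.abs(clf.coef_[0]))
    sens = float((preds & y).sum() / y.sum())
    spec = float((~preds & ~y).sum() / (~y).sum())
    return ClassificationReport(
        balanced_accuracy=(sens + spec) / 2,
        sensitivity=sens,
        specificity=spec,
        coefficients=pd.Series(np.mean(coefs, axis=0), index=features.columns),
        predictions=pd.Series(preds, index=features.index),
    )


def regress_fma(
    features: pd.DataFrame, fma: pd.Series, seed: int = 0
) -> RegressionReport:
    """LOSO elastic-net regression of the Fugl-Meyer score (stroke only).

    Explained variance is 1 - Var(residual)/Var(fma) on the held-out
    predictions, floored at -1 when the model is worse than the mean.
    """
    fma = fma.loc[features.index].astype(float)
    if len(features) < 5:
        raise ValueError("need at least 5 stroke subjects")
    if fma.nunique() < 2:
        raise ValueError("fma is constant: regression undefined")
    x = features.to_numpy(dtype=float)
    y = fma.to_numpy()
    preds = np.zeros(len(y))
    coefs = []
    for i in range(len(y)):
        tr = np.ones(len(y), dtype=bool)
        tr[i] = False
        scaler = StandardScaler().fit(x[tr])
        reg = ElasticNetCV(
            l1_ratio=list(L1_RATIOS), alphas=30, cv=3,
            max_iter=5000, random_state=seed, n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reg.fit(scaler.transform(x[tr]), y[tr])
        preds[i] = reg.predict(scaler.transform(x[[i]]))[0]
        coefs.append(np.abs(reg.coef_))
    resid = y - preds
    ev = 1.0 - resid.var() / y.var()
    return RegressionReport(
        mae=float(np.mean(np.abs(resid))),
        explained_variance=float(max(ev, -1.0)),
        coefficients=pd.Series(np.mean(coefs, axis=0), index=features.columns),
    )


def pooled_cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Cohen's d with the pooled standard deviation, (group1 - group2)."""
    pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return (mean1 - mean2) / pooled


def group_statistics(features: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-feature group summary: means, SDs, Cohen's d, t-test p-value.

    d is (stroke - control) / pooled SD with sample (n-1) SDs; the p-value
    comes from the matching pooled-variance two-sample t-test, two-sided.
    Rows are sorted by |d| descending.
    """
    groups = groups.loc[features.index]
    a = features.loc[groups == "stroke"]
    b = features.loc[groups == "control"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects (SD undefined)")
    rows = []
    for name in features.columns:
        s, c = a[name].to_numpy(), b[name].to_numpy()
        d = pooled_cohens_d(s.mean(), s.std(ddof=1), len(s),
                            c.mean(), c.std(ddof=1), len(c))
        t = _stats.ttest_ind(s, c, equal_var=True)
        rows.append({
            "feature": name,
            "stroke_mean": s.mean(), "stroke_sd": s.std(ddof=1),
            "control_mean": c.mean(), "control_sd": c.std(ddof=1),
            "cohens_d": d, "p_value": float(t.pvalue),
        })
    table = pd.DataFrame(rows)
    return table.reindex(
        table["cohens_d"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)


def masks_from_predictions(
    window_sets: Sequence[WindowSet],
    predictions: pd.DataFrame,
    rule: str = "majority",
) -> dict[tuple[str, str], np.ndarray]:
    """Per-sample GDM masks for every wrist from held-out window predictions.

    ``predictions`` is the window-level frame produced by the LOSO harness
    (columns subject_id, side, start, pred)."""
    lookup = {
        key: dict(zip(grp["start"], grp["pred"]))
        for key, grp in predictions.groupby(["subject_id", "side"])
    }
    masks = {}
    for w in window_sets:
        by_start = lookup.get((w.subject_id, w.side), {})
        pred = np.array([by_start[s] for s in w.start], dtype=bool)
        masks[(w.subject_id, w.side)] = gdm_sample_mask(
            w.n_samples, w.start, w.data.shape[1] if len(w) else 0, pred, rule=rule
        )
    return masks


@dataclass
class DownstreamReport:
    classification: dict[Source, ClassificationReport]
    regression: dict[Source, RegressionReport]
    group_stats: pd.DataFrame  # for the gdm_periods source

    def to_report(self) -> dict:
        return {
            "classification": {k: v.as_dict() for k, v in self.classification.items()},
            "regression": {k: v.as_dict() for k, v in self.regression.items()},
            "group_stats": self.group_stats.to_dict(orient="records"),
        }


def run_downstream(
    subjects: Sequence[SubjectSpec],
    kinematics: Mapping[tuple[str, str], KinematicsPair],
    window_sets: Sequence[WindowSet],
    predictions: pd.DataFrame,
    seed: int = 0,
    fs: float = 25.0,
    vote_rule: str = "majority",
) -> DownstreamReport:
    """Both-source subject descriptors and the three downstream analyses."""
    masks = masks_from_predictions(window_sets, predictions, rule=vote_rule)
    groups = pd.Series({s.subject_id: s.group for s in subjects})
    fma = pd.Series({s.subject_id: s.fma for s in subjects})
    stroke_ids = [s.subject_id for s in subjects if s.group == "stroke"]
    classification: dict[Source, ClassificationReport] = {}
    regression: dict[Source, RegressionReport] = {}
    gdm_table: pd.DataFrame | None = None
    for source, mask in (("gdm_periods", masks), ("entire_recording", None)):
        table = build_subject_feature_table(subjects, kinematics, mask, fs)
        classification[source] = classify_groups(table, groups, seed=seed)
        stroke_table = table.loc[table.index.intersection(stroke_ids)]
        regression[source] = regress_fma(stroke_table, fma, seed=seed)
        if source == "gdm_periods":
            gdm_table = group_statistics(table, groups)
    assert gdm_table is not None
    return DownstreamReport(
        classification=classification, regression=regression, group_stats=gdm_table
    )
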