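"""Slice-wise ROC / Youden-index classification of HF-map features.

The slice feature (maximum of the b0 HF map) separates fibrotic from
non-fibrotic slices; the decision rule is fixed as "feature >= cutoff =>
positive (fibrosis)". The cutoff is tuned on a patient-wise tuning split by
maximizing the Youden index J = sensitivity + specificity - 1 over all ROC
cutpoints, then evaluated slice-wise on the held-out patients. The whole
protocol is repeated over independent random patient splits and the cutoff,
AUROC and the four performance metrics are averaged.

`YoudenThresholdClassifier` wraps the tuning step as a scikit-learn estimator
so the procedure composes with sklearn pipelines and model selection.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ROCResult",
    "CutoffResult",
    "Metrics",
    "ExperimentParams",
    "roc_curve",
    "youden_cutoff",
    "confusion_metrics",
    "patient_split",
    "repeated_experiment",
    "YoudenThresholdClassifier",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision")


@dataclass
class ROCResult:
    """ROC curve over midpoint cutpoints, ordered from strictest to laxest.

    ``cutpoints`` are the midpoints between consecutive distinct sorted
    feature values plus +/-inf sentinels, in decreasing order, so ``fpr`` and
    ``tpr`` are non-decreasing. ``auroc`` is the trapezoidal area.
    """

    cutpoints: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    youden_j: float


@dataclass(frozen=True)
class Metrics:
    """Confusion-table scores; NaN marks an undefined (zero-denominator) score."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


@dataclass(frozen=True)
class ExperimentParams:
    """Protocol for the repeated patient-wise experiment.

    The split is performed on unique patient ids (all slices of a patient land
    on the same side); the tuning side receives round(tuning_fraction * n)
    patients. Each repeat is reproducible from (seed, repeat index).
    """

    n_repeats: int = 5
    tuning_fraction: float = 2.0 / 3.0
    seed: int = 0
    split_unit: str = "patient"

    def __post_init__(self) -> None:
        if not 0 < self.tuning_fraction < 1:
            raise ValueError("tuning_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.split_unit != "patient":
            raise ValueError("only patient-wise splitting is supported")


def _cutpoints(features: np.ndarray) -> np.ndarray:
    """Candidate cutoffs: midpoints between distinct sorted values, +/-inf sentinels."""
    distinct = np.unique(features)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def roc_curve(features: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Slice-wise ROC of the rule "feature >= cutpoint => positive".

    ``labels`` is boolean (True = positive class). Requires both classes.
    """
    f = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    if f.shape != y.shape or f.ndim != 1:
        raise ValueError("features and labels must be aligned 1D vectors")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC analysis requires both classes")
    cuts = _cutpoints(f)[::-1]  # decreasing: strictest rule first
    tpr = np.array([(f[y] >= c).mean() for c in cuts])
    fpr = np.array([(f[~y] >= c).mean() for c in cuts])
    auroc = float(np.trapezoid(tpr, fpr))
    return ROCResult(cuts, tpr, fpr, float(auroc))


def youden_cutoff(roc: ROCResult) -> CutoffResult:
    """Cutpoint maximizing J = TPR - FPR; ties break toward the LOWEST cutoff.

    At equal J the lowest cutoff maximizes sensitivity.
    """
    j = roc.tpr - roc.fpr
    best = j.max()
    candidates = roc.cutpoints[j >= best - 1e-12]
    return CutoffResult(float(candidates.min()), float(best))


def confusion_metrics(predictions: np.ndarray, labels: np.ndarray) -> Metrics:
    """Accuracy, sensitivity, specificity and precision from aligned boolean vectors.

    Zero-denominator scores are reported as NaN, never silently as 0.
    """
    p = np.asarray(predictions, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if p.shape != y.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("predictions and labels must be aligned non-empty 1D vectors")
    tp = int(np.sum(p & y))
    tn = int(np.sum(~p & ~y))
    fp = int(np.sum(p & ~y))
    fn = int(np.sum(~p & y))

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return Metrics(
        accuracy=(tp + tn) / p.size,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        precision=ratio(tp, tp + fp),
    )


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"patient_id", "slice_id", "feature", "label"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"feature table is missing columns {sorted(missing)}")
    return records


def patient_split(
    records: pd.DataFrame,
    params: ExperimentParams,
    repeat_index: int,
    positive_label: str = "fibrosis",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random patient-wise split into (tuning, testing) slice tables.

    All slices of a patient land on the same side. A draw that leaves either
    class absent from either side is resampled (with a logged notice), so the
    downstream ROC analysis is always well posed.
    """
    records = _validate_records(records)
    patients = np.array(sorted(records["patient_id"].unique()))
    if patients.size < 2:
        raise ValueError("patient-wise splitting requires >= 2 patients")
    n_tuning = int(round(params.tuning_fraction * patients.size))
    n_tuning = min(max(n_tuning, 1), patients.size - 1)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, repeat_index]))
    is_pos = records["label"] == positive_label
    for attempt in range(1000):
        perm = rng.permutation(patients)
        tune_ids = set(perm[:n_tuning])
        on_tune = records["patient_id"].isin(tune_ids)
        tuning, testing = records[on_tune], records[~on_tune]
        if (
            is_pos[on_tune].any()
            and (~is_pos[on_tune]).any()
            and is_pos[~on_tune].any()
            and (~is_pos[~on_tune]).any()
        ):
            if attempt > 0:
                logger.info(
                    "repeat %d: resampled split %d time(s) to keep both classes on both sides",
                    repeat_index,
                    attempt,
                )
            return tuning.copy(), testing.copy()
    raise ValueError("could not draw a patient split with both classes on both sides")


def repeated_experiment(
    records: pd.DataFrame,
    params: ExperimentParams = ExperimentParams(),
    positive_label: str = "fibrosis",
) -> dict:
    """Run the full protocol ``n_repeats`` times and average the outcomes.

    Per repeat: patient-wise split -> ROC on the tuning slices -> Youden
    cutoff -> slice-wise metrics on the testing slices. Returns a dict with a
    per-repeat DataFrame (``"repeats"``) and a ``"summary"`` of mean and SD
    for the cutoff, AUROC and the four metrics. With ``n_repeats == 1`` the
    SDs are reported as 0 by convention and flagged with ``"single_repeat"``.
    """
    records = _validate_records(records)
    rows = []
    for rep in range(params.n_repeats):
        tuning, testing = patient_split(records, params, rep, positive_label)
        roc = roc_curve(
            tuning["feature"].to_numpy(), (tuning["label"] == positive_label).to_numpy()
        )
        cut = youden_cutoff(roc)
        pred = testing["feature"].to_numpy() >= cut.cutoff
        m = confusion_metrics(pred, (testing["label"] == positive_label).to_numpy())
        rows.append(
            {
                "repeat": rep,
                "cutoff": cut.cutoff,
                "youden_j": cut.youden_j,
                "auroc": roc.auroc,
                **m.as_dict(),
            }
        )
    repeats = pd.DataFrame(rows)
    summary: dict[str, float | bool] = {}
    for col in ("cutoff", "auroc", *METRIC_NAMES):
        vals = repeats[col].to_numpy()
        summary[f"{col}_mean"] = float(np.nanmean(vals))
        summary[f"{col}_sd"] = float(np.nanstd(vals, ddof=0)) if len(vals) > 1 else 0.0
    summary["single_repeat"] = params.n_repeats == 1
    return {"repeats": repeats, "summary": summary}


class YoudenThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Single-feature threshold classifier tuned by the Youden index.

    fit(X, y) runs the ROC analysis on the (1-column) feature matrix and
    stores the J-maximizing cutoff; predict applies "feature >= cutoff_".

    Attributes
    ----------
    cutoff_ : float
        The tuned decision threshold.
    youden_j_ : float
        J = sensitivity + specificity - 1 at the cutoff, on the tuning data.
    auroc_ : float
        Trapezoidal AUROC on the tuning data.
    classes_ : ndarray
        The two class labels, negative first.
    """

    def __init__(self, positive_label=1):
        self.positive_label = positive_label

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("expected a single-column feature matrix")
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("YoudenThresholdClassifier is strictly binary")
        if self.positive_label not in classes:
            raise ValueError(f"positive_label {self.positive_label!r} not present in y")
        neg = classes[classes != self.positive_label][0]
        self.classes_ = np.array([neg, self.positive_label])
        pos = y == self.positive_label
        roc = roc_curve(X[:, 0], pos)
        cut = youden_cutoff(roc)
        self.cutoff_ = cut.cutoff
        self.youden_j_ = cut.youden_j
        self.auroc_ = roc.auroc
        self.n_features_in_ = 1
        return self

    def decision_function(self, X):
        check_is_fitted(self, "cutoff_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        return X[:, 0] - self.cutoff_

    def predict(self, X):
        pos = self.decision_function(X) >= 0
        return np.where(pos, self.classes_[1], self.classes_[0])
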