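"""ROC construction, Youden cutoff (vs brute force), metrics, splits and the
repeated patient-wise experiment."""
import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

from hfmap import (
    ExperimentParams,
    YoudenThresholdClassifier,
    confusion_metrics,
    patient_split,
    repeated_experiment,
    roc_curve,
    youden_cutoff,
)


def brute_force_youden(features, labels):
    """Exhaustive J-maximization over all midpoint cutpoints (+/-inf sentinels)."""
    f = np.asarray(features, float)
    y = np.asarray(labels, bool)
    distinct = np.unique(f)
    cuts = np.concatenate(([-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]))
    best_j, best_c = -2.0, None
    for c in cuts:
        j = (f[y] >= c).mean() - (f[~y] >= c).mean()
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and c < best_c):
            best_j, best_c = j, c
    return best_c, best_j


def mann_whitney_auroc(features, labels):
    f = np.asarray(features, float)
    y = np.asarray(labels, bool)
    pos, neg = f[y], f[~y]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (pos.size * neg.size)


def test_roc_known_cases():
    perfect = roc_curve(np.array([1, 2, 3, 5, 6, 7.0]), np.array([0, 0, 0, 1, 1, 1], bool))
    assert perfect.auroc == 1.0
    constant = roc_curve(np.full(6, 2.0), np.array([0, 0, 0, 1, 1, 1], bool))
    assert constant.auroc == 0.5
    interleaved = roc_curve(np.array([1, 3, 2, 4.0]), np.array([0, 0, 1, 1], bool))
    assert interleaved.auroc == 0.75
    with pytest.raises(ValueError):
        roc_curve(np.array([1.0, 2.0]), np.array([True, True]))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_roc_matches_rank_statistics(seed):
    rng = np.random.default_rng(seed)
    f = rng.normal(size=50).round(1)  # rounding forces ties
    y = rng.random(50) < 0.4
    roc = roc_curve(f, y)
    assert roc.auroc == pytest.approx(mann_whitney_auroc(f, y), abs=1e-12)
    assert roc.auroc == pytest.approx(roc_auc_score(y, f), abs=1e-12)
    assert np.all(np.diff(roc.tpr) >= 0) and np.all(np.diff(roc.fpr) >= 0)


def test_youden_known_cases():
    roc = roc_curve(np.array([1, 2, 3, 5, 6, 7.0]), np.array([0, 0, 0, 1, 1, 1], bool))
    cut = youden_cutoff(roc)
    assert cut.cutoff == 4.0 and cut.youden_j == 1.0
    flat = youden_cutoff(roc_curve(np.full(6, 2.0), np.array([0, 0, 0, 1, 1, 1], bool)))
    assert flat.youden_j == 0.0


def test_youden_equals_brute_force_on_random_sets():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(6, 30))
        f = rng.normal(size=n).round(1)
        y = np.zeros(n, bool)
        y[: int(rng.integers(1, n - 1))] = True
        rng.shuffle(y)
        if y.all() or not y.any():
            continue
        cut = youden_cutoff(roc_curve(f, y))
        bc, bj = brute_force_youden(f, y)
        assert cut.youden_j == pytest.approx(bj, abs=1e-12)
        assert cut.cutoff == bc


def test_auroc_invariant_under_monotone_transform():
    rng = np.random.default_rng(17)
    f = rng.normal(size=40)
    y = rng.random(40) < 0.5
    if y.all() or not y.any():
        y[0] = ~y[0]
    a = roc_curve(f, y).auroc
    b = roc_curve(np.exp(f) + 5.0, y).auroc
    assert a == pytest.approx(b, abs=1e-12)


def test_confusion_metrics():
    # TP=8, FN=2, TN=6, FP=4
    y = np.array([True] * 10 + [False] * 10)
    p = np.array([True] * 8 + [False] * 2 + [True] * 4 + [False] * 6)
    m = confusion_metrics(p, y)
    assert m.accuracy == pytest.approx(0.7)
    assert m.sensitivity == pytest.approx(0.8)
    assert m.specificity == pytest.approx(0.6)
    assert m.precision == pytest.approx(8 / 12)
    perfect = confusion_metrics(y, y)
    assert (perfect.accuracy, perfect.sensitivity, perfect.specificity, perfect.precision) == (1, 1, 1, 1)
    none_pos = confusion_metrics(np.zeros(4, bool), np.array([1, 0, 1, 0], bool))
    assert np.isnan(none_pos.precision)  # undefined, reported missing


def synthetic_records(n_pos=10, n_neg=10, slices=2, gap=10.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        pid = f"p{i:02d}"
        for s in range(slices):
            rows.append(
                {
                    "patient_id": pid,
                    "slice_id": f"{pid}_s{s}",
                    "feature": rng.normal(gap if positive else 0.0),
                    "label": "fibrosis" if positive else "non_fibrosis",
                }
            )
    return pd.DataFrame(rows)


def test_patient_split_counts_and_integrity():
    records = synthetic_records(n_pos=9, n_neg=9)  # 18 patients
    params = ExperimentParams(seed=3)
    tune, test = patient_split(records, params, 0)
    assert tune.patient_id.nunique() == 12 and test.patient_id.nunique() == 6
    # determinism from (seed, repeat_index)
    tune2, _ = patient_split(records, params, 0)
    pd.testing.assert_frame_equal(tune, tune2)
    # a patient's slices never straddle the split, across many configurations
    for rep in range(100):
        a, b = patient_split(records, params, rep)
        assert not set(a.slice_id) & set(b.slice_id)
        assert not set(a.patient_id) & set(b.patient_id)
        for side in (a, b):
            assert set(side.label) == {"fibrosis", "non_fibrosis"}


def test_patient_split_resamples_until_both_classes_present():
    records = synthetic_records(n_pos=2, n_neg=6)
    for rep in range(50):
        tune, test = patient_split(records, ExperimentParams(seed=1), rep)
        assert set(tune.label) == set(test.label) == {"fibrosis", "non_fibrosis"}


def test_repeated_experiment_on_separable_records():
    records = synthetic_records()
    out = repeated_experiment(records, ExperimentParams(n_repeats=5, seed=0))
    s = out["summary"]
    assert s["auroc_mean"] == 1.0 and s["auroc_sd"] == 0.0
    for name in ("accuracy", "sensitivity", "specificity", "precision"):
        assert s[f"{name}_mean"] == 1.0
    # determinism: identical seed -> identical output
    again = repeated_experiment(records, ExperimentParams(n_repeats=5, seed=0))
    pd.testing.assert_frame_equal(out["repeats"], again["repeats"])
    # single repeat: SDs are 0 by convention and flagged
    single = repeated_experiment(records, ExperimentParams(n_repeats=1, seed=0))
    assert single["summary"]["single_repeat"] and single["summary"]["cutoff_sd"] == 0.0


def test_youden_threshold_classifier_sklearn_contract():
    x = np.array([[1.0], [2.0], [3.0], [5.0], [6.0], [7.0]])
    y = np.array(["neg", "neg", "neg", "pos", "pos", "pos"])
    clf = YoudenThresholdClassifier(positive_label="pos").fit(x, y)
    assert clf.cutoff_ == 4.0 and clf.youden_j_ == 1.0 and clf.auroc_ == 1.0
    np.testing.assert_array_equal(clf.predict(x), y)
    assert (clf.decision_function(x) >= 0).sum() == 3
    clone(clf)  # get_params/set_params round trip
    assert clf.get_params() == {"positive_label": "pos"}
    with pytest.raises(ValueError):
        YoudenThresholdClassifier().fit(x, np.array(["a", "b", "c", "a", "b", "c"]))
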