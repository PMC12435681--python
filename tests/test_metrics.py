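"""Label groupings and the metric suite, cross-checked against brute-force
oracles written from the defining formulas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import her2light as hl
from her2light.metrics import EXCLUDED, mcc


# ----------------------------------------------------------- brute oracles

def oracle_prf(y_true, y_pred, k):
    """Per-class precision/recall/F1 and their macro means, via raw counts."""
    precs, recs, f1s = [], [], []
    for c in range(k):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precs.append(prec); recs.append(rec); f1s.append(f1)
    return np.mean(precs), np.mean(recs), np.mean(f1s)


def oracle_binary_auc(y_true, scores):
    """Pairwise-comparison AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def oracle_ovr_auc(y_true, probs):
    aucs = []
    for c in range(probs.shape[1]):
        yb = (np.asarray(y_true) == c).astype(int)
        if yb.min() == yb.max():
            return None
        aucs.append(oracle_binary_auc(yb, probs[:, c]))
    return float(np.mean(aucs))


def oracle_mcc(y_true, y_pred):
    """Covariance-of-indicators form, computed sample-wise."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    k = int(max(y_true.max(), y_pred.max())) + 1
    t = np.eye(k)[y_true]
    p = np.eye(k)[y_pred]
    cov = lambda a, b: ((a - a.mean(0)) * (b - b.mean(0))).sum()
    denom = np.sqrt(cov(t, t) * cov(p, p))
    return cov(t, p) / denom if denom else 0.0


# ------------------------------------------------------------ label schemes

def test_three_class_grouping():
    labels, mask = hl.group_labels(["0", "1+", "2+", "3+"], "three_class")
    np.testing.assert_array_equal(labels, [0, 0, 1, 2])
    assert mask.all()


def test_binary_grouping_drops_equivocal():
    labels, mask = hl.group_labels(["0", "1+", "2+", "3+"], "binary")
    np.testing.assert_array_equal(labels, [0, 0, 1])
    np.testing.assert_array_equal(mask, [True, True, False, True])


def test_four_class_grouping_is_identity():
    labels, mask = hl.group_labels(["3+", "0", "2+", "1+"], "four_class")
    np.testing.assert_array_equal(labels, [3, 0, 2, 1])
    assert mask.all()


def test_group_labels_empty_and_errors():
    labels, mask = hl.group_labels([], "binary")
    assert len(labels) == 0 and len(mask) == 0
    with pytest.raises(ValueError, match="unknown HER2 score"):
        hl.group_labels(["4+"], "binary")


def test_excluded_sentinel_never_collides_with_class_indices():
    assert EXCLUDED < 0


# ----------------------------------------------------------------- summary

def test_worked_binary_example():
    # TP=45, FN=5, FP=10, TN=40 (positive class = 1)
    y_true = np.array([1] * 50 + [0] * 50)
    y_pred = np.array([1] * 45 + [0] * 5 + [1] * 10 + [0] * 40)
    probs = np.where(y_pred == 1, 0.9, 0.1)[:, None]
    report = hl.confusion_and_summary(y_true, probs)
    np.testing.assert_array_equal(report.confusion, [[40, 10], [5, 45]])
    assert report.accuracy == pytest.approx(85.0)
    pos = report.per_class[report.per_class["class"] == "1"].iloc[0]
    assert pos["precision"] * 100 == pytest.approx(81.8, abs=0.05)
    assert pos["recall"] * 100 == pytest.approx(90.0)
    assert pos["f1"] * 100 == pytest.approx(85.7, abs=0.05)
    assert report.mcc == pytest.approx(0.7035, abs=5e-5)
    assert mcc(y_true, y_pred) == pytest.approx(
        (45 * 40 - 10 * 5) / np.sqrt(55 * 50 * 45 * 50))


def test_perfect_predictions():
    y = np.array([0, 1, 2, 0, 1, 2])
    probs = np.eye(3)[y]
    report = hl.confusion_and_summary(y, probs)
    assert report.accuracy == 100.0
    assert report.f1 == pytest.approx(100.0)
    assert report.mcc == pytest.approx(1.0)
    assert np.all(np.diag(report.confusion) == 2)


def test_single_prediction_class_gives_zero_mcc():
    assert mcc([0, 1, 0, 1], [1, 1, 1, 1]) == 0.0


def test_mcc_errors():
    with pytest.raises(ValueError):
        mcc([0, 1], [0])
    with pytest.raises(ValueError):
        mcc([], [])


def test_single_class_truth_reports_missing_auc():
    with pytest.warns(UserWarning, match="AUC"):
        report = hl.confusion_and_summary([1, 1, 1], np.array([[0.2], [0.8], [0.9]]))
    assert report.auc is None


def test_chance_level_auc_on_random_probabilities():
    rng = np.random.default_rng(0)
    n = 4000
    y = rng.integers(0, 2, n)
    probs = rng.random((n, 1))
    report = hl.confusion_and_summary(y, probs)
    assert report.auc == pytest.approx(50.0, abs=3.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), k=st.integers(2, 4))
def test_metrics_match_bruteforce_oracles(seed, k):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(12, 50))
    y_true = rng.integers(0, k, n)
    probs = rng.dirichlet(np.ones(k), n) if k > 2 else rng.random((n, 1))
    report = hl.confusion_and_summary(y_true, probs)
    y_pred = probs.argmax(1) if k > 2 else (probs[:, 0] >= 0.5).astype(int)
    prec, rec, f1 = oracle_prf(y_true, y_pred, k)
    assert report.precision / 100 == pytest.approx(prec, abs=1e-12)
    assert report.recall / 100 == pytest.approx(rec, abs=1e-12)
    assert report.f1 / 100 == pytest.approx(f1, abs=1e-12)
    assert report.accuracy / 100 == pytest.approx(np.mean(y_true == y_pred), abs=1e-12)
    assert report.mcc == pytest.approx(oracle_mcc(y_true, y_pred), abs=1e-10)
    expected_auc = (oracle_binary_auc(y_true, probs[:, 0]) if k == 2
                    else oracle_ovr_auc(y_true, probs))
    if expected_auc is not None and report.auc is not None:
        assert report.auc / 100 == pytest.approx(expected_auc, abs=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_permutation_invariance_of_symmetric_metrics(seed):
    rng = np.random.default_rng(seed)
    k = 3
    y_true = rng.integers(0, k, 40)
    y_pred = rng.integers(0, k, 40)
    perm = rng.permutation(k)
    acc = np.mean(y_true == y_pred)
    assert np.mean(perm[y_true] == perm[y_pred]) == pytest.approx(acc)
    assert mcc(perm[y_true], perm[y_pred]) == pytest.approx(
        mcc(y_true, y_pred), abs=1e-12)


def test_mcc_is_one_iff_confusion_is_diagonal():
    y = np.array([0, 1, 2, 2, 1, 0])
    assert mcc(y, y) == pytest.approx(1.0)
    y_pred = y.copy()
    y_pred[0] = 1
    assert mcc(y, y_pred) < 1.0


def test_report_serialization_roundtrip(tmp_path):
    y = np.array([0, 1, 1, 0])
    probs = np.array([[0.1], [0.9], [0.8], [0.4]])
    report = hl.confusion_and_summary(y, probs)
    import json
    data = json.loads(report.to_json(tmp_path / "m.json"))
    assert data["accuracy"] == report.accuracy
    assert (tmp_path / "m.json").exists()
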