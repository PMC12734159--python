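"""Confusion-matrix metrics and ROC/AUC, checked against independent oracles."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from stripfuse.metrics import (
    accuracy,
    compute_report,
    confusion_matrix,
    f1_score,
    precision_recall,
    roc_curve_binary,
    roc_curves,
)

RNG = np.random.default_rng(17)


# ---------------------------------------------------------------------------
# confusion matrix and scalar metrics
# ---------------------------------------------------------------------------


def test_confusion_matrix_perfect_predictions_diagonal():
    y = np.array([0, 1, 2, 2, 1, 0])
    cm = confusion_matrix(y, y, 3)
    assert np.all(cm == np.diag([2, 2, 2]))
    assert accuracy(cm) == 1.0


def test_confusion_matrix_empty_and_invalid():
    cm = confusion_matrix([], [], 3)
    assert cm.sum() == 0
    with pytest.raises(ValueError):
        accuracy(cm)
    with pytest.raises(ValueError):
        confusion_matrix([0, 3], [0, 1], 3)
    with pytest.raises(ValueError):
        confusion_matrix([0, 1], [0], 2)


def test_confusion_matrix_hand_tally():
    y_true = [0, 0, 1, 2, 2, 1]
    y_pred = [0, 1, 1, 2, 0, 1]
    cm = confusion_matrix(y_true, y_pred, 3)
    np.testing.assert_array_equal(cm, [[1, 1, 0], [0, 2, 0], [1, 0, 1]])
    p0, r0 = precision_recall(cm, 0)
    assert p0 == pytest.approx(1 / 2) and r0 == pytest.approx(1 / 2)
    p1, r1 = precision_recall(cm, 1)
    assert p1 == pytest.approx(2 / 3) and r1 == pytest.approx(1.0)
    p2, r2 = precision_recall(cm, 2)
    assert p2 == pytest.approx(1.0) and r2 == pytest.approx(1 / 2)
    assert accuracy(cm) == pytest.approx(4 / 6)


def test_binary_accuracy_formula():
    # TP=3, TN=5, FP=1, FN=1 -> (3+5)/10
    cm = np.array([[5, 1], [1, 3]])  # rows true (neg, pos), cols predicted
    assert accuracy(cm) == pytest.approx(0.8)


def test_accuracy_matches_direct_label_comparison():
    for seed in range(10):
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 4, size=50)
        y_pred = rng.integers(0, 4, size=50)
        cm = confusion_matrix(y_true, y_pred, 4)
        assert accuracy(cm) == pytest.approx((y_true == y_pred).mean())


def test_precision_zero_when_class_never_predicted():
    cm = np.array([[3, 0], [2, 0]])
    p, r = precision_recall(cm, 1)
    assert p == 0.0 and r == 0.0
    assert f1_score(p, r) == 0.0


@pytest.mark.parametrize(
    "precision,recall,expected",
    [
        (0.9330, 0.8889, 0.9104),
        (0.9905, 0.9905, 0.9905),
        (0.9660, 0.9401, 0.9529),
    ],
)
def test_f1_published_identities(precision, recall, expected):
    assert round(f1_score(precision, recall), 4) == expected


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def _mann_whitney_auc(y, s):
    """Brute-force rank-sum oracle: P(score_pos > score_neg) + 0.5 ties."""
    pos = s[np.asarray(y, bool)]
    neg = s[~np.asarray(y, bool)]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def test_perfectly_separating_scores_auc_one():
    y_true = np.array([0, 0, 1, 1, 2, 2, 3, 3])
    scores = np.eye(4)[y_true] * 0.7 + 0.075
    rocs = roc_curves(y_true, scores)
    for c in range(4):
        assert rocs["per_class_auc"][c] == pytest.approx(1.0)
    assert rocs["micro_auc"] == pytest.approx(1.0)


def test_label_independent_scores_auc_half():
    y_true = np.array([0, 1, 2, 3] * 5)
    scores = np.tile([0.25, 0.25, 0.25, 0.25], (20, 1))
    rocs = roc_curves(y_true, scores)
    for c in range(4):
        assert rocs["per_class_auc"][c] == pytest.approx(0.5)
    assert rocs["micro_auc"] == pytest.approx(0.5)


def test_binary_auc_matches_rank_sum_on_hand_listed_pairs():
    y = np.array([1, 0, 1, 1, 0, 0, 1, 0])
    s = np.array([0.9, 0.8, 0.7, 0.6, 0.55, 0.3, 0.2, 0.2])
    _, _, auc = roc_curve_binary(y, s)
    assert auc == pytest.approx(_mann_whitney_auc(y, s))


@pytest.mark.parametrize("seed", range(8))
def test_micro_auc_equals_pooled_rank_sum(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(8, 30)
    y_true = rng.integers(0, 3, size=n)
    scores = rng.random((n, 3))
    scores /= scores.sum(axis=1, keepdims=True)
    rocs = roc_curves(y_true, scores)
    onehot = np.eye(3, dtype=bool)[y_true]
    assert rocs["micro_auc"] == pytest.approx(
        _mann_whitney_auc(onehot.ravel(), scores.ravel())
    )


def test_binary_auc_cross_checked_against_sklearn():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, size=40)
    s = rng.random(40)
    _, _, auc = roc_curve_binary(y.astype(bool), s)
    assert auc == pytest.approx(roc_auc_score(y, s))


def test_roc_points_export(tmp_path):
    from stripfuse.metrics import export_roc_points

    rng = np.random.default_rng(2)
    y = rng.integers(0, 3, size=30)
    scores = rng.random((30, 3))
    rocs = roc_curves(y, scores)
    path = tmp_path / "roc.tsv"
    export_roc_points(rocs, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "curve\tfpr\ttpr"
    assert any(line.startswith("micro\t") for line in lines)
    assert any(line.startswith("class_0\t") for line in lines)


def test_absent_class_auc_reported_missing():
    y_true = np.array([0, 0, 1, 1])
    scores = RNG.random((4, 3))
    rocs = roc_curves(y_true, scores)
    assert rocs["per_class_auc"][2] is None


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


def test_report_macro_conventions_and_serialisation(tmp_path):
    rng = np.random.default_rng(11)
    y_true = rng.integers(0, 3, size=60)
    scores = rng.random((60, 3))
    scores /= scores.sum(axis=1, keepdims=True)
    y_pred = scores.argmax(axis=1)
    report = compute_report(y_true, y_pred, ["a", "b", "c"], scores=scores)
    assert report.macro_precision == pytest.approx(
        np.mean(report.per_class_precision)
    )
    assert report.macro_f1_mean == pytest.approx(np.mean(report.per_class_f1))
    assert report.macro_f1_harmonic == pytest.approx(
        f1_score(report.macro_precision, report.macro_recall)
    )
    for i in range(3):
        assert report.per_class_f1[i] == pytest.approx(
            f1_score(report.per_class_precision[i], report.per_class_recall[i])
        )
    assert report.overall_accuracy == pytest.approx(
        np.trace(report.confusion) / report.confusion.sum()
    )
    path = tmp_path / "report.json"
    report.to_json(path)
    import json

    loaded = json.loads(path.read_text())
    assert loaded["overall_accuracy"] == pytest.approx(report.overall_accuracy)
    assert "micro_auc" in loaded
    assert "a" in report.to_text()
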