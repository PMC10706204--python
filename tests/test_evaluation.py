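"""Metric oracles: confusion arithmetic, Mann-Whitney AUC, pair-count tau-b."""

import numpy as np
import pytest

from cfsgrade.evaluation import (
    ConfusionMatrix,
    confusion_matrix_counts,
    confusion_metrics,
    kendall_tau_b,
    roc_auc,
)

# ---------------------------------------------------------------------------
# oracles


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the normalized count of correctly ordered pairs (ties = 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def pair_count_tau_b(x, y) -> float:
    """O(n^2) concordant/discordant pair counting with tie correction."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


# ---------------------------------------------------------------------------
# confusion metrics


def test_identity_matrix_perfect_scores():
    cm = ConfusionMatrix(np.eye(5, dtype=int) * 10, np.arange(5))
    rep = confusion_metrics(cm)
    assert rep.acc == rep.sen == rep.pre == rep.spe == rep.f_measure == 100


def test_two_class_hand_arithmetic():
    cm = ConfusionMatrix(np.array([[40, 10], [20, 30]]), np.array([0, 1]))
    rep = confusion_metrics(cm)
    assert rep.acc == pytest.approx(70.0)
    assert rep.per_class[0]["SEN"] == pytest.approx(80.0)
    assert rep.per_class[0]["PRE"] == pytest.approx(100 * 40 / 60)
    # macro averages and their harmonic-mean F
    sen = (0.8 + 0.6) / 2
    pre = (40 / 60 + 30 / 40) / 2
    assert rep.sen == pytest.approx(100 * sen)
    assert rep.f_measure == pytest.approx(100 * 2 * pre * sen / (pre + sen))


def test_collapsed_predictions_chance_accuracy():
    counts = np.zeros((5, 5), dtype=int)
    counts[:, 0] = 10  # everything predicted as class 0, balanced truth
    with pytest.warns(UserWarning):
        rep = confusion_metrics(ConfusionMatrix(counts, np.arange(5)))
    assert rep.acc == pytest.approx(20.0)


def test_confusion_marginal_conservation():
    rng = np.random.default_rng(3)
    y_true = rng.integers(0, 4, 200)
    y_pred = rng.integers(0, 4, 200)
    cm = confusion_matrix_counts(y_true, y_pred, np.arange(4))
    assert cm.counts.sum() == 200
    assert np.array_equal(cm.counts.sum(axis=1), np.bincount(y_true, minlength=4))


def test_invalid_confusion_matrices_rejected():
    with pytest.raises(ValueError):
        ConfusionMatrix(np.array([[1, 2, 3]]), np.arange(1))
    with pytest.raises(ValueError):
        ConfusionMatrix(np.array([[1, -2], [0, 3]]), np.arange(2))
    with pytest.raises(ValueError):
        confusion_metrics(ConfusionMatrix(np.zeros((2, 2), int), np.arange(2)))


# ---------------------------------------------------------------------------
# ROC / AUC


def test_perfectly_ordered_scores_auc_one():
    y = np.array([0, 0, 1, 1, 2, 2])
    scores = np.zeros((6, 3))
    for i, c in enumerate(y):
        scores[i, c] = 1.0
    res = roc_auc(scores, y, np.arange(3))
    assert all(v == 100 for v in res["per_class"].values())
    assert res["micro"] == 100


def test_auc_equals_mann_whitney_oracle(rng):
    for _ in range(5):
        n = 40
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        s = np.round(rng.random(n), 2)  # rounding forces ties
        scores = np.column_stack([1 - s, s])
        res = roc_auc(scores, y, np.array([0, 1]))
        assert res["per_class"][1] == pytest.approx(100 * mann_whitney_auc(s, y))


def test_auc_chance_level_for_random_scores(rng):
    n = 4000
    y = rng.integers(0, 2, n)
    s = rng.random(n)
    res = roc_auc(np.column_stack([1 - s, s]), y, np.array([0, 1]))
    assert abs(res["per_class"][1] - 50.0) < 3.0


def test_auc_invariant_under_monotone_transform(rng):
    n = 60
    y = rng.integers(0, 2, n)
    s = rng.random(n)
    a = roc_auc(np.column_stack([1 - s, s]), y, np.array([0, 1]))
    t = np.exp(5 * s)  # strictly monotone
    b = roc_auc(np.column_stack([-t, t]), y, np.array([0, 1]))
    assert a["per_class"][1] == pytest.approx(b["per_class"][1])


def test_auc_absent_class_excluded_with_warning():
    y = np.array([0, 0, 1, 1])
    scores = np.column_stack([np.ones(4), np.zeros(4), np.linspace(0, 1, 4)])
    with pytest.warns(UserWarning):
        res = roc_auc(scores, y, np.arange(3))
    assert 2 not in res["per_class"]


# ---------------------------------------------------------------------------
# Kendall tau-b


def test_tau_b_perfect_orders():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    tau, p = kendall_tau_b(x, x)
    assert tau == pytest.approx(1.0)
    tau, _ = kendall_tau_b(x, -x)
    assert tau == pytest.approx(-1.0)
    assert p < 0.05


def test_tau_b_matches_pair_count_oracle_with_ties():
    x = np.array([1.0, 2.0, 2.0, 3.0])
    y = np.array([1.0, 2.0, 3.0, 3.0])
    tau, _ = kendall_tau_b(x, y)
    assert tau == pytest.approx(pair_count_tau_b(x, y))


def test_tau_b_random_vectors_match_oracle(rng):
    for _ in range(5):
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 30).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        tau, _ = kendall_tau_b(x, y)
        assert tau == pytest.approx(pair_count_tau_b(x, y))


def test_tau_b_symmetry_and_bounds(rng):
    x = rng.normal(size=25)
    y = rng.normal(size=25)
    t1, _ = kendall_tau_b(x, y)
    t2, _ = kendall_tau_b(y, x)
    assert t1 == pytest.approx(t2)
    assert -1 <= t1 <= 1


def test_tau_b_all_tied_is_error():
    with pytest.raises(ValueError):
        kendall_tau_b([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
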