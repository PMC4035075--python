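"""Confusion identities, sweeps, optimal score, ROC/AUC, combination, trend."""

import numpy as np
import pytest

from mirduplex.evaluation import (
    ConfusionCounts,
    EnergyRecord,
    ThresholdCurve,
    combine_predictions,
    confusion_from_predictions,
    energy_length_trend,
    optimal_score,
    precision_recall,
    roc_auc,
    specificity_sensitivity,
    threshold_sweep,
)
from mirduplex.io_formats import Prediction


def P(m, t, score, tool="x"):
    return Prediction(m, t, score, tool=tool)


# --- confusion counting -----------------------------------------------------

def test_confusion_example():
    counts = confusion_from_predictions(
        [P("m1", "t1", 1), P("m3", "t3", 1)],
        [("m1", "t1"), ("m2", "t2")],
    )
    assert (counts.tp, counts.fp, counts.fn) == (1, 1, 1)


def test_confusion_perfect_and_tn():
    counts = confusion_from_predictions(
        [P("m1", "t1", 1)], [("m1", "t1")], negatives=[("n", str(i)) for i in range(5)]
    )
    assert (counts.fp, counts.fn, counts.tn) == (0, 0, 5)


def test_confusion_rejects_overlapping_sets():
    with pytest.raises(ValueError):
        confusion_from_predictions([], [("m", "t")], negatives=[("m", "t")])


def test_precision_recall_examples():
    assert precision_recall(ConfusionCounts(8, 2, 2)) == (0.8, 0.8)
    assert precision_recall(ConfusionCounts(0, 0, 5)) == (1.0, 0.0)
    assert precision_recall(ConfusionCounts(10, 0, 0)) == (1.0, 1.0)


def test_specificity_sensitivity():
    counts = ConfusionCounts(8, 2, 2, tn=18)
    spec, sens = specificity_sensitivity(counts)
    assert spec == 0.9 and sens == 0.8
    with pytest.raises(ValueError):
        specificity_sensitivity(ConfusionCounts(1, 1, 1))


def test_closed_form_identities_on_random_tables(rng):
    for _ in range(100):
        tp, fp, fn, tn = (int(x) for x in rng.integers(0, 50, size=4))
        counts = ConfusionCounts(tp, fp, fn, tn)
        prec, rec = precision_recall(counts)
        spec, sens = specificity_sensitivity(counts)
        assert prec == (tp / (tp + fp) if tp + fp else 1.0)
        assert rec == (tp / (tp + fn) if tp + fn else 1.0)
        assert spec == (tn / (tn + fp) if tn + fp else 1.0)
        assert sens == rec


# --- threshold sweep --------------------------------------------------------

def test_sweep_example():
    preds = [P("m1", "t1", 1), P("m2", "t2", 2), P("m3", "t3", 3)]
    validated = [("m1", "t1"), ("m2", "t2")]
    curve = threshold_sweep(preds, validated)
    assert curve.thresholds == (1, 2, 3)
    i = curve.thresholds.index(2)
    assert (curve.precision[i], curve.recall[i]) == (1.0, 1.0)
    j = curve.thresholds.index(3)
    assert curve.precision[j] == pytest.approx(2 / 3)
    assert curve.recall[j] == 1.0


def test_sweep_single_and_all_false():
    curve = threshold_sweep([P("m", "t", 5)], [("m", "t")])
    assert curve.precision == (1.0,) and curve.recall == (1.0,)
    curve = threshold_sweep([P("m", "t", 5)], [("x", "y")])
    assert all(p == 0.0 for p in curve.precision)


def test_sweep_requires_predictions():
    with pytest.raises(ValueError):
        threshold_sweep([], [("m", "t")])


def test_recall_monotone_and_tp_fn_conserved(rng):
    for _ in range(20):
        n = int(rng.integers(3, 30))
        preds = [P(f"m{i}", f"t{i}", float(rng.integers(0, 10))) for i in range(n)]
        validated = [(f"m{i}", f"t{i}") for i in range(n) if rng.random() < 0.5]
        if not validated:
            validated = [preds[0].pair]
        curve = threshold_sweep(preds, validated)
        assert all(
            b >= a for a, b in zip(curve.recall, curve.recall[1:])
        ), "recall must grow with the call set"
        for t in curve.thresholds:
            called = [p for p in preds if p.score <= t]
            c = confusion_from_predictions(called, validated)
            assert c.tp + c.fn == len(set(validated))


def test_higher_better_orientation():
    preds = [P("m1", "t1", 10), P("m2", "t2", 1)]
    curve = threshold_sweep(preds, [("m1", "t1")], orientation="higher_better")
    # at the highest threshold only the score-10 call remains
    i = curve.thresholds.index(10)
    assert curve.precision[i] == 1.0


# --- optimal score ----------------------------------------------------------

def test_optimal_score_crossing():
    curve = ThresholdCurve((2, 4, 6), (1.0, 0.9, 0.6), (0.5, 0.9, 1.0))
    assert optimal_score(curve) == 4


def test_optimal_score_tie_breaks():
    # P == R everywhere: smallest threshold wins
    curve = ThresholdCurve((1, 2, 3), (0.8, 0.8, 0.8), (0.8, 0.8, 0.8))
    assert optimal_score(curve) == 1
    # equal |P-R|: larger P+R wins
    curve = ThresholdCurve((1, 2), (0.5, 0.9), (0.6, 1.0))
    assert optimal_score(curve) == 2


def test_optimal_score_minimal_gap_when_curves_never_cross(rng):
    for _ in range(50):
        n = int(rng.integers(2, 12))
        thresholds = tuple(sorted(rng.choice(100, size=n, replace=False).tolist()))
        precision = tuple(sorted(rng.random(n).tolist(), reverse=True))
        recall = tuple(sorted((0.5 + 0.5 * rng.random(n)).tolist()))
        curve = ThresholdCurve(thresholds, precision, recall)
        got = optimal_score(curve)
        gaps = [abs(p - r) for p, r in zip(precision, recall)]
        assert gaps[thresholds.index(got)] == min(gaps)


# --- ROC / AUC --------------------------------------------------------------

def concordance_auc(pos, neg, orientation):
    better = (lambda a, b: a < b) if orientation == "lower_better" else (lambda a, b: a > b)
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if better(a, b) else 0.5 if a == b else 0.0
    return total / (len(pos) * len(neg))


def test_auc_extremes():
    _, auc = roc_auc([1, 2], [5, 6])
    assert auc == 1.0
    _, auc = roc_auc([1, 2, 3], [1, 2, 3])
    assert auc == pytest.approx(0.5)


def test_auc_equals_concordance_oracle(rng):
    for orientation in ("lower_better", "higher_better"):
        for _ in range(25):
            pos = rng.integers(0, 10, size=int(rng.integers(1, 50))).tolist()
            neg = rng.integers(0, 10, size=int(rng.integers(1, 50))).tolist()
            _, auc = roc_auc(pos, neg, orientation)
            assert auc == pytest.approx(
                concordance_auc(pos, neg, orientation), abs=1e-12
            )


def test_auc_against_sklearn(rng):
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    pos = rng.normal(2, 1, size=30)
    neg = rng.normal(4, 1, size=40)
    _, auc = roc_auc(pos.tolist(), neg.tolist(), "lower_better")
    labels = [1] * 30 + [0] * 40
    scores = np.concatenate([-pos, -neg])  # sklearn expects higher = positive
    assert auc == pytest.approx(sklearn_metrics.roc_auc_score(labels, scores))


def test_auc_requires_both_sets():
    with pytest.raises(ValueError):
        roc_auc([], [1.0])


# --- combination ------------------------------------------------------------

def test_combination_set_algebra():
    a = [P("m", "x", 1, tool="A"), P("m", "y", 2, tool="A")]
    b = [P("m", "y", 3, tool="B"), P("m", "z", 4, tool="B")]
    union = combine_predictions(a, b, "union")
    inter = combine_predictions(a, b, "intersection")
    assert {p.pair for p in union} == {("m", "x"), ("m", "y"), ("m", "z")}
    assert {p.pair for p in inter} == {("m", "y")}
    # union keeps the better (lower) score, intersection the worse
    assert next(p for p in union if p.pair == ("m", "y")).score == 2
    assert inter[0].score == 3


def test_combination_idempotent():
    a = [P("m", "x", 1), P("m", "y", 2)]
    assert {p.pair for p in combine_predictions(a, a, "union")} == {p.pair for p in a}
    assert {p.pair for p in combine_predictions(a, a, "intersection")} == {
        p.pair for p in a
    }


def test_combination_containment_on_random_benchmarks(rng):
    for _ in range(20):
        universe = [(f"m{i}", f"t{i}") for i in range(30)]
        validated = {p for p in universe if rng.random() < 0.4}
        a = [P(*p, float(rng.random())) for p in universe if rng.random() < 0.5]
        b = [P(*p, float(rng.random())) for p in universe if rng.random() < 0.5]
        if not a or not b:
            continue
        tp = lambda preds: confusion_from_predictions(preds, validated).tp
        fp = lambda preds: confusion_from_predictions(preds, validated).fp
        union = combine_predictions(a, b, "union")
        inter = combine_predictions(a, b, "intersection")
        assert tp(union) >= max(tp(a), tp(b))
        assert fp(inter) <= min(fp(a), fp(b))


# --- energy trend -----------------------------------------------------------

def _records(lengths, dgs):
    return [
        EnergyRecord(f"m{i}", f"t{i}", float(dg), int(L))
        for i, (L, dg) in enumerate(zip(lengths, dgs))
    ]


def test_trend_negative_slope(rng):
    lengths = rng.integers(200, 2000, size=200)
    dgs = -0.05 * lengths + rng.normal(0, 5, size=200)
    result = energy_length_trend(_records(lengths, dgs))
    assert result.rho < -0.5
    assert result.smoothed[0] > result.smoothed[-1]


def test_trend_constant_energy():
    result = energy_length_trend(_records(range(100, 120), [-20.0] * 20))
    assert result.rho == pytest.approx(0.0, abs=1e-9)


def test_trend_strictly_decreasing_is_perfectly_anticorrelated():
    lengths = list(range(100, 160, 3))
    dgs = [-0.1 * L for L in lengths]
    result = energy_length_trend(_records(lengths, dgs))
    assert result.rho == pytest.approx(-1.0)


def test_trend_needs_ten_records():
    with pytest.raises(ValueError):
        energy_length_trend(_records(range(100, 105), [-1.0] * 5))
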