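"""Benchmark evaluation: confusion bookkeeping, threshold sweeps, ROC,
predictor combination, and the free-energy-vs-length trend.

A predicted interaction counts as a true positive when its (mirna_id,
target_id) pair appears in the validated set; matching is site-agnostic
because curated validated sets carry no site coordinates.  Score orientation
is explicit everywhere: penalty-like scores improve downward
(``lower_better``), expectation-like scores upward (``higher_better``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import spearmanr
from statsmodels.nonparametric.smoothers_lowess import lowess

from mirduplex.io_formats import Prediction

Pair = tuple[str, str]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN tallies; TN only when a negative set is supplied."""

    tp: int
    fp: int
    fn: int
    tn: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name}")
        if self.tn is not None and self.tn < 0:
            raise ValueError("negative tn")


@dataclass(frozen=True)
class ThresholdCurve:
    """Precision and recall as functions of the score cutoff.

    ``thresholds`` ascend; at each threshold the call set is every prediction
    with score <= t (``lower_better``) or >= t (``higher_better``).
    """

    thresholds: tuple[float, ...]
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    orientation: str = "lower_better"

    def __post_init__(self) -> None:
        if not (len(self.thresholds) == len(self.precision) == len(self.recall)):
            raise ValueError("curve arrays must have equal length")
        if any(b < a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be ascending")


@dataclass(frozen=True)
class EnergyRecord:
    """Duplex formation energy (kcal/mol, typically negative) and the target
    transcript's length in nt."""

    mirna_id: str
    target_id: str
    delta_g: float
    transcript_length: int

    def __post_init__(self) -> None:
        if self.transcript_length <= 0:
            raise ValueError("transcript_length must be positive")
        if not math.isfinite(self.delta_g):
            raise ValueError("delta_g must be finite")


def _pairs(items: Iterable) -> set[Pair]:
    out = set()
    for it in items:
        out.add(it.pair if hasattr(it, "pair") else (it[0], it[1]))
    return out


def confusion_from_predictions(
    predictions: Iterable,
    validated: Iterable,
    negatives: Iterable | None = None,
) -> ConfusionCounts:
    """Tally TP/FP/FN (and TN when negatives are given) at pair level."""
    pred = _pairs(predictions)
    val = _pairs(validated)
    tn = None
    if negatives is not None:
        neg = _pairs(negatives)
        overlap = val & neg
        if overlap:
            raise ValueError(f"validated and negative sets overlap: {sorted(overlap)[:3]}")
        tn = len(neg - pred)
    return ConfusionCounts(
        tp=len(pred & val),
        fp=len(pred - val),
        fn=len(val - pred),
        tn=tn,
    )


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    """precision = TP/(TP+FP), recall = TP/(TP+FN).

    An empty call set has vacuous precision 1.0; recall is 1.0 when there is
    nothing to recall.
    """
    precision = 1.0 if counts.tp + counts.fp == 0 else counts.tp / (counts.tp + counts.fp)
    recall = 1.0 if counts.tp + counts.fn == 0 else counts.tp / (counts.tp + counts.fn)
    return precision, recall


def specificity_sensitivity(counts: ConfusionCounts) -> tuple[float, float]:
    """specificity = TN/(TN+FP); sensitivity = TP/(TP+FN)."""
    if counts.tn is None:
        raise ValueError("specificity requires a TN count")
    specificity = 1.0 if counts.tn + counts.fp == 0 else counts.tn / (counts.tn + counts.fp)
    _, sensitivity = precision_recall(counts)
    return specificity, sensitivity


def _called(predictions: Sequence[Prediction], t: float, orientation: str):
    if orientation == "lower_better":
        return [p for p in predictions if p.score <= t]
    return [p for p in predictions if p.score >= t]


def threshold_sweep(
    predictions: Sequence[Prediction],
    validated: Iterable,
    negatives: Iterable | None = None,
    orientation: str = "lower_better",
) -> ThresholdCurve:
    """Precision/recall at every distinct prediction score.

    The threshold grid is the predictor's native set of unique scores, sorted
    ascending.  Recall is monotone along the sweep in the direction that
    grows the call set.
    """
    if not predictions:
        raise ValueError("threshold_sweep requires at least one prediction")
    validated = _pairs(validated)
    grid = sorted({p.score for p in predictions})
    precisions, recalls = [], []
    for t in grid:
        counts = confusion_from_predictions(_called(predictions, t, orientation), validated, negatives)
        p, r = precision_recall(counts)
        precisions.append(p)
        recalls.append(r)
    return ThresholdCurve(tuple(grid), tuple(precisions), tuple(recalls), orientation)


def optimal_score(curve: ThresholdCurve) -> float:
    """The cutoff where precision and recall intersect.

    On the discrete grid this is the threshold minimizing |precision −
    recall|; ties go to the larger precision + recall, then to the smaller
    threshold.
    """
    if not curve.thresholds:
        raise ValueError("empty curve")
    best = min(
        range(len(curve.thresholds)),
        key=lambda i: (
            abs(curve.precision[i] - curve.recall[i]),
            -(curve.precision[i] + curve.recall[i]),
            curve.thresholds[i],
        ),
    )
    return curve.thresholds[best]


def roc_auc(
    positive_scores: Sequence[float],
    negative_scores: Sequence[float],
    orientation: str = "lower_better",
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) over all score thresholds and the trapezoid AUC.

    The AUC equals the probability that a random positive scores better than
    a random negative, ties counted one half.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    grid = np.unique(np.concatenate([pos, neg]))
    points = [(0.0, 0.0)]
    thresholds = grid if orientation == "lower_better" else grid[::-1]
    for t in thresholds:
        if orientation == "lower_better":
            tpr = float((pos <= t).mean())
            fpr = float((neg <= t).mean())
        else:
            tpr = float((pos >= t).mean())
            fpr = float((neg >= t).mean())
        points.append((fpr, tpr))
    points.append((1.0, 1.0))
    xs, ys = zip(*points)
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def combine_predictions(
    set_a: Iterable[Prediction],
    set_b: Iterable[Prediction],
    mode: str,
    orientation: str = "lower_better",
    tool: str | None = None,
) -> list[Prediction]:
    """Union or intersection of two predictors' call sets at pair level.

    The retained score is the better of the two for a union and the worse for
    an intersection (orientation-aware); site coordinates come from the
    prediction whose score is retained.
    """
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")
    better = min if orientation == "lower_better" else max
    worse = max if orientation == "lower_better" else min
    keep = better if mode == "union" else worse

    by_pair_a = {p.pair: p for p in set_a}
    by_pair_b = {p.pair: p for p in set_b}
    if mode == "union":
        pairs = sorted(set(by_pair_a) | set(by_pair_b))
    else:
        pairs = sorted(set(by_pair_a) & set(by_pair_b))

    out = []
    for pair in pairs:
        a, b = by_pair_a.get(pair), by_pair_b.get(pair)
        chosen = a if b is None else b if a is None else keep(a, b, key=lambda p: p.score)
        label = tool if tool is not None else f"{chosen.tool}|{mode}"
        out.append(
            Prediction(
                mirna_id=pair[0],
                target_id=pair[1],
                score=chosen.score,
                site_start=chosen.site_start,
                site_end=chosen.site_end,
                tool=label,
            )
        )
    return out


@dataclass(frozen=True)
class TrendResult:
    """Locally weighted ΔG-vs-length fit plus the Spearman rank correlation."""

    lengths: tuple[float, ...]
    smoothed: tuple[float, ...]
    rho: float
    pvalue: float


def energy_length_trend(records: Sequence, frac: float = 0.5) -> TrendResult:
    """Smoothed trend of duplex free energy against transcript length.

    Fits a lowess curve of ΔG on length (span ``frac``) and reports the
    Spearman rank correlation.  A negative rho means longer transcripts
    reach lower (more favourable) energies.
    """
    records = list(records)
    if len(records) < 10:
        raise ValueError("energy_length_trend requires at least 10 records")
    lengths = np.array([r.transcript_length for r in records], dtype=float)
    dg = np.array([r.delta_g for r in records], dtype=float)
    fitted = lowess(dg, lengths, frac=frac, return_sorted=True)
    if np.ptp(dg) == 0 or np.ptp(lengths) == 0:
        rho, pvalue = 0.0, 1.0
    else:
        rho, pvalue = spearmanr(lengths, dg)
    return TrendResult(
        lengths=tuple(fitted[:, 0]),
        smoothed=tuple(fitted[:, 1]),
        rho=float(rho),
        pvalue=float(pvalue),
    )
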