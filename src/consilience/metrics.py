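"""Confusion-matrix metrics, ROC curves and rank-based AUC.

The validation harness used throughout this package scores a binary
"positive prediction" set against a truth set of known-true and known-false
items and summarises it with three percentages:

* ACC — fraction of all items classified correctly, ``100·(TP+TN)/total``;
* PPV — fraction of positive calls that are true, ``100·TP/(TP+FP)``;
* FPR — fraction of known-false items called positive, ``100·FP/(FP+TN)``.

PPV is undefined when a strategy makes no positive call at all (TP+FP = 0)
and FPR is undefined when the truth set contains no negatives; undefined
values are carried as ``None`` and serialised as ``NA``/``null`` rather than
being coerced to 0 or 100, so the remaining metrics stay reportable.

Ranked screens are summarised by the rank AUC: the probability that a
randomly chosen active is ranked better than a randomly chosen decoy, with
ties credited 1/2 (the Mann–Whitney convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricTriple",
    "RocCurve",
    "StrategyReport",
    "TruthSet",
    "confusion_from_sets",
    "compute_metrics",
    "auc_rank",
    "roc_curve",
    "compare_strategies",
]


@dataclass(frozen=True)
class TruthSet:
    """Disjoint sets of known-true and known-false items.

    Items may be any hashable identifier: (miRNA, gene) pairs for
    interaction validation, compound ids for screening validation.
    ``provenance`` optionally records where each labelled item came from.
    """

    true_set: frozenset
    false_set: frozenset
    provenance: Optional[dict] = None

    def __post_init__(self):
        object.__setattr__(self, "true_set", frozenset(self.true_set))
        object.__setattr__(self, "false_set", frozenset(self.false_set))
        overlap = self.true_set & self.false_set
        if overlap:
            raise ValueError(
                f"truth sets overlap on {len(overlap)} item(s), e.g. "
                f"{sorted(map(str, overlap))[:3]}"
            )

    @property
    def universe(self) -> frozenset:
        return self.true_set | self.false_set


@dataclass(frozen=True)
class ConfusionCounts:
    """The four counts of a binary confusion matrix."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def positives(self) -> int:
        """Number of positive predictions made (TP+FP)."""
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricTriple:
    """ACC / PPV / FPR in percent; undefined values carried as None."""

    acc: float
    ppv: Optional[float]
    fpr: Optional[float]

    def __post_init__(self):
        for name in ("acc", "ppv", "fpr"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} out of [0, 100]: {v}")


@dataclass(frozen=True)
class RocCurve:
    """Stepwise ROC curve: ordered (FPR, TPR) points and trapezoidal area."""

    points: tuple
    auc: float


@dataclass(frozen=True)
class StrategyReport:
    """A labelled strategy's confusion counts and metrics on one truth set."""

    strategy: str
    counts: ConfusionCounts
    metrics: MetricTriple

    @property
    def positives(self) -> int:
        return self.counts.positives


def confusion_from_sets(predicted_positive: Iterable, truth: TruthSet) -> ConfusionCounts:
    """Count TP/FP/TN/FN for a positive-prediction set against a truth set.

    Items that appear in the intersection-style prediction and in the
    known-true set are TP; known-true items missed are FN; known-false items
    predicted are FP; known-false items correctly excluded are TN.  Predicted
    items outside the truth universe are dropped with a logged warning —
    evaluation is restricted to the labelled test set.
    """
    universe = truth.universe
    if not universe:
        raise ValueError("truth universe is empty")
    pred = set(predicted_positive)
    outside = pred - universe
    if outside:
        logger.warning(
            "%d predicted item(s) outside the truth universe dropped from evaluation",
            len(outside),
        )
        pred &= universe
    tp = len(pred & truth.true_set)
    fp = len(pred & truth.false_set)
    fn = len(truth.true_set) - tp
    tn = len(truth.false_set) - fp
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def compute_metrics(c: ConfusionCounts) -> MetricTriple:
    """Evaluate ACC, PPV and FPR (percent) from confusion counts.

    PPV is None when no positive call was made (TP+FP = 0); FPR is None when
    there are no known-false items (FP+TN = 0).
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    acc = 100.0 * (c.tp + c.tn) / c.total
    ppv = 100.0 * c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    fpr = 100.0 * c.fp / (c.fp + c.tn) if (c.fp + c.tn) > 0 else None
    return MetricTriple(acc=acc, ppv=ppv, fpr=fpr)


def _oriented(scores: Sequence[float], better: str) -> np.ndarray:
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("score list is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("scores must be finite numbers")
    if better == "lower":
        return -arr
    if better == "higher":
        return arr
    raise ValueError(f"better must be 'lower' or 'higher', got {better!r}")


def auc_rank(
    active_scores: Sequence[float],
    decoy_scores: Sequence[float],
    better: str = "lower",
) -> float:
    """Rank-based AUC: 1 minus the mean fraction of decoys outranking each active.

    Equivalent to the Mann–Whitney probability that a random active is
    ranked better than a random decoy, with tied scores contributing 1/2.
    ``better`` states the score direction ("lower" for docking energies).
    """
    act = _oriented(active_scores, better)
    dec = _oriented(decoy_scores, better)
    n_a, n_d = act.size, dec.size
    ranks = rankdata(np.concatenate([act, dec]))  # average ranks on ties
    r_act = ranks[:n_a].sum()
    # Sum over actives of (decoys worse than it + half ties) = R_act - n_a(n_a+1)/2
    return float((r_act - n_a * (n_a + 1) / 2.0) / (n_a * n_d))


def roc_curve(
    active_scores: Sequence[float],
    decoy_scores: Sequence[float],
    better: str = "lower",
) -> RocCurve:
    """Full ROC curve over all score thresholds, with trapezoidal area.

    The trapezoidal area equals :func:`auc_rank` (tie segments become
    diagonal steps that integrate to the half-credit convention).
    """
    act = _oriented(active_scores, better)
    dec = _oriented(decoy_scores, better)
    y = np.concatenate([np.ones_like(act), np.zeros_like(dec)])
    s = np.concatenate([act, dec])
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    if fpr[0] != 0.0 or tpr[0] != 0.0:  # pragma: no cover - sklearn guarantees this
        fpr = np.insert(fpr, 0, 0.0)
        tpr = np.insert(tpr, 0, 0.0)
    area = float(np.trapezoid(tpr, fpr))
    points = tuple((float(x), float(t)) for x, t in zip(fpr, tpr))
    return RocCurve(points=points, auc=area)


def _check_same_truth(reports: Sequence[StrategyReport]) -> None:
    n_true = {r.counts.tp + r.counts.fn for r in reports}
    n_false = {r.counts.fp + r.counts.tn for r in reports}
    if len(n_true) != 1 or len(n_false) != 1:
        raise ValueError("strategy reports come from mixed truth universes")


def compare_strategies(reports: Sequence[StrategyReport]) -> pd.DataFrame:
    """Tabulate strategies sorted by ACC (descending), flagging the winners.

    Flags the strategy with the highest ACC, the highest defined PPV and the
    lowest defined FPR; undefined metrics sort last and are never flagged.
    """
    if len(reports) < 2:
        raise ValueError("need at least two strategy reports to compare")
    _check_same_truth(reports)
    rows = []
    for r in reports:
        rows.append(
            {
                "strategy": r.strategy,
                "tp": r.counts.tp,
                "fp": r.counts.fp,
                "tn": r.counts.tn,
                "fn": r.counts.fn,
                "acc": r.metrics.acc,
                "ppv": r.metrics.ppv,
                "fpr": r.metrics.fpr,
                "positives": r.positives,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values("acc", ascending=False, kind="mergesort").reset_index(drop=True)
    df["best_acc"] = df["acc"] == df["acc"].max()
    defined_ppv = df["ppv"].dropna()
    df["best_ppv"] = False
    if not defined_ppv.empty:
        df.loc[df["ppv"] == defined_ppv.max(), "best_ppv"] = True
    defined_fpr = df["fpr"].dropna()
    df["best_fpr"] = False
    if not defined_fpr.empty:
        df.loc[df["fpr"] == defined_fpr.min(), "best_fpr"] = True
    return df
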