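"""Evaluation harness: accuracy, repeated stratified k-fold CV, McNemar.

FALL is the positive class throughout — a true positive is a correctly
detected fall, the clinically actionable event.

The cross-validation protocol mirrors the reference evaluation: stratified
10-fold splits (each class partitioned separately, so every test fold keeps
the class proportions), repeated for 100 independently shuffled iterations,
with the classifier refitted on every training fold.  Accuracy is

    a = (sp + sn) / (sp + qp + sn + qn),

the fraction of correctly classified incidents, aggregated as the grand
mean over folds and iterations.

Paired model comparison uses McNemar's test on the discordant predictions:
exact two-sided binomial when b + c < 25, chi-square with continuity
correction ((|b - c| - 1)^2 / (b + c)) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, clone

from .incidents import BEND, FALL, Incident

__all__ = [
    "ConfusionCounts",
    "CVResult",
    "McNemarResult",
    "accuracy",
    "confusion_counts",
    "stratified_kfold",
    "cross_validate",
    "mcnemar_test",
    "EXACT_SWITCH",
]

#: Discordant-pair count below which McNemar's test uses the exact binomial.
EXACT_SWITCH = 25


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with FALL as the positive class.

    sp: true positives, sn: true negatives, qp: false positives,
    qn: false negatives.
    """

    sp: int
    sn: int
    qp: int
    qn: int

    def __post_init__(self) -> None:
        if min(self.sp, self.sn, self.qp, self.qn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.sp + self.sn + self.qp + self.qn


def confusion_counts(
    truth: Sequence[str], predicted: Sequence[str]
) -> ConfusionCounts:
    """Tally confusion counts from aligned truth/prediction sequences."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predictions must have equal length")
    sp = sn = qp = qn = 0
    for t, p in zip(truth, predicted):
        if t == FALL:
            if p == FALL:
                sp += 1
            else:
                qn += 1
        elif t == BEND:
            if p == BEND:
                sn += 1
            else:
                qp += 1
        else:
            raise ValueError(f"unknown label {t!r}")
    return ConfusionCounts(sp=sp, sn=sn, qp=qp, qn=qn)


def accuracy(counts: ConfusionCounts) -> float:
    """Classification accuracy a = (sp + sn) / (sp + qp + sn + qn)."""
    if counts.total == 0:
        raise ValueError("accuracy undefined with no evaluated incidents")
    return (counts.sp + counts.sn) / counts.total


def stratified_kfold(
    labels: Sequence[str], k: int, rng: np.random.Generator
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold index splits over a labeled sequence.

    Each class is shuffled and partitioned separately into k folds of size
    floor(n/k), the remainder spread round-robin over the first folds, so
    every test fold keeps the class balance and the union of test folds
    covers the data exactly once.

    Returns a list of (train_indices, test_indices) pairs.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2 (no held-out data otherwise)")
    classes = np.unique(labels)
    fold_members: List[List[np.ndarray]] = [[] for _ in range(k)]
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls!r} has {len(idx)} members, fewer than k={k}"
            )
        idx = rng.permutation(idx)
        for fold in range(k):
            fold_members[fold].append(idx[fold::k])
    all_idx = np.arange(len(labels))
    splits = []
    for fold in range(k):
        test = np.sort(np.concatenate(fold_members[fold]))
        train = np.setdiff1d(all_idx, test)
        splits.append((train, test))
    return splits


@dataclass(frozen=True)
class CVResult:
    """Repeated stratified k-fold cross-validation outcome.

    ``fold_accuracies`` has shape (iterations, k); ``predictions`` (when
    collected) holds one out-of-fold predicted label per incident per
    iteration, aligned with the id-sorted incident order in ``incident_ids``.
    """

    fold_accuracies: np.ndarray
    k: int
    iterations: int
    seed: int
    incident_ids: Tuple[str, ...]
    predictions: Optional[np.ndarray] = None

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.fold_accuracies.std(ddof=1))


def cross_validate(
    incidents: Sequence[Incident],
    estimator: BaseEstimator,
    k: int = 10,
    iterations: int = 100,
    seed: int = 0,
    collect_predictions: bool = False,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of a classifier.

    The estimator is cloned and refitted on every training fold and scored
    with :func:`accuracy` on the held-out fold; each iteration reshuffles
    the folds.  Incidents are sorted by id before the seeded shuffles, so
    the result is invariant to the input ordering.  Deterministic given
    ``seed``.
    """
    order = np.argsort([inc.id for inc in incidents])
    incidents = [incidents[i] for i in order]
    labels = np.array([inc.label for inc in incidents])
    if any(lab is None for lab in labels):
        raise ValueError("cross-validation requires labeled incidents")
    rng = np.random.default_rng(seed)
    accs = np.empty((iterations, k))
    preds = (
        np.empty((iterations, len(incidents)), dtype=object)
        if collect_predictions
        else None
    )
    for it in range(iterations):
        for fold, (train, test) in enumerate(stratified_kfold(labels, k, rng)):
            model = clone(estimator)
            model.fit([incidents[i] for i in train], labels[train])
            predicted = model.predict([incidents[i] for i in test])
            accs[it, fold] = accuracy(confusion_counts(labels[test], predicted))
            if preds is not None:
                preds[it, test] = predicted
    return CVResult(
        fold_accuracies=accs,
        k=k,
        iterations=iterations,
        seed=seed,
        incident_ids=tuple(inc.id for inc in incidents),
        predictions=preds,
    )


@dataclass(frozen=True)
class McNemarResult:
    """McNemar's paired test on two classifiers' discordant predictions.

    b: incidents model A got wrong and model B right;
    c: incidents model A got right and model B wrong.
    ``method`` is "exact" (binomial), "chi2-continuity" or "degenerate"
    (no discordant pairs).
    """

    b: int
    c: int
    statistic: float
    p_value: float
    method: str


def mcnemar_test(
    truth: Sequence[str],
    predictions_a: Sequence[str],
    predictions_b: Sequence[str],
) -> McNemarResult:
    """McNemar's test for paired classifier predictions on shared incidents.

    Uses the exact two-sided binomial test when b + c < ``EXACT_SWITCH``
    and the continuity-corrected chi-square approximation otherwise.  With
    no discordant pairs the test is degenerate and p = 1.
    """
    if not (len(truth) == len(predictions_a) == len(predictions_b)):
        raise ValueError("all three sequences must have equal length")
    b = c = 0
    for t, pa, pb in zip(truth, predictions_a, predictions_b):
        a_right, b_right = pa == t, pb == t
        if not a_right and b_right:
            b += 1
        elif a_right and not b_right:
            c += 1
    n = b + c
    if n == 0:
        return McNemarResult(b=0, c=0, statistic=0.0, p_value=1.0, method="degenerate")
    if n < EXACT_SWITCH:
        p = float(stats.binomtest(b, n, 0.5).pvalue)
        return McNemarResult(b=b, c=c, statistic=float(min(b, c)), p_value=p,
                             method="exact")
    statistic = (abs(b - c) - 1) ** 2 / n
    p = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(b=b, c=c, statistic=float(statistic), p_value=p,
                         method="chi2-continuity")
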