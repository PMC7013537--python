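"""The two temporal inference models, CM-I and CM-II.

Both decide whether a recorded descent incident is a FALL or a BEND
(lean-over) from its height-time trajectory alone.

**CM-I** (:class:`TotalTimeThresholdClassifier`) is static: it fits a
normal duration model per class and thresholds an incident's total descent
time t_I at the midpoint of the class means,

    r = (mu_F + mu_B) / 2,

predicting FALL iff t_I < r.  Nothing is known before floor contact.

**CM-II** (:class:`CheckpointVoteClassifier`) is incremental: it lays a
grid of K height checkpoints from the start height down to the floor and
learns per-class reference crossing-time vectors t_F and t_B (element-wise
means over the training incidents).  At each checkpoint j the incident's
crossing time t_Ij casts a vote for the nearer reference,

    vote_j = FALL  iff  |t_Ij - t_Fj| < |t_Ij - t_Bj|,

and the majority at floor contact decides.  Because a fall starts at rest
and accelerates while a lean-over starts fast and decelerates, the two
reference vectors differ in shape, not just in length — which is what lets
CM-II separate classes whose total durations overlap.

Ties resolve to BEND at both decision points (the per-checkpoint vote and
the final majority): the safe default is to treat an ambiguous incident as
routine movement pending more evidence.

Both classifiers are scikit-learn estimators taking a sequence of
:class:`~fallverify.incidents.Incident` objects as X; module-level
``fit_cm1`` / ``classify_cm1`` / ``fit_cm2`` / ``classify_cm2`` /
``classify_cm2_stream`` are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .incidents import (
    BEND,
    FALL,
    H_FLOOR_TOL,
    CheckpointProfile,
    Incident,
    IncidentError,
    NormalTimeModel,
    checkpoint_grid,
    checkpoint_times,
    total_time,
)

__all__ = [
    "midpoint_criterion",
    "TotalTimeThresholdClassifier",
    "CheckpointVoteClassifier",
    "VoteTrace",
    "StreamVoter",
    "fit_cm1",
    "classify_cm1",
    "fit_cm2",
    "classify_cm2",
    "classify_cm2_stream",
]


def midpoint_criterion(mu_fall: float, mu_bend: float) -> float:
    """CM-I's classification criterion r: the midpoint of the class means."""
    return (mu_fall + mu_bend) / 2.0


def _split_by_label(
    incidents: Sequence[Incident], y: Optional[Sequence[str]]
) -> Tuple[List[Incident], List[Incident]]:
    if y is None:
        y = [inc.label for inc in incidents]
    falls, bends = [], []
    for inc, label in zip(incidents, y):
        if label == FALL:
            falls.append(inc)
        elif label == BEND:
            bends.append(inc)
        else:
            raise ValueError(f"incident {inc.id!r}: unlabeled or unknown label {label!r}")
    for name, group in ((FALL, falls), (BEND, bends)):
        if len(group) < 2:
            raise ValueError(f"need at least 2 training incidents of class {name}")
    return falls, bends


class TotalTimeThresholdClassifier(ClassifierMixin, BaseEstimator):
    """CM-I: threshold the total descent time at the class-mean midpoint r.

    Parameters
    ----------
    fall_model, bend_model : NormalTimeModel, optional
        Pre-specified duration models.  When given, ``fit`` validates and
        adopts them instead of estimating from data (the published PDFs can
        be plugged in directly); when given, ``fall_model.mu`` must be
        smaller than ``bend_model.mu``.

    Attributes
    ----------
    fall_model_, bend_model_ : NormalTimeModel
        Fitted (or adopted) class duration models.
    r_ : float
        Decision threshold in seconds; FALL iff total time < ``r_``.
    """

    def __init__(
        self,
        fall_model: Optional[NormalTimeModel] = None,
        bend_model: Optional[NormalTimeModel] = None,
    ):
        self.fall_model = fall_model
        self.bend_model = bend_model

    def fit(self, X: Sequence[Incident], y: Optional[Sequence[str]] = None):
        if (self.fall_model is None) != (self.bend_model is None):
            raise ValueError("provide both fall_model and bend_model, or neither")
        if self.fall_model is not None:
            if self.fall_model.mu >= self.bend_model.mu:
                raise ValueError("fall_model.mu must be < bend_model.mu")
            self.fall_model_ = self.fall_model
            self.bend_model_ = self.bend_model
        else:
            falls, bends = _split_by_label(X, y)
            self.fall_model_ = self._fit_class(falls)
            self.bend_model_ = self._fit_class(bends)
        self.r_ = midpoint_criterion(self.fall_model_.mu, self.bend_model_.mu)
        self.classes_ = np.array([BEND, FALL])
        return self

    @staticmethod
    def _fit_class(incidents: Sequence[Incident]) -> NormalTimeModel:
        totals = np.array([total_time(inc) for inc in incidents])
        mu = float(np.mean(totals))
        sigma = float(np.std(totals, ddof=1))
        sigma = max(sigma, 1e-9)  # degenerate identical-duration folds
        lo = min(float(totals.min()), mu - 3 * sigma)
        hi = max(float(totals.max()), mu + 3 * sigma)
        return NormalTimeModel(mu=mu, sigma=sigma, lo=lo, hi=hi, n_obs=len(totals))

    def predict(self, X: Sequence[Incident]) -> np.ndarray:
        self._check_fitted()
        return np.array([FALL if total_time(inc) < self.r_ else BEND for inc in X])

    def _check_fitted(self) -> None:
        if not hasattr(self, "r_"):
            raise AttributeError("classifier is not fitted")


@dataclass(frozen=True)
class VoteRecord:
    """One checkpoint's vote: distances to both references and the winner."""

    j: int
    height: float
    t_incident: float
    d_fall: float
    d_bend: float
    vote: str


@dataclass
class VoteTrace:
    """Running state of CM-II's per-checkpoint majority vote.

    ``decision`` is ``None`` until the floor checkpoint has been evaluated
    (no verdict is issued before floor contact), then FALL iff
    ``fall_count > bend_count`` — a tied vote resolves to BEND.
    """

    records: List[VoteRecord] = field(default_factory=list)
    fall_count: int = 0
    bend_count: int = 0
    decision: Optional[str] = None

    @property
    def n_evaluated(self) -> int:
        return len(self.records)

    def _add(self, record: VoteRecord) -> None:
        self.records.append(record)
        if record.vote == FALL:
            self.fall_count += 1
        else:
            self.bend_count += 1

    def _decide(self) -> None:
        self.decision = FALL if self.fall_count > self.bend_count else BEND


def _vote(t_i: float, t_f: float, t_b: float) -> Tuple[float, float, str]:
    d_fall = abs(t_i - t_f)
    d_bend = abs(t_i - t_b)
    return d_fall, d_bend, (FALL if d_fall < d_bend else BEND)


class CheckpointVoteClassifier(ClassifierMixin, BaseEstimator):
    """CM-II: per-height-checkpoint nearest-reference voting.

    Parameters
    ----------
    n_checkpoints : int, default 20
        Number K of equally spaced height checkpoints from the training
        start height down to 0.  An odd final majority is not guaranteed;
        with the default even K a tied vote resolves to BEND.

    Attributes
    ----------
    checkpoints_ : ndarray of shape (K,)
        Decreasing height grid with spacing h0/K, ending at 0.  The start
        height itself is not a checkpoint: every trajectory crosses it at
        t = 0 with zero distance to both references, which would cast one
        guaranteed tie (= BEND) vote per incident and bias the majority.
    t_fall_ref_, t_bend_ref_ : ndarray of shape (K,)
        Per-class element-wise mean crossing times over the training set.
    """

    def __init__(self, n_checkpoints: int = 20):
        self.n_checkpoints = n_checkpoints

    def fit(self, X: Sequence[Incident], y: Optional[Sequence[str]] = None):
        if self.n_checkpoints < 2:
            raise ValueError("n_checkpoints must be >= 2")
        falls, bends = _split_by_label(X, y)
        h0 = float(np.median([inc.h0 for inc in falls + bends]))
        self.checkpoints_ = np.linspace(h0, 0.0, self.n_checkpoints + 1)[1:]
        self.t_fall_ref_ = self._mean_profile(falls)
        self.t_bend_ref_ = self._mean_profile(bends)
        self.classes_ = np.array([BEND, FALL])
        return self

    def _mean_profile(self, incidents: Sequence[Incident]) -> np.ndarray:
        rows = np.stack(
            [checkpoint_times(inc, np.minimum(self.checkpoints_, inc.h0)).times
             for inc in incidents]
        )
        return rows.mean(axis=0)

    def predict(self, X: Sequence[Incident]) -> np.ndarray:
        return np.array([trace.decision for trace in self.predict_trace(X)])

    def predict_trace(self, X: Sequence[Incident]) -> List[VoteTrace]:
        """Classify each incident, returning the full per-checkpoint trace."""
        self._check_fitted()
        return [self._classify_one(inc) for inc in X]

    def _classify_one(self, incident: Incident) -> VoteTrace:
        grid = np.minimum(self.checkpoints_, incident.h0)
        profile = checkpoint_times(incident, grid)
        trace = VoteTrace()
        for j, (c, t_i) in enumerate(zip(self.checkpoints_, profile.times)):
            d_fall, d_bend, vote = _vote(
                t_i, self.t_fall_ref_[j], self.t_bend_ref_[j]
            )
            trace._add(VoteRecord(j, float(c), float(t_i), d_fall, d_bend, vote))
        trace._decide()
        return trace

    def stream(self) -> "StreamVoter":
        """A fresh incremental voter bound to this fitted model."""
        self._check_fitted()
        return StreamVoter(self)

    def _check_fitted(self) -> None:
        if not hasattr(self, "checkpoints_"):
            raise AttributeError("classifier is not fitted")


class StreamVoter:
    """Incremental CM-II evaluation over a live (t, h) sample stream.

    Feed samples in time order with :meth:`update`; each call returns the
    current :class:`VoteTrace`, whose votes grow as checkpoints are crossed
    and whose ``decision`` is set the moment the floor is reached.  The
    final state is identical to the batch classifier on the assembled
    incident: crossings use the same first-crossing linear interpolation.
    """

    def __init__(self, model: CheckpointVoteClassifier):
        self._model = model
        self._trace = VoteTrace()
        self._next_j = 0
        self._prev: Optional[Tuple[float, float]] = None

    @property
    def trace(self) -> VoteTrace:
        return self._trace

    @property
    def decided(self) -> bool:
        return self._trace.decision is not None

    def update(self, t: float, h: float) -> VoteTrace:
        if self._prev is not None and t <= self._prev[0]:
            raise IncidentError(
                f"out-of-order sample at t={t} (previous t={self._prev[0]})"
            )
        model = self._model
        checkpoints = model.checkpoints_
        while self._next_j < len(checkpoints) and self._trace.decision is None:
            c = checkpoints[self._next_j]
            if c <= H_FLOOR_TOL:
                if h > H_FLOOR_TOL:
                    break
                t_cross = t  # first floor contact: no interpolation past it
            else:
                if h > c:
                    break
                # If a previous sample exists its height exceeds c, else the
                # checkpoint would have been crossed on that update already.
                t_cross = 0.0 if self._prev is None else self._cross(c, t, h)
            j = self._next_j
            d_fall, d_bend, vote = _vote(
                t_cross, model.t_fall_ref_[j], model.t_bend_ref_[j]
            )
            self._trace._add(
                VoteRecord(j, float(c), float(t_cross), d_fall, d_bend, vote)
            )
            self._next_j += 1
            if self._next_j == len(checkpoints):
                self._trace._decide()
        self._prev = (t, h)
        return self._trace

    def _cross(self, c: float, t: float, h: float) -> float:
        t0, h0 = self._prev
        return t0 + (h0 - c) / (h0 - h) * (t - t0)


# ---------------------------------------------------------------------------
# Thin functional wrappers

def fit_cm1(training: Sequence[Incident]) -> TotalTimeThresholdClassifier:
    """Fit CM-I on labeled incidents."""
    return TotalTimeThresholdClassifier().fit(training)


def classify_cm1(model: TotalTimeThresholdClassifier, incident: Incident) -> str:
    """CM-I label for one incident: FALL iff total time < r."""
    return str(model.predict([incident])[0])


def fit_cm2(training: Sequence[Incident], k: int = 20) -> CheckpointVoteClassifier:
    """Fit CM-II with K height checkpoints on labeled incidents."""
    return CheckpointVoteClassifier(n_checkpoints=k).fit(training)


def classify_cm2(
    model: CheckpointVoteClassifier, incident: Incident
) -> Tuple[str, VoteTrace]:
    """CM-II label and vote trace for one incident."""
    trace = model.predict_trace([incident])[0]
    return trace.decision, trace


def classify_cm2_stream(
    model: CheckpointVoteClassifier, samples: Iterable[Tuple[float, float]]
) -> Iterator[VoteTrace]:
    """Replay (t, h) samples through CM-II incrementally.

    Yields the updated vote state after every sample that crosses at least
    one checkpoint; the final yielded state carries the decision if the
    stream reached the floor, and remains undecided otherwise.
    """
    voter = model.stream()
    previous = 0
    for t, h in samples:
        trace = voter.update(t, h)
        if trace.n_evaluated > previous:
            previous = trace.n_evaluated
            yield trace
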