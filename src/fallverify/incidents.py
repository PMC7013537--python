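"""Core domain types for altimeter-recorded descent incidents.

An *incident* is one descent event recorded by a wearable altimeter: an
ordered sequence of (time, height) samples starting at the wearer's sensor
height h0 and ending at the floor (h = 0).  Two kinds of incident are
distinguished: an involuntary *fall* (short, accelerating descent) and a
voluntary *lean-over* / *bend* (longer, decelerating descent).

The features both classifiers consume live here:

* :func:`total_time` — the time of first floor contact, i.e. the total
  descent duration t_I;
* :func:`checkpoint_times` — the times at which the trajectory first
  crosses a fixed grid of height checkpoints, which makes trajectories of
  different lengths comparable element-wise.

Heights are meters, times are seconds throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FALL",
    "BEND",
    "LABELS",
    "H_FLOOR_TOL",
    "RISE_TOL",
    "IncidentError",
    "Incident",
    "NormalTimeModel",
    "CheckpointProfile",
    "total_time",
    "checkpoint_times",
    "checkpoint_grid",
]

FALL = "FALL"
BEND = "BEND"
LABELS = (FALL, BEND)

#: Heights at or below this (meters) count as floor contact; real barometric
#: sensors never read exactly zero.
H_FLOOR_TOL = 0.01

#: Largest upward wiggle (meters) tolerated between consecutive samples of a
#: descent; covers sensor noise without admitting genuine re-ascents.
RISE_TOL = 0.02


class IncidentError(ValueError):
    """An incident violates the descent-event contract."""


@dataclass(frozen=True)
class Incident:
    """One descent event: ordered (t, h) samples plus an optional label.

    Invariants (checked on construction):

    * times strictly increasing, first sample at t = 0;
    * first height is the start height h0 > 0, last height is at the floor
      (h <= ``H_FLOOR_TOL``);
    * heights non-increasing up to a ``RISE_TOL`` sensor wiggle.
    """

    id: str
    t: np.ndarray
    h: np.ndarray
    label: Optional[str] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        h = np.asarray(self.h, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "h", h)
        self._validate()

    def _validate(self) -> None:
        ident = self.id
        t, h = self.t, self.h
        if self.label is not None and self.label not in LABELS:
            raise IncidentError(
                f"incident {ident!r}: label {self.label!r} not in {LABELS}"
            )
        if t.ndim != 1 or h.ndim != 1 or t.shape != h.shape:
            raise IncidentError(
                f"incident {ident!r}: t and h must be 1-d arrays of equal length"
            )
        if len(t) < 2:
            raise IncidentError(f"incident {ident!r}: needs at least 2 samples")
        if not math.isclose(t[0], 0.0, abs_tol=1e-9):
            raise IncidentError(f"incident {ident!r}: first sample must be at t=0")
        if np.any(np.diff(t) <= 0):
            raise IncidentError(f"incident {ident!r}: times not strictly increasing")
        if h[0] <= 0:
            raise IncidentError(f"incident {ident!r}: start height must be > 0")
        if np.any(h < -1e-9):
            raise IncidentError(f"incident {ident!r}: negative heights")
        if h[-1] > H_FLOOR_TOL:
            raise IncidentError(
                f"incident {ident!r}: last sample (h={h[-1]:.4f} m) never reaches "
                f"the floor (tolerance {H_FLOOR_TOL} m)"
            )
        rises = np.diff(h)
        if np.any(rises > RISE_TOL + 1e-12):
            raise IncidentError(
                f"incident {ident!r}: height rises by more than {RISE_TOL} m "
                "(not a descent event)"
            )

    @property
    def h0(self) -> float:
        """Start height of the sensor (meters)."""
        return float(self.h[0])

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class NormalTimeModel:
    """Class-conditional descent-duration distribution: a truncated normal.

    Parameters are the Gaussian mean ``mu`` and standard deviation ``sigma``
    (seconds), truncated to the closed support ``[lo, hi]``.  ``n_obs``
    records how many observations the fit used, when fitted from data.
    """

    mu: float
    sigma: float
    lo: float
    hi: float
    n_obs: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (self.lo < self.mu < self.hi):
            raise ValueError(
                f"support must bracket the mean: lo={self.lo} mu={self.mu} hi={self.hi}"
            )

    @classmethod
    def from_spread(
        cls,
        mu: float,
        spread: float,
        support: Optional[tuple[float, float]] = None,
        spread_is_variance: bool = True,
        n_obs: Optional[int] = None,
    ) -> "NormalTimeModel":
        """Build a model from a mean and a printed spread value.

        Published parameter tables are ambiguous about whether the spread is
        a variance (the notation) or a standard deviation (the unit); both
        readings are supported.  When no support is given it defaults to
        ``mu ± spread`` — the convention the bundled parameter sets follow —
        which keeps the truncation symmetric, so the truncated mean is mu.
        """
        sigma = math.sqrt(spread) if spread_is_variance else spread
        if support is None:
            support = (mu - spread, mu + spread)
        return cls(mu=mu, sigma=sigma, lo=support[0], hi=support[1], n_obs=n_obs)


@dataclass(frozen=True)
class CheckpointProfile:
    """First-crossing times of a trajectory over a decreasing height grid."""

    heights: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        heights = np.asarray(self.heights, dtype=float)
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "heights", heights)
        object.__setattr__(self, "times", times)
        if heights.shape != times.shape or heights.ndim != 1:
            raise ValueError("heights and times must be 1-d arrays of equal length")
        if np.any(np.diff(heights) >= 0):
            raise ValueError("checkpoint heights must be strictly decreasing")
        if np.any(np.diff(times) < 0):
            raise ValueError("crossing times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.heights)


def total_time(incident: Incident) -> float:
    """Total descent time: the time of the earliest sample at the floor.

    The floor is ``h <= H_FLOOR_TOL``.  For a monotone descent this is the
    last sample's time; for trajectories that linger at the floor it is the
    first floor contact.
    """
    at_floor = incident.h <= H_FLOOR_TOL
    if not at_floor.any():
        raise IncidentError(
            f"incident {incident.id!r}: incomplete — never reaches the floor"
        )
    return float(incident.t[int(np.argmax(at_floor))])


def checkpoint_grid(h0: float, k: int) -> np.ndarray:
    """K equally spaced height checkpoints from h0 down to 0 (inclusive)."""
    if k < 2:
        raise ValueError("need at least 2 checkpoints")
    if h0 <= 0:
        raise ValueError("h0 must be > 0")
    return np.linspace(h0, 0.0, k)


def checkpoint_times(
    incident: Incident, heights: Sequence[float] | np.ndarray
) -> CheckpointProfile:
    """First-crossing times of ``incident`` at each checkpoint height.

    For each checkpoint c the crossing time is linearly interpolated between
    the last sample above c and the first sample at or below c
    (first-crossing semantics, robust to small sensor wiggles).  Checkpoints
    at or below the floor tolerance return :func:`total_time`; a checkpoint
    at or above the start height returns t = 0.

    Raises :class:`IncidentError` if a checkpoint exceeds the start height.
    """
    heights = np.asarray(heights, dtype=float)
    t, h = incident.t, incident.h
    h0 = incident.h0
    if np.any(heights > h0 + 1e-9):
        raise IncidentError(
            f"incident {incident.id!r}: checkpoint above start height {h0:.3f} m"
        )
    t_total = total_time(incident)

    # Running minimum makes the profile non-increasing, so the first index
    # with h <= c can be found by bisection; at that index the raw h is <= c
    # and at the previous index it is > c, so interpolation uses raw samples.
    hmin = np.minimum.accumulate(h)
    times = np.empty_like(heights)
    idx = np.searchsorted(-hmin, -heights, side="left")
    for out, (c, i) in enumerate(zip(heights, idx)):
        if c <= H_FLOOR_TOL:
            times[out] = t_total
        elif i == 0:
            times[out] = 0.0
        else:
            ha, hb = h[i - 1], h[i]
            times[out] = t[i - 1] + (ha - c) / (ha - hb) * (t[i] - t[i - 1])
    return CheckpointProfile(heights=heights, times=times)
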