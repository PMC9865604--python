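"""Successive-difference count statistics on RR-interval series.

The central quantity is the relative difference between neighbouring RR
intervals: ``|RR[i] - RR[i-1]| / RR[i-1] * 100`` (percent of the *preceding*
interval).  ``pRRx%`` is the percentage of admissible consecutive pairs whose
relative difference is **at least** x percent; ``pRRx`` (the pNN50/pRR31
family) is the analogous count with absolute differences in milliseconds.
Atrial fibrillation produces large, serially uncorrelated beat-to-beat
changes, so pRRx% at moderate x separates AF from sinus rhythm.

All durations are milliseconds; all statistics are percent in [0, 100].
A segment with zero admissible pairs has an *undefined* statistic, carried
as NaN — never coerced to 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "RRSeries",
    "RelDiffSeries",
    "ParamGrid",
    "PRRxProfile",
    "default_percent_grid",
    "relative_differences",
    "absolute_differences",
    "prrx_percent",
    "prrx_ms",
    "prrx_profile",
    "relative_difference_at_hr",
]

#: rhythm labels carried per interval
SR, AF, OTHER = "SR", "AF", "OTHER"


@dataclass
class RRSeries:
    """A time-ordered series of RR intervals.

    Parameters
    ----------
    beat_times
        Time of each interval's *terminating* beat, ms from recording start,
        strictly increasing.
    rr
        Interval durations in ms.  For contiguous data
        ``rr[i] == beat_times[i] - beat_times[i-1]``.
    valid
        Per-interval validity flag, cleared by range filtering.
    rhythm
        Per-interval rhythm label in {``SR``, ``AF``, ``OTHER``}.
    """

    beat_times: NDArray[np.float64]
    rr: NDArray[np.float64]
    valid: NDArray[np.bool_] = None  # type: ignore[assignment]
    rhythm: NDArray[np.str_] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.rr.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.rhythm is None:
            self.rhythm = np.full(self.rr.shape, SR, dtype="<U8")
        else:
            self.rhythm = np.asarray(self.rhythm, dtype="<U8")
        if not (self.beat_times.shape == self.rr.shape == self.valid.shape == self.rhythm.shape):
            raise ValueError("beat_times, rr, valid and rhythm must have equal length")
        if np.any(self.rr <= 0):
            raise ValueError("all RR durations must be positive")
        if self.beat_times.size > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.rr.size)


@dataclass
class RelDiffSeries:
    """Relative successive differences, percent, one per admissible pair.

    ``pair_index[k]`` is the index of the *later* interval of pair ``k``.
    """

    values: NDArray[np.float64]
    pair_index: NDArray[np.intp]

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True, eq=False)
class ParamGrid:
    """Ordered threshold grid, either percent of the preceding RR or ms."""

    kind: str  # "percent" | "ms"
    values: NDArray[np.float64]

    def __post_init__(self) -> None:
        if self.kind not in ("percent", "ms"):
            raise ValueError(f"unknown grid kind {self.kind!r}")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("grid must be a non-empty 1-D array")
        if np.any(np.diff(vals) <= 0):
            raise ValueError("grid thresholds must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)


def default_percent_grid() -> ParamGrid:
    """The standard percent grid: 0.25% to 25% in steps of 0.25% (100 values)."""
    return ParamGrid("percent", np.arange(1, 101) * 0.25)


@dataclass
class PRRxProfile:
    """pRRx values over a threshold grid for one segment.

    ``values`` are percent in [0, 100], or NaN throughout when the segment
    has no admissible pairs.  ``n_pairs`` is the denominator used.
    """

    grid: ParamGrid
    values: NDArray[np.float64]
    n_pairs: int

    @property
    def defined(self) -> bool:
        return self.n_pairs > 0


def _pair_mask(rr: NDArray[np.float64], adjacency: ArrayLike | None) -> NDArray[np.bool_]:
    """Admissibility mask over the n-1 consecutive pairs of ``rr``."""
    n = rr.size
    if adjacency is None:
        return np.ones(max(n - 1, 0), dtype=bool)
    adj = np.asarray(adjacency, dtype=bool)
    if adj.shape != (max(n - 1, 0),):
        raise ValueError(f"adjacency must have length len(rr)-1 = {max(n - 1, 0)}")
    return adj


def _as_rr(rr: ArrayLike) -> NDArray[np.float64]:
    arr = np.asarray(rr, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("all RR durations must be positive")
    return arr


def relative_differences(rr: ArrayLike, adjacency: ArrayLike | None = None) -> RelDiffSeries:
    """Relative successive differences in percent of the preceding interval.

    For each admissible pair (i-1, i):
    ``100 * |rr[i] - rr[i-1]| / rr[i-1]``.  Pairs spanning a removed interval
    (adjacency False) are absent from the result, not zero.

    Examples
    --------
    >>> relative_differences([500, 550]).values
    array([10.])
    """
    arr = _as_rr(rr)
    adj = _pair_mask(arr, adjacency)
    if arr.size < 2 or not adj.any():
        return RelDiffSeries(np.empty(0), np.empty(0, dtype=np.intp))
    idx = np.flatnonzero(adj) + 1
    vals = 100.0 * np.abs(arr[idx] - arr[idx - 1]) / arr[idx - 1]
    return RelDiffSeries(vals, idx)


def absolute_differences(rr: ArrayLike, adjacency: ArrayLike | None = None) -> NDArray[np.float64]:
    """Absolute successive differences ``|rr[i] - rr[i-1]|`` in ms, admissible pairs only."""
    arr = _as_rr(rr)
    adj = _pair_mask(arr, adjacency)
    if arr.size < 2 or not adj.any():
        return np.empty(0)
    idx = np.flatnonzero(adj) + 1
    return np.abs(arr[idx] - arr[idx - 1])


def _count_fraction(diffs: NDArray[np.float64], x: float) -> float:
    if x < 0:
        raise ValueError("threshold must be non-negative")
    if diffs.size == 0:
        return float("nan")
    return 100.0 * np.count_nonzero(diffs >= x) / diffs.size


def prrx_percent(rr: ArrayLike, adjacency: ArrayLike | None = None, *, x_percent: float) -> float:
    """pRRx%: percentage of pairs with relative difference >= ``x_percent``.

    The inequality is inclusive (a difference exactly at the threshold
    counts).  Returns NaN when there are no admissible pairs.
    """
    return _count_fraction(relative_differences(rr, adjacency).values, x_percent)


def prrx_ms(rr: ArrayLike, adjacency: ArrayLike | None = None, *, x_ms: float) -> float:
    """pRRx: percentage of pairs with absolute difference >= ``x_ms`` ms."""
    return _count_fraction(absolute_differences(rr, adjacency), x_ms)


def prrx_profile(
    rr: ArrayLike,
    adjacency: ArrayLike | None = None,
    grid: ParamGrid | None = None,
) -> PRRxProfile:
    """pRRx value at every threshold of ``grid`` (default: 100-point percent grid).

    Because the same pairs are counted at every threshold, the profile is
    non-increasing along the grid.
    """
    if grid is None:
        grid = default_percent_grid()
    if grid.kind == "percent":
        diffs = relative_differences(rr, adjacency).values
    else:
        diffs = absolute_differences(rr, adjacency)
    n = int(diffs.size)
    if n == 0:
        return PRRxProfile(grid, np.full(len(grid), np.nan), 0)
    # one vectorised sweep: count of diffs >= x for every x in the grid
    counts = n - np.searchsorted(np.sort(diffs), grid.values, side="left")
    return PRRxProfile(grid, 100.0 * counts / n, n)


def relative_difference_at_hr(x_ms: float, hr: float) -> float:
    """Relative difference (percent) of an ``x_ms`` change at heart rate ``hr``.

    At heart rate ``hr`` beats/min the RR interval is ``60000/hr`` ms, so a
    fixed absolute change of ``x_ms`` corresponds to a relative change of
    ``100 * x_ms / (60000/hr) = x_ms * hr / 600`` percent — linear in heart
    rate, which is why a fixed ms threshold means different things at
    different rates and a relative threshold does not.
    """
    if hr <= 0:
        raise ValueError("heart rate must be positive")
    if x_ms < 0:
        raise ValueError("x_ms must be non-negative")
    return x_ms * hr / 600.0
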