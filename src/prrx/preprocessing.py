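"""Segmentation and artifact filtering of annotated RR streams.

The pipeline turns a continuous, rhythm-annotated RR series into
rhythm-pure, fixed-length (default 60 s) segments suitable for pRRx%
computation:

1. range filter — intervals shorter than 240 ms (heart rate above 250
   beats/min) or longer than 3000 ms (below 20 beats/min) are flagged as
   technical artifacts; the boundary values themselves are retained;
2. tiling — each maximal same-rhythm run labelled SR or AF is cut from its
   onset into non-overlapping windows; trailing partial windows are dropped
   and runs with other rhythms are skipped entirely;
3. rejection — a segment losing strictly more than 6 s of removed interval
   duration is discarded as a whole.

An RR interval belongs to the window containing its terminating beat:
the interval exists once its closing beat has occurred.  Pairs touching or
spanning a removed interval are inadmissible for difference statistics, so
artifacts never create fictitious successive differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .statistics import AF, SR, RRSeries

__all__ = [
    "RhythmInterval",
    "SegmentationConfig",
    "Segment",
    "FilterReport",
    "filter_rr",
    "segment_recording",
    "reject_segments",
    "preprocess",
]


@dataclass(frozen=True)
class RhythmInterval:
    """Half-open [onset, offset) span of one rhythm, ms from recording start."""

    onset: float
    offset: float
    label: str  # SR | AF | OTHER

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("rhythm interval requires onset < offset")


@dataclass(frozen=True)
class SegmentationConfig:
    """Segmentation and artifact-filter parameters (all durations in ms)."""

    segment_len: float = 60_000.0
    rr_min: float = 240.0
    rr_max: float = 3000.0
    max_removed: float = 6000.0

    def __post_init__(self) -> None:
        if not 0 < self.rr_min < self.rr_max:
            raise ValueError("need 0 < rr_min < rr_max")
        if self.segment_len <= 0:
            raise ValueError("segment_len must be positive")
        if self.max_removed > self.segment_len:
            raise ValueError("max_removed cannot exceed segment_len")


@dataclass
class Segment:
    """One rhythm-pure window of retained RR intervals.

    ``rr`` holds only the retained durations; ``adjacency[k]`` says whether
    retained intervals k and k+1 were truly consecutive in the recording
    (no removed interval between them).  ``removed_ms`` is the summed
    duration of range-filtered intervals whose terminating beat fell in
    this window.
    """

    id: str
    label: str
    rr: NDArray[np.float64]
    adjacency: NDArray[np.bool_]
    removed_ms: float = 0.0
    start: float = 0.0

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        if self.adjacency.shape != (max(self.rr.size - 1, 0),):
            raise ValueError("adjacency must have length len(rr) - 1")

    @property
    def n_pairs(self) -> int:
        return int(np.count_nonzero(self.adjacency))


@dataclass
class FilterReport:
    """Bookkeeping of interval removal and segment rejection."""

    n_total: int = 0
    n_removed: int = 0
    n_segments_kept: int = 0
    n_segments_rejected: int = 0

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_total if self.n_total else 0.0


def filter_rr(series: RRSeries, cfg: SegmentationConfig = SegmentationConfig()) -> RRSeries:
    """Flag out-of-range intervals invalid; returns a new series.

    Intervals *strictly* shorter than ``rr_min`` or strictly longer than
    ``rr_max`` are removed, so durations of exactly 240 or 3000 ms survive.
    """
    valid = (series.rr >= cfg.rr_min) & (series.rr <= cfg.rr_max)
    return RRSeries(series.beat_times.copy(), series.rr.copy(), valid, series.rhythm.copy())


def pair_adjacency(valid: NDArray[np.bool_]) -> NDArray[np.bool_]:
    """Admissibility of each consecutive pair: both members must be valid."""
    if valid.size < 2:
        return np.zeros(0, dtype=bool)
    return valid[:-1] & valid[1:]


def segment_recording(
    series: RRSeries,
    rhythms: list[RhythmInterval],
    cfg: SegmentationConfig = SegmentationConfig(),
) -> list[Segment]:
    """Tile SR/AF rhythm runs into non-overlapping fixed-length segments.

    Windows are anchored at each run's onset; a trailing window shorter
    than ``cfg.segment_len`` is dropped.  Intervals are assigned to the
    window containing their terminating beat time (half-open windows).
    Invalid intervals contribute to ``removed_ms`` instead of ``rr``;
    within a segment, a pair of retained intervals is admissible only if
    they were consecutive in the original series and both valid.
    """
    segments: list[Segment] = []
    t = series.beat_times
    for run_no, run in enumerate(rhythms):
        if run.label not in (SR, AF):
            continue
        n_windows = int((run.offset - run.onset) // cfg.segment_len)
        for w in range(n_windows):
            w_start = run.onset + w * cfg.segment_len
            w_end = w_start + cfg.segment_len
            sel = np.flatnonzero((t >= w_start) & (t < w_end))
            if sel.size == 0:
                continue
            valid_sel = series.valid[sel]
            rr_kept = series.rr[sel][valid_sel]
            # retained pair admissible iff original indices consecutive and both valid
            kept_idx = sel[valid_sel]
            adjacency = np.diff(kept_idx) == 1 if kept_idx.size > 1 else np.zeros(0, dtype=bool)
            removed = float(series.rr[sel][~valid_sel].sum())
            segments.append(
                Segment(
                    id=f"run{run_no}_win{w}",
                    label=run.label,
                    rr=rr_kept,
                    adjacency=adjacency,
                    removed_ms=removed,
                    start=w_start,
                )
            )
    return segments


def reject_segments(
    segments: list[Segment],
    cfg: SegmentationConfig = SegmentationConfig(),
) -> tuple[list[Segment], FilterReport]:
    """Drop segments whose removed duration strictly exceeds ``cfg.max_removed``.

    A segment with exactly ``max_removed`` ms removed is kept.  The report
    counts retained/removed intervals over the kept+rejected population.
    """
    kept = [s for s in segments if s.removed_ms <= cfg.max_removed]
    rejected = len(segments) - len(kept)
    n_total = sum(len(s.rr) for s in segments)
    report = FilterReport(
        n_total=n_total,
        n_removed=0,
        n_segments_kept=len(kept),
        n_segments_rejected=rejected,
    )
    return kept, report


def preprocess(
    series: RRSeries,
    rhythms: list[RhythmInterval],
    cfg: SegmentationConfig = SegmentationConfig(),
) -> tuple[list[Segment], FilterReport]:
    """Full pipeline: range filter, tile into segments, reject damaged ones."""
    filtered = filter_rr(series, cfg)
    segments = segment_recording(filtered, rhythms, cfg)
    kept, report = reject_segments(segments, cfg)
    report.n_total = len(series)
    report.n_removed = int(np.count_nonzero(~filtered.valid))
    return kept, report
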