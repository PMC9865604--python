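"""Segment-level AF/SR classification with calibrated pRRx cutoffs.

A segment is called AF when its pRRx score is greater than or equal to the
decision cutoff for the chosen parameter.  The package ships a calibration
table of Youden-optimal cutoffs for the full percent grid (0.25%–25%,
step 0.25%) derived from the Long-Term Atrial Fibrillation Database; the
headline parameter is pRR3.25% with cutoff 75.32%.

Calibration is data, not code: the table lives in
``data/cutoffs_ltafdb_youden.csv`` and is checksum-verified at load.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from importlib import resources

from .preprocessing import RhythmInterval, Segment, SegmentationConfig, preprocess
from .statistics import AF, SR, RRSeries, prrx_ms, prrx_percent

__all__ = [
    "UNDEFINED",
    "CutoffTable",
    "Detection",
    "load_packaged_cutoffs",
    "classify_segment",
    "score_segment",
    "screen_recording",
]

UNDEFINED = "UNDEFINED"

_PACKAGED_CSV = "cutoffs_ltafdb_youden.csv"
_PACKAGED_SHA256 = "7a49e5149d5212a340f339a30de24cc32d620bf572ab59e09ef9ffaf8e1fe3fa"


@dataclass
class CutoffTable:
    """Decision cutoffs (percent units) keyed by (kind, threshold x)."""

    entries: dict[tuple[str, float], float]
    provenance: str = ""

    def __post_init__(self) -> None:
        for (kind, x), cutoff in self.entries.items():
            if not 0.0 <= cutoff <= 100.0:
                raise ValueError(f"cutoff for ({kind}, {x}) outside [0, 100]")

    def lookup(self, kind: str, x: float) -> float:
        try:
            return self.entries[(kind, float(x))]
        except KeyError:
            raise KeyError(f"no calibrated cutoff for kind={kind!r}, x={x}") from None


@dataclass
class Detection:
    """One segment's score, cutoff and rhythm call."""

    segment_id: str
    kind: str
    x: float
    score: float
    cutoff: float
    call: str
    label: str | None = None  # annotated truth, when available


def load_packaged_cutoffs() -> CutoffTable:
    """Load the packaged Youden-optimal cutoff table (LTAFDB calibration).

    The CSV is verified against a SHA-256 checksum; corruption is a hard
    failure since every downstream call would silently change.
    """
    ref = resources.files("prrx").joinpath("data", _PACKAGED_CSV)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _PACKAGED_SHA256:
        raise RuntimeError(
            f"packaged cutoff table failed checksum verification ({digest})"
        )
    entries: dict[tuple[str, float], float] = {}
    for line in raw.decode().splitlines()[1:]:
        kind, x, cutoff = line.split(",")
        entries[(kind, float(x))] = float(cutoff)
    return CutoffTable(entries, provenance="LTAFDB, Youden index")


def classify_segment(score: float, cutoff: float) -> str:
    """AF when ``score >= cutoff``, SR below, UNDEFINED propagates NaN scores."""
    if not 0.0 <= cutoff <= 100.0:
        raise ValueError("cutoff must lie in [0, 100]")
    if score is None or math.isnan(score):
        return UNDEFINED
    return AF if score >= cutoff else SR


def score_segment(segment: Segment, kind: str, x: float) -> float:
    """pRRx score of one segment (NaN when it has no admissible pairs)."""
    if kind == "percent":
        return prrx_percent(segment.rr, segment.adjacency, x_percent=x)
    if kind == "ms":
        return prrx_ms(segment.rr, segment.adjacency, x_ms=x)
    raise ValueError(f"unknown parameter kind {kind!r}")


def screen_recording(
    series: RRSeries,
    rhythms: list[RhythmInterval] | None = None,
    cfg: SegmentationConfig = SegmentationConfig(),
    *,
    kind: str = "percent",
    x: float = 3.25,
    cutoffs: CutoffTable | None = None,
    cutoff: float | None = None,
) -> list[Detection]:
    """Screen a whole recording: preprocess, score and classify each segment.

    When ``rhythms`` is None the whole recording is tiled as a single
    unlabelled run, which is the screening use case (no annotations).
    ``cutoff`` overrides the calibrated table entry when given.
    """
    if cutoff is None:
        table = cutoffs if cutoffs is not None else load_packaged_cutoffs()
        cutoff = table.lookup(kind, x)
    labelled = rhythms is not None
    if rhythms is None:
        end = float(series.beat_times[-1]) if len(series) else 0.0
        start = float(series.beat_times[0] - series.rr[0]) if len(series) else 0.0
        if end <= start:
            rhythms = []
        else:
            rhythms = [RhythmInterval(start, end, SR)]  # label placeholder, dropped below
    segments, _ = preprocess(series, rhythms, cfg)
    if not segments:
        warnings.warn("no segments kept after preprocessing", stacklevel=2)
        return []
    detections = []
    for seg in segments:
        score = score_segment(seg, kind, x)
        detections.append(
            Detection(
                segment_id=seg.id,
                kind=kind,
                x=x,
                score=score,
                cutoff=cutoff,
                call=classify_segment(score, cutoff),
                label=seg.label if labelled else None,
            )
        )
    return detections
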