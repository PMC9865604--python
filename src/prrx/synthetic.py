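"""Synthetic RR-interval generator for sinus rhythm and atrial fibrillation.

The generator reproduces the statistical contrast the pRRx% detector
exploits, not the physiology behind it:

* **Sinus rhythm** — a slow sinusoidal modulation (respiratory sinus
  arrhythmia, default 4 s period, 40 ms amplitude) around a mean RR of
  850 ms, plus small white jitter (default SD 10 ms).  Successive relative
  differences stay below ~8%, keeping pRR3.25% under the 75.32% cutoff.
* **Atrial fibrillation** — i.i.d. Gamma-distributed intervals with mean
  650 ms and coefficient of variation 0.20 (shape 1/cv², moment-matched),
  giving the "irregularly irregular" response: typical successive relative
  differences around 28%, pRR3.25% near 100, near-zero lag-1
  autocorrelation.

Artifact injection replaces intervals with out-of-range durations so the
range filter and the per-segment rejection rule can be exercised end to
end.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import Segment, SegmentationConfig, filter_rr
from .statistics import AF, SR, RRSeries

__all__ = [
    "SynthConfig",
    "LabeledDataset",
    "simulate_sr",
    "simulate_af",
    "inject_artifacts",
    "generate_dataset",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters (durations in ms unless noted)."""

    sr_mean_rr: float = 850.0
    sr_modulation_amp: float = 40.0
    sr_modulation_period: float = 4.0  # seconds, respiratory
    sr_jitter_sd: float = 10.0
    af_mean_rr: float = 650.0
    af_cv: float = 0.20
    af_correlation: float = 0.0  # target lag-1 autocorrelation
    n_segments_per_class: int = 200
    segment_len: float = 60_000.0
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (240.0 <= self.sr_mean_rr <= 3000.0 and 240.0 <= self.af_mean_rr <= 3000.0):
            raise ValueError("mean RR must lie within the physiological range [240, 3000] ms")
        if self.af_cv < 0 or self.sr_jitter_sd < 0 or self.sr_modulation_amp < 0:
            raise ValueError("dispersion parameters must be non-negative")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must lie in [0, 1)")


@dataclass
class LabeledDataset:
    """Balanced, shuffled SR/AF segments ready for evaluation."""

    segments: list[Segment]
    config: SynthConfig
    seed: int

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.segments], dtype="<U8")


def _clip(rr: np.ndarray) -> np.ndarray:
    return np.clip(rr, 240.0, 3000.0)


def _series(rr: np.ndarray, rhythm: str) -> RRSeries:
    beat_times = np.cumsum(rr)
    return RRSeries(beat_times, rr, rhythm=np.full(rr.shape, rhythm, dtype="<U8"))


def simulate_sr(cfg: SynthConfig = SynthConfig(), seed: int | np.random.Generator = 0) -> RRSeries:
    """One sinus-rhythm series spanning ``cfg.segment_len`` ms.

    rr_i = mean + amp * sin(2*pi*t_i / period) + jitter, clipped to the
    physiological range.  Durations accumulate into beat times.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # upper bound on beat count, then trim to the window
    n_max = int(cfg.segment_len / max(cfg.sr_mean_rr - 4 * cfg.sr_jitter_sd - cfg.sr_modulation_amp, 240.0)) + 2
    rr = np.empty(n_max)
    t = 0.0
    period_ms = cfg.sr_modulation_period * 1000.0
    eps = rng.normal(0.0, cfg.sr_jitter_sd, size=n_max)
    n = 0
    for i in range(n_max):
        dur = cfg.sr_mean_rr + cfg.sr_modulation_amp * np.sin(2 * np.pi * t / period_ms) + eps[i]
        dur = min(max(dur, 240.0), 3000.0)
        if t + dur > cfg.segment_len:
            break
        rr[i] = dur
        t += dur
        n += 1
    return _series(rr[:n], SR)


def simulate_af(cfg: SynthConfig = SynthConfig(), seed: int | np.random.Generator = 0) -> RRSeries:
    """One atrial-fibrillation series spanning ``cfg.segment_len`` ms.

    Intervals are i.i.d. Gamma with mean ``af_mean_rr`` and SD
    ``af_cv * af_mean_rr`` (shape 1/cv**2, scale mean*cv**2), clipped to
    the physiological range; serially uncorrelated by construction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if cfg.af_cv == 0:
        n = int(cfg.segment_len // cfg.af_mean_rr)
        return _series(np.full(n, cfg.af_mean_rr), AF)
    shape = 1.0 / cfg.af_cv**2
    scale = cfg.af_mean_rr * cfg.af_cv**2
    n_max = int(cfg.segment_len / 240.0) + 2
    draws = _clip(rng.gamma(shape, scale, size=n_max))
    t = np.cumsum(draws)
    n = int(np.searchsorted(t, cfg.segment_len, side="right"))
    return _series(draws[:n], AF)


def inject_artifacts(
    series: RRSeries,
    cfg: SynthConfig,
    seed: int | np.random.Generator = 0,
) -> RRSeries:
    """Replace intervals with out-of-range durations at ``cfg.artifact_rate``.

    Half of the artifacts fall below 240 ms (uniform on [60, 239]), half
    above 3000 ms (uniform on [3001, 6000]).  Beat times are re-accumulated
    from the modified durations.
    """
    if cfg.artifact_rate == 0.0:
        return series
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rr = series.rr.copy()
    hit = rng.random(rr.size) < cfg.artifact_rate
    n_hit = int(hit.sum())
    if n_hit:
        low = rng.random(n_hit) < 0.5
        vals = np.where(
            low,
            rng.uniform(60.0, 239.0, size=n_hit),
            rng.uniform(3001.0, 6000.0, size=n_hit),
        )
        rr[hit] = vals
    return RRSeries(np.cumsum(rr) + float(series.beat_times[0] - series.rr[0]), rr, rhythm=series.rhythm.copy())


def _segment_from_series(series: RRSeries, seg_id: str, seg_cfg: SegmentationConfig) -> Segment:
    filtered = filter_rr(series, seg_cfg)
    rr_kept = filtered.rr[filtered.valid]
    kept_idx = np.flatnonzero(filtered.valid)
    adjacency = np.diff(kept_idx) == 1 if kept_idx.size > 1 else np.zeros(0, dtype=bool)
    return Segment(
        id=seg_id,
        label=str(series.rhythm[0]),
        rr=rr_kept,
        adjacency=adjacency,
        removed_ms=float(filtered.rr[~filtered.valid].sum()),
        start=0.0,
    )


def generate_dataset(cfg: SynthConfig = SynthConfig()) -> LabeledDataset:
    """Balanced labelled dataset: n segments per class, seeded shuffle.

    Each segment is simulated independently (sub-streams spawned from
    ``cfg.seed``), optionally corrupted with artifacts, range-filtered and
    wrapped as a Segment.  The order is shuffled so class labels are not
    positional.
    """
    seg_cfg = SegmentationConfig(segment_len=cfg.segment_len)
    root = np.random.SeedSequence(cfg.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(2 * cfg.n_segments_per_class + 1)]
    shuffle_rng, streams = streams[0], streams[1:]
    segments: list[Segment] = []
    for i in range(cfg.n_segments_per_class):
        sr_rng, af_rng = streams[2 * i], streams[2 * i + 1]
        for tag, series in (("sr", simulate_sr(cfg, sr_rng)), ("af", simulate_af(cfg, af_rng))):
            rng = sr_rng if tag == "sr" else af_rng
            if cfg.artifact_rate > 0:
                series = inject_artifacts(series, cfg, rng)
            segments.append(_segment_from_series(series, f"{tag}{i}", seg_cfg))
    order = shuffle_rng.permutation(len(segments))
    return LabeledDataset([segments[k] for k in order], cfg, cfg.seed)
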