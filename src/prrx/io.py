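"""Readers and writers for RR-interval data and pipeline outputs.

Two input formats are supported:

* **CSV** — columns ``time_ms, rr_ms[, rhythm]`` with a header; times are
  milliseconds from recording start, 0-based, and per-beat rhythm labels
  (``SR|AF|OTHER``) are collapsed into maximal rhythm intervals.
* **WFDB annotations** — the MIT annotation format used by PhysioNet
  (e.g. the LTAFDB and AFDB Holter databases): beat locations as sample
  indices plus rhythm-change aux strings.  The binary format is parsed
  directly: 16-bit little-endian words carrying a 6-bit type code and a
  10-bit time increment, with SKIP/NUM/SUB/CHN/AUX pseudo-annotations.
  Sample indices become ms via the sampling frequency from the ``.hea``
  header (LTAFDB records are 128 Hz).

All times inside the package are milliseconds from recording start.
Output CSVs begin with a ``#``-prefixed metadata line (tool version,
seed) which readers skip.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detection import Detection
from .preprocessing import RhythmInterval, Segment
from .statistics import AF, OTHER, SR, PRRxProfile, RRSeries

__all__ = [
    "read_rr_csv",
    "write_rr_csv",
    "read_wfdb_annotations",
    "write_wfdb_annotations",
    "write_profiles_csv",
    "write_segments_csv",
    "write_detections_csv",
    "write_metric_table",
    "rhythm_intervals_from_labels",
    "DEFAULT_AUX_MAP",
]

#: rhythm aux-label mapping, user-extensible; unknown labels become OTHER
DEFAULT_AUX_MAP = {"(N": SR, "(AFIB": AF}

_RHYTHM_VALUES = {SR, AF, OTHER}


def _meta_line(seed: int | None = None) -> str:
    extra = f" seed={seed}" if seed is not None else ""
    return f"# prrx {__version__}{extra}\n"


def rhythm_intervals_from_labels(
    beat_times: np.ndarray, rr: np.ndarray, labels: np.ndarray
) -> list[RhythmInterval]:
    """Collapse per-interval rhythm labels into maximal rhythm intervals.

    Interval i spans (beat_times[i] - rr[i], beat_times[i]]; runs of equal
    labels merge, and consecutive runs share a boundary at the terminating
    beat of the earlier run.  The final offset is nudged past the last
    beat so that beat lies inside its half-open rhythm interval.
    """
    if beat_times.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    out = []
    onset = float(beat_times[0] - rr[0])
    for s, e in zip(starts, ends):
        offset = float(beat_times[e - 1]) if e < labels.size else float(beat_times[-1]) + 1e-6
        out.append(RhythmInterval(onset, offset, str(labels[s])))
        onset = offset
    return out


def read_rr_csv(path: str | Path) -> tuple[RRSeries, list[RhythmInterval]]:
    """Read an RR series from CSV (``time_ms, rr_ms[, rhythm]``).

    Raises a descriptive error naming the offending line for missing
    columns, non-monotone beat times or non-positive durations.
    """
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in ("time_ms", "rr_ms"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    t = df["time_ms"].to_numpy(dtype=float)
    rr = df["rr_ms"].to_numpy(dtype=float)
    # +2: one for the header line, one for 1-based line numbering
    bad = np.flatnonzero(rr <= 0)
    if bad.size:
        raise ValueError(f"{path}: non-positive rr_ms on line {bad[0] + 2}")
    if t.size > 1:
        nonmono = np.flatnonzero(np.diff(t) <= 0)
        if nonmono.size:
            raise ValueError(f"{path}: time_ms not strictly increasing on line {nonmono[0] + 3}")
    if "rhythm" in df.columns:
        labels = df["rhythm"].astype(str).str.strip().to_numpy(dtype="<U8")
        unknown = set(labels) - _RHYTHM_VALUES
        if unknown:
            raise ValueError(f"{path}: unknown rhythm labels {sorted(unknown)}")
    else:
        labels = np.full(rr.shape, SR, dtype="<U8")
    series = RRSeries(t, rr, rhythm=labels)
    rhythms = rhythm_intervals_from_labels(t, rr, labels) if "rhythm" in df.columns else []
    return series, rhythms


def write_rr_csv(path: str | Path, series: RRSeries, *, seed: int | None = None) -> None:
    """Write an RR series in the CSV dialect ``read_rr_csv`` accepts."""
    with open(path, "w") as f:
        f.write(_meta_line(seed))
        f.write("time_ms,rr_ms,rhythm\n")
        for t, rr, lab in zip(series.beat_times, series.rr, series.rhythm):
            f.write(f"{t:g},{rr:g},{lab}\n")


# ---------------------------------------------------------------------------
# MIT/WFDB annotation format

# pseudo-annotation type codes
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63
#: annotation type codes that mark beats (normal, ectopic, paced, escape...)
BEAT_CODES = frozenset(range(1, 14)) | {25, 34, 35, 38}
_RHYTHM_CODE = 28


def _read_header_fs(record_path: Path) -> float | None:
    hea = record_path.with_suffix(".hea")
    if not hea.exists():
        return None
    first = hea.read_text().splitlines()[0].split()
    if len(first) < 3:
        return None
    return float(first[2].split("/")[0])


def read_wfdb_annotations(
    record_path: str | Path,
    *,
    extension: str = "atr",
    fs: float | None = None,
    aux_map: dict[str, str] | None = None,
) -> tuple[RRSeries, list[RhythmInterval]]:
    """Read beat times and rhythm intervals from a WFDB annotation file.

    ``record_path`` is the record name without extension; the annotation
    file ``<record>.<extension>`` and, when present, the ``<record>.hea``
    header (for the sampling frequency) are read.  Rhythm aux strings are
    mapped through ``aux_map`` (default ``(N``→SR, ``(AFIB``→AF); unknown
    labels map to OTHER.
    """
    record_path = Path(record_path)
    aux_map = DEFAULT_AUX_MAP if aux_map is None else aux_map
    if fs is None:
        fs = _read_header_fs(record_path)
    if fs is None:
        raise ValueError(f"{record_path}: sampling frequency unknown (no .hea header; pass fs=)")
    raw = record_path.with_suffix("." + extension).read_bytes()

    beats: list[int] = []  # sample indices
    rhythm_changes: list[tuple[int, str]] = []  # (sample, mapped label)
    t = 0
    i = 0
    last_sample: int | None = None
    while i + 2 <= len(raw):
        (word,) = struct.unpack_from("<H", raw, i)
        i += 2
        code, interval = word >> 10, word & 0x3FF
        if word == 0:  # EOF
            break
        if code == _SKIP:
            high, low = struct.unpack_from("<HH", raw, i)
            i += 4
            t += (high << 16) | low
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            aux = raw[i : i + interval].rstrip(b"\x00").decode("ascii", errors="replace")
            i += interval + (interval & 1)  # pad to even
            if aux.startswith("(") and last_sample is not None:
                rhythm_changes.append((last_sample, aux_map.get(aux, OTHER)))
        else:
            t += interval
            last_sample = t
            if code in BEAT_CODES:
                beats.append(t)

    ms_per_sample = 1000.0 / fs
    beat_ms = np.asarray(beats, dtype=float) * ms_per_sample
    if beat_ms.size < 2:
        return RRSeries(beat_ms, np.full(beat_ms.shape, np.nan)), []  # pragma: no cover
    rr = np.diff(beat_ms)
    times = beat_ms[1:]

    rhythms: list[RhythmInterval] = []
    if rhythm_changes:
        changes_ms = [(s * ms_per_sample, lab) for s, lab in rhythm_changes]
        end = float(beat_ms[-1]) + 1e-6
        for k, (onset, lab) in enumerate(changes_ms):
            offset = changes_ms[k + 1][0] if k + 1 < len(changes_ms) else end
            if offset > onset:
                rhythms.append(RhythmInterval(onset, offset, lab))
    else:
        import warnings

        warnings.warn(f"{record_path}: no rhythm labels found", stacklevel=2)

    labels = np.full(rr.shape, OTHER, dtype="<U8")
    for iv in rhythms:
        labels[(times > iv.onset) & (times <= iv.offset)] = iv.label
    return RRSeries(times, rr, rhythm=labels), rhythms


def write_wfdb_annotations(
    record_path: str | Path,
    beat_samples: np.ndarray,
    *,
    extension: str = "atr",
    fs: float = 128.0,
    rhythm_changes: list[tuple[int, str]] | None = None,
    write_header: bool = True,
) -> None:
    """Write a minimal MIT-format annotation file (beats + rhythm aux).

    ``rhythm_changes`` are (sample index, aux string) pairs, e.g.
    ``(0, "(AFIB")``; each must coincide with a beat sample or precede
    one.  Mainly used to build small test recordings and fixtures.
    """
    record_path = Path(record_path)
    events: list[tuple[int, int, str | None]] = [(int(s), 1, None) for s in beat_samples]
    for s, aux in rhythm_changes or []:
        events.append((int(s), _RHYTHM_CODE, aux))
    events.sort(key=lambda e: (e[0], e[1]))

    out = bytearray()
    t = 0
    for sample, code, aux in events:
        delta = sample - t
        if delta > 0x3FF or delta < 0:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
        t = sample
        if aux is not None:
            data = aux.encode("ascii")
            out += struct.pack("<H", (_AUX << 10) | len(data))
            out += data
            if len(data) & 1:
                out += b"\x00"
    out += struct.pack("<H", 0)  # EOF
    record_path.with_suffix("." + extension).write_bytes(bytes(out))
    if write_header:
        record_path.with_suffix(".hea").write_text(f"{record_path.name} 1 {fs:g}\n")


# ---------------------------------------------------------------------------
# pipeline output writers


def write_profiles_csv(
    path: str | Path, profiles: list[PRRxProfile], segment_ids: list[str], labels: list[str],
    *, seed: int | None = None,
) -> None:
    """Long-format profile export: ``segment_id, label, x, prrx``."""
    with open(path, "w") as f:
        f.write(_meta_line(seed))
        f.write("segment_id,label,x,prrx\n")
        for sid, lab, prof in zip(segment_ids, labels, profiles):
            for x, v in zip(prof.grid.values, prof.values):
                f.write(f"{sid},{lab},{x:g},{v}\n")


def write_segments_csv(path: str | Path, segments: list[Segment], *, seed: int | None = None) -> None:
    """Segment bookkeeping export: ``segment_id, label, start_ms, n_rr, removed_ms``."""
    with open(path, "w") as f:
        f.write(_meta_line(seed))
        f.write("segment_id,label,start_ms,n_rr,removed_ms\n")
        for s in segments:
            f.write(f"{s.id},{s.label},{s.start:g},{len(s.rr)},{s.removed_ms:g}\n")


def write_detections_csv(path: str | Path, detections: list[Detection], *, seed: int | None = None) -> None:
    """Detection export: ``segment_id, x_kind, x, score, cutoff, call``."""
    with open(path, "w") as f:
        f.write(_meta_line(seed))
        f.write("segment_id,x_kind,x,score,cutoff,call\n")
        for d in detections:
            f.write(f"{d.segment_id},{d.kind},{d.x:g},{d.score},{d.cutoff},{d.call}\n")


def write_metric_table(path: str | Path, table: pd.DataFrame, *, seed: int | None = None) -> None:
    """Metric-grid export (long format, one row per threshold x)."""
    with open(path, "w") as f:
        f.write(_meta_line(seed))
        table.to_csv(f, index=False)
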