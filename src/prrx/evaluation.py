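"""Diagnostic evaluation: ROC/AUC, Youden cutoffs, bootstrap CIs, DOR.

Conventions, fixed once:

* AF is the positive class, SR the negative class; a segment is called
  positive when its score is >= the cutoff (same boundary rule as
  classification, so calibration and deployment agree).
* ROC candidate thresholds are the unique observed scores plus a sentinel
  above the maximum; AUC is the trapezoid area, which on this threshold set
  equals the Mann–Whitney probability (concordant pairs + half the ties
  over n_pos * n_neg).
* The Youden cutoff maximises J = sensitivity + specificity - 1; ties are
  broken toward the smallest threshold.
* Bootstrap CIs are percentile (2.5th/97.5th of B replicates, default
  B = 5000); point estimates are reported as replicate medians, with the
  plug-in value kept alongside.  Resampling is unstratified over segments
  by default.  A replicate that loses one class entirely leaves sensitivity
  or specificity undefined and is re-drawn.
* Quantiles use linear interpolation between order statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .statistics import AF, SR, PRRxProfile

__all__ = [
    "LabeledScores",
    "ROCCurve",
    "ConfusionCounts",
    "MetricSet",
    "BootstrapResult",
    "roc_auc",
    "youden_cutoff",
    "confusion",
    "metrics_from_confusion",
    "bootstrap_metrics",
    "compare_parameters",
    "percentile_summary",
    "metric_grid",
]

_METRICS = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "dor")


@dataclass
class LabeledScores:
    """Per-segment scores with AF/SR truth labels (AF = positive class)."""

    scores: NDArray[np.float64]
    labels: NDArray[np.str_]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype="<U8")
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")

    def drop_undefined(self) -> tuple["LabeledScores", int]:
        """Remove NaN-scored segments; returns (cleaned, n_dropped)."""
        keep = ~np.isnan(self.scores)
        return LabeledScores(self.scores[keep], self.labels[keep]), int(np.count_nonzero(~keep))

    @property
    def positive(self) -> NDArray[np.bool_]:
        return self.labels == AF


@dataclass
class ROCCurve:
    thresholds: NDArray[np.float64]
    tpr: NDArray[np.float64]
    fpr: NDArray[np.float64]
    auc: float


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    """Diagnostic metrics in percent (DOR is a ratio, possibly inf)."""

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    dor: float
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    plugin: "MetricSet | None" = None  # plug-in (full-data) estimate alongside bootstrap medians

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in _METRICS}


@dataclass
class BootstrapResult:
    """Replicate metric vectors from B bootstrap resamples."""

    replicates: dict[str, NDArray[np.float64]]
    seed: int
    method: str = "percentile"
    n_redrawn: int = 0

    @property
    def b(self) -> int:
        return len(next(iter(self.replicates.values())))


def roc_auc(data: LabeledScores) -> ROCCurve:
    """ROC curve and AUC for AF-vs-SR discrimination.

    AUC equals the probability that a random AF segment scores above a
    random SR segment, counting ties as one half.
    """
    pos = data.positive
    if not pos.any() or pos.all():
        raise ValueError("ROC requires both classes present")
    if np.isnan(data.scores).any():
        raise ValueError("undefined scores must be dropped before ROC analysis")
    fpr, tpr, thr = _sk_roc_curve(pos, data.scores, drop_intermediate=False)
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=float(_trapezoid_auc(fpr, tpr)))


def youden_cutoff(roc: ROCCurve) -> tuple[float, float]:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Only finite candidate thresholds (the observed scores) are considered;
    ties are broken toward the smallest threshold.
    """
    finite = np.isfinite(roc.thresholds)
    j = roc.tpr[finite] - roc.fpr[finite]
    thr = roc.thresholds[finite]
    best_j = j.max()
    # thresholds are sorted descending; among maxima take the smallest one
    best_thr = thr[j >= best_j - 1e-12].min()
    return float(best_thr), float(best_j)


def confusion(data: LabeledScores, cutoff: float) -> ConfusionCounts:
    """Confusion counts at a cutoff, with score >= cutoff called positive."""
    pos = data.positive
    called = data.scores >= cutoff
    return ConfusionCounts(
        tp=int(np.count_nonzero(pos & called)),
        fp=int(np.count_nonzero(~pos & called)),
        tn=int(np.count_nonzero(~pos & ~called)),
        fn=int(np.count_nonzero(pos & ~called)),
    )


def _dor(tp: float, fp: float, tn: float, fn: float, haldane: bool = False) -> float:
    if haldane:
        tp, fp, tn, fn = tp + 0.5, fp + 0.5, tn + 0.5, fn + 0.5
    num, den = tp * tn, fp * fn
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def metrics_from_confusion(c: ConfusionCounts, *, haldane: bool = False) -> MetricSet:
    """Point diagnostic metrics from confusion counts.

    accuracy = (tp+tn)/n, sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
    PPV = tp/(tp+fp), NPV = tn/(tn+fn), all in percent;
    DOR = (tp*tn)/(fp*fn), infinite when fp*fn = 0 with tp*tn > 0, with an
    optional Haldane–Anscombe +0.5 correction.  A metric whose denominator
    is zero is NaN (undefined), never silently 0.
    """
    if c.n == 0:
        raise ValueError("empty confusion matrix")

    def _rate(num: int, den: int) -> float:
        return 100.0 * num / den if den else math.nan

    return MetricSet(
        accuracy=_rate(c.tp + c.tn, c.n),
        sensitivity=_rate(c.tp, c.tp + c.fn),
        specificity=_rate(c.tn, c.tn + c.fp),
        ppv=_rate(c.tp, c.tp + c.fp),
        npv=_rate(c.tn, c.tn + c.fn),
        dor=_dor(c.tp, c.fp, c.tn, c.fn, haldane),
    )


def _replicate_metrics(cells: NDArray[np.int64]) -> dict[str, NDArray[np.float64]]:
    """Vectorised metrics for an array of confusion cells (B, 4) = tp, fp, tn, fn."""
    tp, fp, tn, fn = (cells[:, k].astype(float) for k in range(4))
    n = tp + fp + tn + fn
    with np.errstate(divide="ignore", invalid="ignore"):
        out = {
            "accuracy": 100.0 * (tp + tn) / n,
            "sensitivity": 100.0 * tp / (tp + fn),
            "specificity": 100.0 * tn / (tn + fp),
            "ppv": np.where(tp + fp > 0, 100.0 * tp / (tp + fp), np.nan),
            "npv": np.where(tn + fn > 0, 100.0 * tn / (tn + fn), np.nan),
            "dor": np.where(fp * fn > 0, tp * tn / (fp * fn), np.where(tp * tn > 0, np.inf, np.nan)),
        }
    return out


def bootstrap_metrics(
    data: LabeledScores,
    cutoff: float,
    b: int = 5000,
    seed: int = 0,
    *,
    stratified: bool = False,
    haldane: bool = False,
) -> tuple[BootstrapResult, MetricSet]:
    """Bootstrap diagnostic metrics at a fixed cutoff.

    Each replicate resamples the n segments with replacement (unstratified
    by default; stratified resamples each class separately, preserving
    class sizes).  Because the metrics depend on a resample only through
    its confusion-cell counts, replicates are drawn directly as multinomial
    cell counts — an exact, vectorised equivalent of resampling segment
    indices.  Replicates missing one class entirely are re-drawn.

    Returns the replicate vectors and a MetricSet whose point values are
    replicate medians and whose ``ci95`` holds percentile intervals.
    """
    if b < 1:
        raise ValueError("need at least one bootstrap replicate")
    c = confusion(data, cutoff)
    if c.n == 0:
        raise ValueError("no segments to resample")
    rng = np.random.default_rng(seed)
    counts = np.array([c.tp, c.fp, c.tn, c.fn])
    n_redrawn = 0
    if stratified:
        n_pos, n_neg = c.tp + c.fn, c.fp + c.tn
        if n_pos == 0 or n_neg == 0:
            raise ValueError("stratified bootstrap requires both classes")
        pos_draw = rng.multinomial(n_pos, [c.tp / n_pos, c.fn / n_pos], size=b)
        neg_draw = rng.multinomial(n_neg, [c.fp / n_neg, c.tn / n_neg], size=b)
        cells = np.column_stack([pos_draw[:, 0], neg_draw[:, 0], neg_draw[:, 1], pos_draw[:, 1]])
    else:
        cells = rng.multinomial(c.n, counts / c.n, size=b)
        # re-draw replicates that lost one class (sens or spec undefined)
        while True:
            bad = ((cells[:, 0] + cells[:, 3]) == 0) | ((cells[:, 1] + cells[:, 2]) == 0)
            if not bad.any():
                break
            n_redrawn += int(bad.sum())
            cells[bad] = rng.multinomial(c.n, counts / c.n, size=int(bad.sum()))
    reps = _replicate_metrics(cells)
    if haldane:
        reps["dor"] = _dor_vec_haldane(cells)
    result = BootstrapResult(replicates=reps, seed=seed, n_redrawn=n_redrawn)
    point = metrics_from_confusion(c, haldane=haldane)

    def _pctl(arr: NDArray[np.float64], q: float) -> float:
        # linear interpolation is undefined between infinite order statistics
        # (infinite DOR replicates); fall back to the nearest order statistic
        if np.isinf(arr).any():
            return float(np.percentile(arr, q, method="nearest"))
        return float(np.percentile(arr, q))

    summary = MetricSet(
        **{m: float(np.median(reps[m])) for m in _METRICS},
        ci95={m: (_pctl(reps[m], 2.5), _pctl(reps[m], 97.5)) for m in _METRICS},
        plugin=point,
    )
    return result, summary


def _dor_vec_haldane(cells: NDArray[np.int64]) -> NDArray[np.float64]:
    tp, fp, tn, fn = (cells[:, k].astype(float) + 0.5 for k in range(4))
    return tp * tn / (fp * fn)


def compare_parameters(
    result_a: BootstrapResult,
    result_b: BootstrapResult,
    metric: str,
    *,
    bins: int = 50,
) -> tuple[float, float, float]:
    """Compare two parameters' bootstrap distributions of one metric.

    Returns (Welch t statistic, p value, histogram-overlap fraction).
    Overlap is the summed bin-wise minimum of the two normalised
    histograms on a shared binning: 1 for identical distributions, 0 for
    disjoint ones.  Identical replicate vectors report t = 0, p = 1.
    """
    a_all = np.asarray(result_a.replicates[metric], dtype=float)
    b_all = np.asarray(result_b.replicates[metric], dtype=float)
    if a_all.size == 0 or b_all.size == 0:
        raise ValueError("no replicates to compare")
    # infinite replicates (degenerate DOR) form a shared point mass at infinity
    inf_a = float(np.isinf(a_all).mean())
    inf_b = float(np.isinf(b_all).mean())
    a, b = a_all[np.isfinite(a_all)], b_all[np.isfinite(b_all)]
    inf_overlap = min(inf_a, inf_b)
    if a.size == 0 and b.size == 0:
        return 0.0, 1.0, 1.0
    if a.size == 0 or b.size == 0:
        return math.copysign(math.inf, inf_a - inf_b), 0.0, inf_overlap
    if np.array_equal(a, b) or (a.std() == 0 and b.std() == 0 and a[0] == b[0]):
        return 0.0, 1.0, 1.0
    if a.std() == 0 and b.std() == 0:
        return math.copysign(math.inf, a[0] - b[0]), 0.0, inf_overlap
    t, p = stats.ttest_ind(a, b, equal_var=False)
    lo, hi = min(a.min(), b.min()), max(a.max(), b.max())
    if lo == hi:
        finite_overlap = min(a.size / a_all.size, b.size / b_all.size)
    else:
        ha, edges = np.histogram(a, bins=bins, range=(lo, hi))
        hb, _ = np.histogram(b, bins=edges)
        finite_overlap = float(np.minimum(ha / a_all.size, hb / b_all.size).sum())
    return float(t), float(p), finite_overlap + inf_overlap


def percentile_summary(
    values: ArrayLike, probs: tuple[float, ...] = (10, 25, 50, 75, 90)
) -> NDArray[np.float64]:
    """Quantiles at the given percentage points, linear interpolation."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty vector")
    return np.percentile(arr, probs)


def metric_grid(
    profiles: list[PRRxProfile],
    labels: ArrayLike,
    cutoffs: dict[float, float] | None = None,
    b: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-threshold evaluation over a shared pRRx grid.

    For every threshold x of the common grid: collect the segment scores,
    drop undefined segments, calibrate a Youden cutoff (or use the supplied
    one), then bootstrap the diagnostic metrics.  Returns a long-format
    table, one row per x.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    grid = profiles[0].grid
    for p in profiles[1:]:
        if p.grid.kind != grid.kind or len(p.grid) != len(grid) or not np.array_equal(
            p.grid.values, grid.values
        ):
            raise ValueError("profiles must share one grid")
    labels = np.asarray(labels, dtype="<U8")
    score_mat = np.vstack([p.values for p in profiles])  # (n_segments, n_x)
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(grid)) % (2**31)
    for k, x in enumerate(grid.values):
        data, n_undef = LabeledScores(score_mat[:, k], labels).drop_undefined()
        roc = roc_auc(data)
        cutoff = cutoffs[float(x)] if cutoffs is not None else youden_cutoff(roc)[0]
        _, ms = bootstrap_metrics(data, cutoff, b=b, seed=int(child_seeds[k]))
        row = {
            "x_kind": grid.kind,
            "x": float(x),
            "cutoff": float(cutoff),
            "auc": roc.auc,
            "n_undefined": n_undef,
        }
        for m in _METRICS:
            short = {"accuracy": "acc", "sensitivity": "sens", "specificity": "spec"}.get(m, m)
            row[short] = getattr(ms, m)
            row[f"{short}_lo"], row[f"{short}_hi"] = ms.ci95[m]
        row["n_boot"] = b
        row["seed"] = int(child_seeds[k])
        rows.append(row)
    return pd.DataFrame(rows)
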