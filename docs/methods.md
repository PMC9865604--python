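# Methods

## The statistic and its conventions

For RR intervals `RR_1 … RR_n` (ms), the relative successive difference of
the pair `(i−1, i)` is `d_i = 100·|RR_i − RR_{i−1}| / RR_{i−1}`, normalised
by the **preceding** interval. `pRRx%` is the percentage of admissible
pairs with `d_i ≥ x`; `pRRx` (ms variant) counts `|RR_i − RR_{i−1}| ≥ x`.
Conventions fixed throughout:

* The inequality is inclusive (`≥`): a difference exactly at the threshold
  counts, and a score exactly at the decision cutoff is called AF. Using
  the same boundary rule for calibration and classification keeps the
  confusion counts of a calibrate-then-classify round trip identical.
* The denominator is the number of **admissible** pairs of the segment,
  not `n−1` of the raw series. A pair is admissible only if its two
  intervals were truly consecutive in the recording and both survived
  filtering; differences are never computed across a removed interval
  (the adjacency mask can express other policies, but skipping is the
  default and the only one used here).
* A segment with zero admissible pairs has an *undefined* statistic,
  carried as NaN — never 0 or 100 — and is excluded from calibration and
  metrics, counted separately.
* Values are percent (0–100) end to end; no internal rounding. The
  default threshold grid is 0.25–25% in 0.25% steps (100 thresholds).
* `relative_difference_at_hr(x_ms, hr) = x_ms·hr/600` gives the relative
  meaning of an absolute threshold at a given heart rate (the RR interval
  at `hr` beats/min is `60000/hr` ms); it is exact for a pair whose
  preceding interval is exactly `60000/hr`.

## Preprocessing

Durations outside [240, 3000] ms (heart rates above 250 or below
20 beats/min) are treated as technical artifacts. Both rules are strict:
240 and 3000 ms themselves are retained, and a segment is rejected only
when its removed interval time strictly exceeds 6000 ms.

Rhythm-pure segmentation tiles each maximal SR or AF run into
non-overlapping 60-s windows **anchored at the run's onset**; trailing
partial windows are dropped and other rhythms are skipped. An interval is
assigned to the half-open window containing its terminating beat — the
interval exists once its closing beat occurs. Window anchoring,
interval-to-window assignment and boundary strictness are genuine design
choices (several conventions are defensible); the ones above maximise
rhythm-pure yield, are deterministic, and are all configurable through
`SegmentationConfig`. Removed-duration bookkeeping counts only
range-filtered intervals; other-rhythm exclusions never enter a segment.

## Calibration data

The packaged cutoff table (`data/cutoffs_ltafdb_youden.csv`) maps each
percent threshold to its Youden-optimal decision cutoff derived from the
Long-Term Atrial Fibrillation Database, headed by `pRR3.25% → 75.32`.
Calibration is data, not code: the file is plain text, versioned with the
package, and SHA-256-verified at load so silent corruption cannot shift
every downstream decision.

## Evaluation

AF is the positive class. The ROC sweep uses the unique observed scores
plus a sentinel above the maximum as candidate thresholds (finite and
exact); AUC is the trapezoid area, which on this candidate set equals the
Mann–Whitney probability (concordant pairs + ½·ties)/(n₊·n₋) — the test
suite cross-checks the two routes. The Youden cutoff maximises
J = sensitivity + specificity − 1, breaking ties toward the smallest
threshold.

Diagnostic metrics: accuracy, sensitivity, specificity, PPV, NPV
(percent) and the diagnostic odds ratio DOR = (TP·TN)/(FP·FN), which is
reported as infinite when FP·FN = 0 with TP·TN > 0 (an optional
Haldane–Anscombe +0.5 correction is available behind a flag).

Confidence intervals use a nonparametric bootstrap, B = 5000 by default,
unstratified resampling of segments with replacement (a stratified mode
preserving class sizes is available). Because every metric depends on a
resample only through its four confusion-cell counts, replicates are
drawn directly as multinomial cell counts — an exact, vectorised
equivalent of resampling segment indices. Replicates that lose one class
entirely (undefined sensitivity or specificity) are re-drawn and counted.
Intervals are percentile (2.5th/97.5th); point estimates are replicate
medians, with the plug-in estimate kept alongside. BCa intervals are out
of scope.

Parameter-vs-parameter comparison applies a Welch (unequal-variance)
t-test to the two replicate vectors plus a histogram-overlap fraction
(bin-wise minimum of the normalised histograms on shared bins). Two
caveats are deliberate: a t-test on bootstrap replicates is
anti-conservative (replicates are not independent samples from the
sampling distribution), and infinite DOR replicates are treated as a
shared point mass at infinity (the t-test uses the finite parts; the
overlap adds the smaller of the two infinite fractions). Identical
vectors report t = 0, p = 1, overlap = 1.

Quantile summaries (10th/25th/50th/75th/90th percentiles) use linear
interpolation between order statistics.

## Synthetic generator

The generator reproduces the statistical contrast the detector exploits,
not cardiac electrophysiology:

| parameter | default | meaning |
|---|---|---|
| `sr_mean_rr` | 850 ms | SR mean interval (~71 bpm) |
| `sr_modulation_amp` | 40 ms | respiratory sinus-arrhythmia amplitude |
| `sr_modulation_period` | 4 s | respiratory period |
| `sr_jitter_sd` | 10 ms | white beat-to-beat jitter |
| `af_mean_rr` | 650 ms | AF mean interval (~92 bpm) |
| `af_cv` | 0.20 | AF coefficient of variation |
| `af_correlation` | 0 | target lag-1 autocorrelation |
| `artifact_rate` | 0 | per-interval out-of-range replacement probability |

SR is a sinusoid plus white jitter clipped to [240, 3000] ms; AF is
i.i.d. Gamma with shape `1/cv²` and scale `mean·cv²` (moment-matched,
positive support), serially uncorrelated by construction. Artifact
injection replaces intervals with uniform draws on [60, 239] or
[3001, 6000] ms (half below, half above) so the range filter and the 6-s
rejection rule can be exercised end to end. All randomness flows through
spawned `numpy` generator streams from a single seed; identical seeds
give byte-identical datasets.

**What the generator does and does not show.** With these defaults the SR
and AF `pRR3.25%` distributions are widely separated (typical AF relative
differences ≈ 28% versus ≲ 8% for SR even at the steepest point of the
respiratory cycle), so the packaged 75.32% cutoff classifies synthetic
segments almost perfectly, and the accuracy/AUC-versus-x curve shows the
expected high plateau at moderate x. Two features of real Holter data are
*not* emulated: class overlap (ectopy, sick-sinus variability, imperfect
annotations) and non-stationarity. Consequently the gradual degradation
of the metrics toward large x seen on real data does not appear —
synthetic classes remain separable over the whole 0.25–25% grid — and
passing tests demonstrate pipeline correctness and the direction of every
effect, not real-data effect sizes. The `af_cv = 0` degenerate case
(perfectly regular "AF") is classified SR, documenting the detector's
intrinsic blind spot to regularised ventricular response.

## Numerical and interface choices

* Profiles are computed with a single sort + `searchsorted` sweep, so the
  per-threshold values are exactly the naive counts (no binning error);
  monotonicity in x follows by construction.
* Times are milliseconds, 0-based from recording start, everywhere; WFDB
  sample indices are converted at read time using the header's sampling
  frequency. The MIT annotation format (16-bit words, 6-bit type + 10-bit
  time increment, SKIP/AUX pseudo-annotations) is parsed directly, with a
  matching writer used to build test recordings; rhythm aux strings map
  `(N → SR`, `(AFIB → AF`, anything else → OTHER (user-extensible).
* Output CSVs embed a `#`-prefixed metadata line (tool version, seed);
  readers skip it, keeping the declared column headers bit-exact.
* Problem sizes in the tests and examples — 50–200 segments per class,
  B ≤ 5000 bootstrap replicates — are the package's chosen defaults for
  desk-scale reproducibility; all are parameters.

## Known limitations

* The generator's idealised separability (above) — real-data metric
  decay at large x is out of reach without emulating class overlap.
* Ectopic-beat classification, interpolation of removed intervals, AF
  burden/episode merging and R-peak detection from raw ECG are out of
  scope.
* The calibrated cutoffs are specific to 1-min segments; other segment
  lengths require recalibration (`metric_grid` with Youden selection).
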