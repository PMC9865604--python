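"""Head-to-head comparison of a relative (pRR3.25%) and an absolute
(pRR31, i.e. x = 31 ms) parameter on the same segments.

Each parameter is calibrated with the Youden index, bootstrapped, and the
replicate distributions are compared with a Welch t-test and a
histogram-overlap fraction (0 = disjoint, 1 = identical).
"""

import numpy as np

from prrx import (
    LabeledScores,
    SynthConfig,
    bootstrap_metrics,
    compare_parameters,
    generate_dataset,
    roc_auc,
    youden_cutoff,
)
from prrx.detection import score_segment

ds = generate_dataset(SynthConfig(n_segments_per_class=150, seed=13))

boots = {}
for name, (x, kind) in {"pRR3.25%": (3.25, "percent"), "pRR31": (31.0, "ms")}.items():
    scores = np.array([score_segment(s, kind, x) for s in ds.segments])
    data, _ = LabeledScores(scores, ds.labels).drop_undefined()
    cutoff, _j = youden_cutoff(roc_auc(data))
    boots[name], metrics = bootstrap_metrics(data, cutoff, b=2000, seed=13)
    print(f"{name}: cutoff {cutoff:.2f}, median accuracy {metrics.accuracy:.2f}%")

t, p, overlap = compare_parameters(boots["pRR3.25%"], boots["pRR31"], "accuracy")
print(f"\naccuracy comparison: t = {t:.2f}, p = {p:.3g}, overlap = {overlap:.3f}")

# An overlap near 1 with p near 1 means the two parameters are effectively
# interchangeable on this dataset; a small overlap with a large |t| would
# mean one parameter dominates, as reported for pRR3.25% over pRR31 on
# real Holter recordings.
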