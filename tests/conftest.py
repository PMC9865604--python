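import numpy as np
import pytest

from prrx import SynthConfig, generate_dataset
from prrx.detection import score_segment
from prrx.evaluation import LabeledScores


@pytest.fixture(scope="session")
def dataset():
    """Small balanced synthetic dataset shared across tests (50/class)."""
    return generate_dataset(SynthConfig(n_segments_per_class=50, seed=11))


@pytest.fixture(scope="session")
def labeled_scores(dataset):
    """pRR3.25% scores with truth labels for the shared dataset."""
    scores = np.array([score_segment(s, "percent", 3.25) for s in dataset.segments])
    return LabeledScores(scores, dataset.labels).drop_undefined()[0]


def naive_prrx_percent(rr, x):
    """Brute-force double-loop oracle for pRRx% on a gap-free series."""
    count = total = 0
    for i in range(1, len(rr)):
        total += 1
        if abs(rr[i] - rr[i - 1]) / rr[i - 1] * 100.0 >= x:
            count += 1
    return 100.0 * count / total if total else float("nan")


def naive_auc(pos, neg):
    """Mann-Whitney pair-count oracle: P(pos > neg) + 0.5 P(tie)."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
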