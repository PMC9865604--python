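"""ROC/AUC, Youden cutoffs, diagnostic metrics, bootstrap and comparisons."""

import math

import numpy as np
import pytest

from prrx import (
    ConfusionCounts,
    LabeledScores,
    bootstrap_metrics,
    compare_parameters,
    confusion,
    default_percent_grid,
    metric_grid,
    metrics_from_confusion,
    percentile_summary,
    prrx_profile,
    roc_auc,
    youden_cutoff,
)

from conftest import naive_auc


def labeled(pos, neg):
    scores = np.concatenate([pos, neg]).astype(float)
    labels = np.array(["AF"] * len(pos) + ["SR"] * len(neg))
    return LabeledScores(scores, labels)


def exhaustive_youden(pos, neg):
    """Oracle: maximise J over every candidate threshold, smallest wins."""
    best = (-np.inf, None)
    for thr in sorted(set(pos) | set(neg)):
        sens = np.mean(np.asarray(pos) >= thr)
        spec = np.mean(np.asarray(neg) < thr)
        j = sens + spec - 1
        if j > best[0] + 1e-12:
            best = (j, thr)
    return best[1], best[0]


class TestROC:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([0.8, 0.6], [0.7, 0.5], 0.75),  # 3 of 4 pairs concordant
            ([5, 6, 7], [1, 2, 3], 1.0),
            ([1, 2, 3], [1, 2, 3], 0.5),  # all ties count one half
        ],
    )
    def test_auc_examples(self, pos, neg, expected):
        assert roc_auc(labeled(pos, neg)).auc == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(labeled([1, 2], []))

    def test_trapezoid_equals_mannwhitney(self):
        """Dual route: trapezoid ROC area vs brute-force pair counting."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            pos = rng.choice(np.arange(0, 101, 2.5), size=rng.integers(3, 40))
            neg = rng.choice(np.arange(0, 101, 2.5), size=rng.integers(3, 40))
            assert roc_auc(labeled(pos, neg)).auc == pytest.approx(naive_auc(pos, neg))


class TestYouden:
    def test_perfect_separation(self):
        cutoff, j = youden_cutoff(roc_auc(labeled([0.9, 0.8], [0.4, 0.2])))
        assert cutoff == pytest.approx(0.8)
        assert j == pytest.approx(1.0)

    def test_no_separation_returns_smallest_candidate(self):
        data = labeled([1, 2, 3], [1, 2, 3])
        cutoff, j = youden_cutoff(roc_auc(data))
        assert j == pytest.approx(0.0)
        assert cutoff == pytest.approx(1.0)

    def test_single_crossing_case(self):
        cutoff, j = youden_cutoff(roc_auc(labeled([10, 80, 90], [5, 20, 70])))
        oracle_cut, oracle_j = exhaustive_youden([10, 80, 90], [5, 20, 70])
        assert cutoff == pytest.approx(oracle_cut) == 80
        assert j == pytest.approx(oracle_j) == pytest.approx(2 / 3)

    def test_maximises_j_against_exhaustive_search(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pos = rng.normal(60, 20, 30)
            neg = rng.normal(40, 20, 30)
            roc = roc_auc(labeled(pos, neg))
            cutoff, j = youden_cutoff(roc)
            _, oracle_j = exhaustive_youden(pos, neg)
            assert j == pytest.approx(oracle_j)


class TestConfusionAndMetrics:
    @pytest.mark.parametrize(
        "pos, neg, cutoff, cells",
        [
            ([80, 90], [10, 20], 50, (2, 0, 2, 0)),
            ([80, 40], [60, 20], 50, (1, 1, 1, 1)),
            ([80, 40], [60, 20], 0, (2, 2, 0, 0)),
        ],
    )
    def test_confusion_counts(self, pos, neg, cutoff, cells):
        c = confusion(labeled(pos, neg), cutoff)
        assert (c.tp, c.fp, c.tn, c.fn) == cells

    def test_point_metrics(self):
        m = metrics_from_confusion(ConfusionCounts(tp=90, fp=20, tn=80, fn=10))
        assert m.sensitivity == pytest.approx(90)
        assert m.specificity == pytest.approx(80)
        assert m.accuracy == pytest.approx(85)
        assert m.ppv == pytest.approx(81.8181818)
        assert m.npv == pytest.approx(88.8888889)
        assert m.dor == pytest.approx(36)

    def test_headline_consistency(self):
        """Published sensitivity/specificity and class sizes imply the other metrics."""
        n_af, n_sr = 32_141, 32_769
        tp = round(0.9716 * n_af)
        tn = round(0.9376 * n_sr)
        m = metrics_from_confusion(ConfusionCounts(tp=tp, fp=n_sr - tn, tn=tn, fn=n_af - tp))
        assert round(m.accuracy, 2) == 95.44
        assert round(m.ppv, 2) == 93.85
        assert round(m.npv, 2) == 97.11
        assert round(m.dor) == 514

    def test_dor_identity(self):
        m = metrics_from_confusion(ConfusionCounts(tp=90, fp=20, tn=80, fn=10))
        s, p = m.sensitivity / 100, m.specificity / 100
        assert m.dor == pytest.approx((s / (1 - s)) * (p / (1 - p)))

    def test_accuracy_identity(self):
        c = ConfusionCounts(tp=31, fp=11, tn=42, fn=7)
        m = metrics_from_confusion(c)
        n_pos, n_neg = c.tp + c.fn, c.tn + c.fp
        assert m.accuracy == pytest.approx(
            (m.sensitivity * n_pos + m.specificity * n_neg) / c.n
        )

    def test_dor_degenerate_and_haldane(self):
        m = metrics_from_confusion(ConfusionCounts(tp=10, fp=0, tn=10, fn=5))
        assert math.isinf(m.dor)
        mh = metrics_from_confusion(ConfusionCounts(tp=10, fp=0, tn=10, fn=5), haldane=True)
        assert math.isfinite(mh.dor)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionCounts(0, 0, 0, 0))


class TestBootstrap:
    def test_fixed_seed_reproducible(self, labeled_scores):
        r1, m1 = bootstrap_metrics(labeled_scores, 75.32, b=200, seed=42)
        r2, m2 = bootstrap_metrics(labeled_scores, 75.32, b=200, seed=42)
        for k in r1.replicates:
            np.testing.assert_array_equal(r1.replicates[k], r2.replicates[k])
        assert m1.accuracy == m2.accuracy

    def test_degenerate_dataset_zero_width_ci(self):
        data = labeled([90] * 8, [10] * 8)
        _, m = bootstrap_metrics(data, 50, b=100, seed=0)
        assert m.ci95["accuracy"] == (100.0, 100.0)

    def test_ci_brackets_point_and_mean_consistent(self, labeled_scores):
        boot, m = bootstrap_metrics(labeled_scores, 75.32, b=1000, seed=3)
        acc = boot.replicates["accuracy"]
        plugin = m.plugin.accuracy
        lo, hi = m.ci95["accuracy"]
        assert lo <= plugin <= hi
        # replicate accuracy is unbiased for the plug-in value, so the
        # replicate mean sits within ~3 standard errors of it
        se = acc.std(ddof=1) / math.sqrt(len(acc))
        assert abs(acc.mean() - plugin) <= 3 * se + 1e-9

    def test_stratified_mode_runs(self, labeled_scores):
        _, m = bootstrap_metrics(labeled_scores, 75.32, b=200, seed=1, stratified=True)
        assert 0 <= m.accuracy <= 100

    def test_b_validation(self, labeled_scores):
        with pytest.raises(ValueError):
            bootstrap_metrics(labeled_scores, 50, b=0)


class TestCompareParameters:
    def _boot(self, vec):
        from prrx.evaluation import BootstrapResult

        return BootstrapResult(replicates={"accuracy": np.asarray(vec, float)}, seed=0)

    def test_identical_vectors(self):
        a = self._boot([90, 91, 92, 93])
        t, p, ov = compare_parameters(a, self._boot([90, 91, 92, 93]), "accuracy")
        assert (t, p, ov) == (0.0, 1.0, 1.0)

    def test_disjoint_distributions(self):
        rng = np.random.default_rng(0)
        a = self._boot(rng.normal(95, 0.5, 500))
        b = self._boot(rng.normal(80, 0.5, 500))
        t, p, ov = compare_parameters(a, b, "accuracy")
        assert ov == 0.0
        assert p < 1e-6 and t > 0

    def test_shifted_normals_significant(self):
        rng = np.random.default_rng(1)
        a = self._boot(rng.normal(90, 1, 5000))
        b = self._boot(rng.normal(89, 1, 5000))  # shift of one SD
        _, p, ov = compare_parameters(a, b, "accuracy")
        assert p < 0.001
        assert 0 < ov < 1

    def test_constant_but_different(self):
        t, p, ov = compare_parameters(self._boot([5, 5]), self._boot([3, 3]), "accuracy")
        assert math.isinf(t) and p == 0.0 and ov == 0.0


class TestPercentileSummary:
    def test_uniform_grid_closed_form(self):
        # linear interpolation between order statistics of 1..100
        out = percentile_summary(np.arange(1, 101))
        np.testing.assert_allclose(out, [10.9, 25.75, 50.5, 75.25, 90.1])

    def test_constant_vector(self):
        np.testing.assert_allclose(percentile_summary([7.0] * 9), [7] * 5)

    def test_two_values_median(self):
        assert percentile_summary([2.0, 4.0], probs=(50,))[0] == 3.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_summary([])


class TestMetricGrid:
    @pytest.fixture(scope="class")
    @staticmethod
    def grid_table(dataset):
        profiles = [prrx_profile(s.rr, s.adjacency, default_percent_grid()) for s in dataset.segments]
        return metric_grid(profiles, dataset.labels, b=50, seed=5)

    def test_one_row_per_threshold(self, grid_table):
        assert len(grid_table) == 100
        np.testing.assert_allclose(grid_table["x"], np.arange(1, 101) * 0.25)

    def test_separable_data_perfect_somewhere(self, grid_table):
        assert grid_table["auc"].max() == pytest.approx(1.0)
        assert grid_table["acc"].max() == pytest.approx(100.0)

    def test_shuffled_labels_auc_near_half(self, dataset):
        rng = np.random.default_rng(6)
        profiles = [prrx_profile(s.rr, s.adjacency, default_percent_grid()) for s in dataset.segments]
        labels = rng.permutation(dataset.labels)
        aucs = []
        for k in (10, 50, 90):
            scores = np.array([p.values[k] for p in profiles])
            data, _ = LabeledScores(scores, labels).drop_undefined()
            aucs.append(roc_auc(data).auc)
        assert all(0.35 < a < 0.65 for a in aucs)
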