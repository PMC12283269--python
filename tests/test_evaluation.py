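import numpy as np
import pytest
from sklearn.metrics import roc_auc_score, silhouette_samples

from pascl import evaluation
from pascl.evaluation import (
    ConfusionCounts,
    auc_rank,
    classification_metrics,
    compare_models,
    confusion_counts,
    metric_set_from,
    score,
    silhouette,
    subsample_evaluate,
)


class TestConfusionMetrics:
    def test_hand_arithmetic(self):
        m = classification_metrics(ConfusionCounts(tp=5, tn=3, fp=1, fn=1))
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(5 / 6)
        assert m["recall"] == pytest.approx(5 / 6)
        assert m["specificity"] == pytest.approx(0.75)
        assert m["degenerate"] == ()

    def test_zero_denominator_flags_degenerate(self):
        m = classification_metrics(ConfusionCounts(tp=0, tn=4, fp=0, fn=2))
        assert m["precision"] == 0.0
        assert "precision" in m["degenerate"]

    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(tp=4, tn=6, fp=0, fn=0))
        assert all(m[k] == 1.0 for k in ("accuracy", "precision", "recall", "specificity"))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)

    def test_counts_from_predictions(self):
        c = confusion_counts([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)


class TestAUC:
    def test_separable(self):
        assert auc_rank([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0]) == 1.0

    def test_four_pair_enumeration(self):
        # pos {0.9, 0.4}, neg {0.5, 0.1}: 3 of 4 pairs ranked correctly
        assert auc_rank([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert auc_rank([0.3] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_rank([0.1, 0.2], [1, 1])

    def test_monotone_transform_invariance(self, rng):
        s = rng.standard_normal(40)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        assert auc_rank(np.exp(s), y) == pytest.approx(auc_rank(s, y))

    def test_matches_trapezoid_and_sklearn_oracles(self, rng):
        """Rank AUC equals trapezoidal ROC integration on random instances."""
        for _ in range(500):
            n = int(rng.integers(4, 40))
            s = rng.choice(np.round(rng.standard_normal(8), 2), size=n)
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            got = auc_rank(s, y)
            assert got == pytest.approx(roc_auc_score(y, s), abs=1e-9)


class TestScore:
    def test_table_row_arithmetic(self):
        m = {"accuracy": 0.71, "precision": 0.86, "recall": 0.54,
             "specificity": 0.88, "auc": 0.90}
        assert score(m) == pytest.approx(0.778)
        assert round(score(m), 2) == 0.78

    def test_second_row_arithmetic(self):
        m = {"accuracy": 0.58, "precision": 0.67, "recall": 0.55,
             "specificity": 0.50, "auc": 0.52}
        assert score(m) == pytest.approx(0.564)
        assert round(score(m), 2) == 0.56

    def test_all_ones(self):
        m = dict.fromkeys(("accuracy", "precision", "recall", "specificity", "auc"), 1.0)
        assert score(m) == 1.0

    def test_missing_metric_rejected(self):
        with pytest.raises(ValueError, match="auc"):
            score({"accuracy": 1.0, "precision": 1.0, "recall": 1.0,
                   "specificity": 1.0})

    def test_metric_set_consistency(self, rng):
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        pred = rng.integers(0, 2, size=30)
        s = rng.random(30)
        ms = metric_set_from(y, pred, s)
        assert ms.score == pytest.approx(
            (ms.accuracy + ms.precision + ms.recall + ms.specificity + ms.auc) / 5
        )


class TestSubsample:
    def _data(self, rng, n=40):
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        s = rng.random(n)
        pred = (s > 0.5).astype(int)
        return y, pred, s

    def test_bookkeeping_10_fractions_times_10_reps(self, rng):
        y, pred, s = self._data(rng)
        per_rep, mean = subsample_evaluate(y, pred, s, reps=10, seed=1)
        assert len(per_rep) == 100
        assert len(mean) == 10

    def test_full_fraction_reproduces_full_test_metrics(self, rng):
        y, pred, s = self._data(rng)
        per_rep, _ = subsample_evaluate(y, pred, s, fractions=np.array([1.0]), seed=2)
        full = metric_set_from(y, pred, s)
        assert np.allclose(per_rep["score"], full.score)

    def test_deterministic_per_seed(self, rng):
        y, pred, s = self._data(rng)
        a, _ = subsample_evaluate(y, pred, s, seed=3)
        b, _ = subsample_evaluate(y, pred, s, seed=3)
        assert a.equals(b)


class TestCompareModels:
    def test_identical_vectors_give_p_one(self):
        t, p = compare_models([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert p == 1.0

    def test_separated_vectors_give_tiny_p(self):
        a = [0.9, 0.91, 0.89, 0.9]
        b = [0.5, 0.51, 0.49, 0.5]
        t, p = compare_models(a, b)
        assert p < 0.001
        # reference computation via the t distribution
        from scipy import stats

        ref = stats.ttest_ind(a, b, equal_var=False)
        assert p == pytest.approx(ref.pvalue)

    def test_symmetry(self):
        a = [0.8, 0.7, 0.9, 0.6]
        b = [0.4, 0.5, 0.3, 0.6]
        _, p1 = compare_models(a, b)
        _, p2 = compare_models(b, a)
        assert p1 == pytest.approx(p2)


class TestSilhouette:
    def test_tight_far_clusters(self):
        pts = np.array([0.0, 0.1, 10.0, 10.1])
        labels = np.array([0, 0, 1, 1])
        # hand value: a = 0.1, b = (10 + 9.9)/2 or similar -> ~0.99
        assert silhouette(pts, labels) == pytest.approx(0.99, abs=0.005)

    def test_all_identical_points_give_zero(self):
        pts = np.zeros((6, 2))
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert silhouette(pts, labels) == 0.0

    def test_interleaved_labels_are_negative(self):
        pts = np.array([0.0, 1.0, 2.0, 3.0])
        labels = np.array([0, 1, 0, 1])
        assert silhouette(pts, labels) < 0

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((3, 2)), np.zeros(3))

    def test_matches_sklearn_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            pts = rng.standard_normal((n, 2))
            labels = rng.integers(0, 2, size=n)
            labels[:2] = [0, 1]
            got = silhouette(pts, labels)
            want = float(np.mean(silhouette_samples(pts, labels)))
            assert got == pytest.approx(want, abs=1e-9)


class TestEmbeddingPlot:
    def test_writes_nonempty_file(self, tmp_path, rng):
        pts = rng.standard_normal((10, 2))
        labels = rng.integers(0, 2, size=10)
        path = tmp_path / "emb.png"
        evaluation.export_embedding_plot(pts, labels, path)
        assert path.exists() and path.stat().st_size > 0

    def test_empty_input_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            evaluation.export_embedding_plot(np.empty((0, 2)), [], tmp_path / "x.png")

    def test_non_2d_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="2-dim"):
            evaluation.export_embedding_plot(np.zeros((4, 3)), [0, 1, 0, 1],
                                             tmp_path / "x.png")
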