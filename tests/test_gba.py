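import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata

from harmonet import (
    ClassifierConfig,
    GbaTask,
    GeneAttributeMatrix,
    assemble_features,
    compute_metrics,
    make_pair_task,
    monotonize_fdr,
    pca_reduce,
    predict_with_fdr,
    rank_features_by_roc,
    train_multilabel,
    train_oob_ensemble,
)
from harmonet.gba import _bare_task


def simple_task(X, labels, n_blocks=1):
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    edges = np.linspace(0, p, n_blocks + 1).astype(int)
    blocks = {f"d{i}": (edges[i], edges[i + 1]) for i in range(n_blocks)}
    return GbaTask(
        feature_matrix=X,
        example_ids=[f"g{i}" for i in range(X.shape[0])],
        labels=list(labels),
        feature_blocks=blocks,
    )


class TestPcaReduce:
    def test_rank_one_matrix_needs_one_component(self, rng):
        X = np.outer(rng.normal(size=30), rng.normal(size=10))
        scores, explained = pca_reduce(X, 0.99)
        assert scores.shape[1] == 1
        assert explained[0] == pytest.approx(1.0)

    def test_isotropic_data_needs_both_components(self, rng):
        X = rng.normal(size=(500, 2))
        scores, explained = pca_reduce(X, 0.99)
        assert scores.shape[1] == 2

    def test_component_count_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(50, 20)) @ np.diag(np.linspace(3, 0.1, 20))
        scores, explained = pca_reduce(X, 0.99)
        # oracle: full eigendecomposition of the covariance matrix
        centered = X - X.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(centered.T @ centered))[::-1]
        cum = np.cumsum(eigvals) / eigvals.sum()
        k_oracle = int(np.searchsorted(cum, 0.99 - 1e-12) + 1)
        assert scores.shape[1] == k_oracle
        assert np.sum(explained) >= 0.99
        assert np.sum(explained[:-1]) < 0.99

    def test_constant_matrix_gives_zero_components(self):
        with pytest.warns(UserWarning, match="no variance"):
            scores, explained = pca_reduce(np.ones((5, 3)), 0.99)
        assert scores.shape == (5, 0) and explained == []

    def test_bad_variance_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_reduce(rng.normal(size=(5, 3)), 0.0)

    def test_projection_is_deterministic(self, rng):
        X = rng.normal(size=(40, 12))
        s1, _ = pca_reduce(X, 0.99)
        s2, _ = pca_reduce(X, 0.99)
        assert np.array_equal(s1, s2)


class TestAssembleFeatures:
    def make_datasets(self, rng):
        genes1 = [f"g{i}" for i in range(20)]
        genes2 = [f"g{i}" for i in range(10, 30)]
        d1 = GeneAttributeMatrix(genes1, [f"a{j}" for j in range(6)],
                                 rng.normal(size=(20, 6)), "raw_continuous",
                                 metadata={"name": "d1"})
        d2 = GeneAttributeMatrix(genes2, [f"b{j}" for j in range(8)],
                                 rng.normal(size=(20, 8)), "raw_continuous",
                                 metadata={"name": "d2"})
        return d1, d2

    def test_blocks_concatenate_with_provenance(self, rng):
        d1, d2 = self.make_datasets(rng)
        task = assemble_features([d1, d2], [f"g{i}" for i in range(30)])
        starts = [task.feature_blocks["d1"][0], task.feature_blocks["d2"][0]]
        assert starts == sorted(starts)
        assert task.feature_blocks["d1"][1] == task.feature_blocks["d2"][0]
        assert task.feature_matrix.shape[1] == task.feature_blocks["d2"][1]

    def test_gene_missing_from_a_dataset_zero_filled(self, rng):
        d1, d2 = self.make_datasets(rng)
        task = assemble_features([d1, d2], ["g0"])  # g0 absent from d2
        start, stop = task.feature_blocks["d2"]
        assert np.all(task.feature_matrix[0, start:stop] == 0)

    def test_gene_absent_everywhere_dropped_with_warning(self, rng):
        d1, d2 = self.make_datasets(rng)
        with pytest.warns(UserWarning, match="absent from every dataset"):
            task = assemble_features([d1, d2], ["g0", "nowhere"])
        assert task.example_ids == ["g0"]

    def test_empty_dataset_list_rejected(self):
        with pytest.raises(ValueError, match="empty dataset list"):
            assemble_features([], ["g0"])


class TestRankFeatures:
    def test_perfect_separator_ranks_first(self, rng):
        labels = ["positive"] * 10 + ["negative"] * 10
        X = np.column_stack([
            np.concatenate([np.ones(10), np.zeros(10)]),  # perfect
            rng.normal(size=20),                          # noise
        ])
        ranking = rank_features_by_roc(simple_task(X, labels))
        assert ranking.iloc[0]["feature"] == 0
        assert ranking.iloc[0]["auc"] == pytest.approx(1.0)

    def test_anti_correlated_separator_ranks_equally_high(self, rng):
        labels = ["positive"] * 10 + ["negative"] * 10
        X = np.column_stack([
            np.concatenate([np.zeros(10), np.ones(10)]),  # inverted perfect
            rng.normal(size=20),
        ])
        ranking = rank_features_by_roc(simple_task(X, labels))
        assert ranking.iloc[0]["feature"] == 0
        assert ranking.iloc[0]["auc"] == pytest.approx(0.0)

    def test_independent_feature_near_half(self, rng):
        labels = ["positive"] * 500 + ["negative"] * 500
        X = rng.normal(size=(1000, 1))
        ranking = rank_features_by_roc(simple_task(X, labels))
        assert ranking.iloc[0]["auc"] == pytest.approx(0.5, abs=0.06)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            simple_task(np.zeros((4, 2)), ["positive"] * 4)


class TestComputeMetrics:
    def test_perfect_scores(self):
        curves = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert curves.auc == pytest.approx(1.0)
        assert curves.max_f1 == pytest.approx(1.0)
        assert curves.max_mcc == pytest.approx(1.0)

    def test_inverted_perfect_scores(self):
        curves = compute_metrics([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert curves.auc == pytest.approx(0.0)

    def test_confusion_count_example(self):
        # TP=8, FP=2, FN=2, TN=8 at the 1.0 threshold
        scores = [1.0] * 10 + [0.0] * 10
        labels = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
        curves = compute_metrics(scores, labels)
        i = list(curves.thresholds).index(1.0)
        assert curves.f1_by_threshold[i] == pytest.approx(0.8)
        assert curves.mcc_by_threshold[i] == pytest.approx(0.6)

    def test_auc_equals_mann_whitney_u(self, rng):
        for _ in range(100):
            n_pos = int(rng.integers(3, 50))
            n_neg = int(rng.integers(3, 50))
            scores = np.round(rng.normal(size=n_pos + n_neg), 1)  # force ties
            labels = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
            curves = compute_metrics(scores, labels)
            u = mannwhitneyu(scores[:n_pos], scores[n_pos:]).statistic
            assert curves.auc == pytest.approx(u / (n_pos * n_neg), abs=1e-12)

    def test_roc_is_monotone_and_auc_is_trapezoid(self, rng):
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80)
        labels[:2] = [0, 1]
        curves = compute_metrics(scores, labels)
        assert np.all(np.diff(curves.roc_points[:, 0]) >= 0)
        assert np.all(np.diff(curves.roc_points[:, 1]) >= 0)
        area = np.trapezoid(curves.roc_points[:, 1], curves.roc_points[:, 0])
        assert curves.auc == pytest.approx(area)

    def test_bounds_on_small_confusion_grid(self):
        """Exhaustive check over confusion matrices with small totals:
        computed F1/MCC match direct formula arithmetic and bounds."""
        for tp in range(0, 8):
            for fp in range(0, 8):
                for fn in range(0, 8):
                    for tn in range(0, 8):
                        if tp + fn == 0 or fp + tn == 0:
                            continue
                        scores = [1.0] * (tp + fp) + [0.0] * (fn + tn)
                        labels = [1] * tp + [0] * fp + [1] * fn + [0] * tn
                        curves = compute_metrics(scores, labels)
                        i = list(curves.thresholds).index(1.0) if 1.0 in curves.thresholds else None
                        if i is None:
                            continue
                        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
                        denom = np.sqrt(
                            float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
                        )
                        mcc = (tp * tn - fp * fn) / denom if denom else 0.0
                        assert curves.f1_by_threshold[i] == pytest.approx(f1)
                        assert curves.mcc_by_threshold[i] == pytest.approx(mcc)
                        assert -1 <= curves.mcc_by_threshold[i] <= 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            compute_metrics([0.1, 0.2], [1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_metrics([0.1, 0.2], [1, 1])


class TestTrainOob:
    def planted_separable(self, rng, n=200, n_informative=5, shift=3.0):
        n_pos = n // 2
        X = rng.normal(size=(n, 20))
        X[:n_pos, :n_informative] += shift
        labels = ["positive"] * n_pos + ["negative"] * (n - n_pos)
        return simple_task(X, labels)

    def test_separable_task_reaches_high_oob_auc(self, rng):
        task = self.planted_separable(rng)
        config = ClassifierConfig(n_trees=100, n_features=20, rng_seed=1)
        _, curves = train_oob_ensemble(task, config)
        assert curves.auc >= 0.95

    def test_shuffled_labels_destroy_signal(self, rng):
        task = self.planted_separable(rng)
        shuffled = list(rng.permutation(task.labels))
        task_null = simple_task(task.feature_matrix, shuffled)
        config = ClassifierConfig(n_trees=100, n_features=20, rng_seed=1)
        _, curves = train_oob_ensemble(task_null, config)
        assert 0.4 <= curves.auc <= 0.6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            simple_task(np.zeros((6, 2)), ["positive"] * 6)

    def test_n_features_clipped_with_warning(self, rng):
        task = self.planted_separable(rng, n=60)
        config = ClassifierConfig(n_trees=20, n_features=100, rng_seed=0)
        with pytest.warns(UserWarning, match="clipping"):
            model, _ = train_oob_ensemble(task, config)
        assert len(model.feature_indices) == 20

    def test_identical_seed_gives_identical_oob_scores(self, rng):
        task = self.planted_separable(rng, n=100)
        config = ClassifierConfig(n_trees=50, n_features=20, rng_seed=9)
        _, c1 = train_oob_ensemble(task, config)
        _, c2 = train_oob_ensemble(task, config)
        assert np.array_equal(c1.oob_scores, c2.oob_scores)


class TestMultilabel:
    def test_label_without_positives_skipped(self, rng):
        n = 80
        X = rng.normal(size=(n, 10))
        L = np.zeros((n, 3), dtype=int)
        L[: n // 2, 0] = 1
        X[: n // 2, 0] += 3.0
        L[n // 2 :, 1] = 1
        X[n // 2 :, 1] += 3.0
        task = _bare_task(X, [f"g{i}" for i in range(n)], ["unknown"] * n,
                          {"d0": (0, 10)}, label_matrix=L,
                          label_names=["lab0", "lab1", "lab2"])
        models, pooled, skipped = train_multilabel(
            task, ClassifierConfig(n_trees=50, n_features=10, rng_seed=3)
        )
        assert skipped == ["lab2"]
        assert set(models) == {"lab0", "lab1"}
        assert pooled.auc >= 0.9  # each label driven by its own feature

    def test_all_labels_skipped_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        L = np.zeros((20, 2), dtype=int)
        task = _bare_task(X, [f"g{i}" for i in range(20)], ["unknown"] * 20,
                          {"d0": (0, 4)}, label_matrix=L)
        with pytest.raises(ValueError, match="skipped"):
            train_multilabel(task, ClassifierConfig(n_trees=10, n_features=4))


class TestFdr:
    def test_monotonization_is_a_running_maximum(self):
        out = monotonize_fdr([0.1, 0.3, 0.2])
        assert out.tolist() == [0.1, 0.3, 0.3]

    def test_perfect_model_has_zero_fdr_at_top(self, rng, gba_fixture):
        datasets, labels, hidden = gba_fixture
        config = ClassifierConfig(n_trees=100, rng_seed=5)
        task = assemble_features(datasets, list(labels), config, labels=labels)
        model, curves = train_oob_ensemble(task, config)
        preds = predict_with_fdr(model, task, curves)
        assert preds[0].estimated_fdr == pytest.approx(0.0, abs=0.05)
        fdrs = [p.estimated_fdr for p in preds]
        assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))

    def test_unattainable_level_returns_empty_with_warning(self, rng):
        labels = list(rng.permutation(["positive"] * 20 + ["negative"] * 20))
        task = simple_task(rng.normal(size=(50, 5)), labels + ["unknown"] * 10)
        config = ClassifierConfig(n_trees=30, n_features=5, rng_seed=2)
        model, curves = train_oob_ensemble(task, config)
        with pytest.warns(UserWarning, match="no prediction attains"):
            preds = predict_with_fdr(model, task, curves, fdr_level=-0.1)
        assert preds == []

    def test_fdr_complements_oob_precision(self):
        """OOB precision 1/3 at a threshold gives estimated FDR 2/3."""
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.05])
        labels = np.array([1, 0, 0, 1, 0, 0])
        curves = compute_metrics(scores, labels)
        from harmonet.gba import _fdr_by_threshold

        fdr = _fdr_by_threshold(curves)
        i = list(curves.thresholds).index(0.7)
        assert fdr[i] == pytest.approx(2 / 3)


class TestPairTask:
    def test_pair_features_concatenate_both_genes(self, rng):
        left = simple_task(rng.normal(size=(6, 3)),
                           ["positive", "negative"] * 3)
        right = simple_task(rng.normal(size=(6, 4)),
                            ["positive", "negative"] * 3)
        pairs = [("g0", "g1"), ("g2", "g3")]
        task = make_pair_task(left, right, pairs, ["positive", "negative"])
        assert task.feature_matrix.shape == (2, 7)
        assert task.task_kind == "pair"
        assert np.array_equal(task.feature_matrix[0, :3], left.feature_matrix[0])
        assert np.array_equal(task.feature_matrix[0, 3:], right.feature_matrix[1])

    def test_unfeaturizable_pairs_rejected(self, rng):
        left = simple_task(rng.normal(size=(4, 2)), ["positive", "negative"] * 2)
        right = simple_task(rng.normal(size=(4, 2)), ["positive", "negative"] * 2)
        with pytest.raises(ValueError, match="no pair"):
            make_pair_task(left, right, [("gX", "gY")], ["positive"])
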