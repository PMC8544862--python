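"""The HOTS pipeline steps and the cross-validated driver."""

import numpy as np
import pytest

import hots
from conftest import make_decomp


def correct(conf, cls, names=None, contributions=(1.0, 0.0), sample_id=None):
    p = conf if cls == 1 else 1.0 - conf
    return make_decomp(
        contributions, probability=p, predicted_class=cls, true_class=cls,
        names=names, sample_id=sample_id,
    )


def incorrect(conf, cls, sample_id=None):
    p = conf if cls == 1 else 1.0 - conf
    return make_decomp(
        [1.0, 0.0], probability=p, predicted_class=cls, true_class=1 - cls,
        sample_id=sample_id,
    )


class TestFilterPredictions:
    def test_boundary_kept_at_equality(self):
        dropped = correct(0.69, 1)
        kept = correct(0.70, 1)
        assert hots.filter_predictions([dropped, kept], 0.7) == [kept]

    def test_empty_input(self):
        assert hots.filter_predictions([], 0.7) == []

    def test_missing_true_class_rejected(self):
        d = make_decomp([1.0], probability=0.9, predicted_class=1, true_class=None)
        with pytest.raises(ValueError, match="true_class"):
            hots.filter_predictions([d], 0.7)

    def test_hand_enumerated_retention(self):
        """6 confident-correct, 2 under-confident-correct, 2 incorrect -> 6."""
        keepers = [correct(c, cls, sample_id=i) for i, (c, cls) in
                   enumerate([(0.9, 1), (0.75, 0), (0.7, 1), (0.99, 0),
                              (0.8, 1), (0.71, 0)])]
        losers = [correct(0.69, 1, sample_id=6), correct(0.5, 0, sample_id=7),
                  incorrect(0.95, 1, sample_id=8), incorrect(0.6, 0, sample_id=9)]
        out = hots.filter_predictions(keepers + losers, 0.7)
        assert [d.sample_id for d in out] == [0, 1, 2, 3, 4, 5]

    def test_raising_threshold_is_monotone(self):
        decomps = [correct(c, 1) for c in np.linspace(0.5, 1.0, 11)]
        sizes = [len(hots.filter_predictions(decomps, t))
                 for t in np.linspace(0.0, 1.0, 21)]
        assert sizes == sorted(sizes, reverse=True)


class TestSplitByClass:
    def test_all_positive_leaves_negative_empty(self):
        parts = hots.split_by_class([correct(0.9, 1), correct(0.8, 1)])
        assert parts["negative"] == []
        assert len(parts["positive"]) == 2

    def test_partition_sizes_sum(self):
        decomps = [correct(0.9, i % 2) for i in range(6)]
        parts = hots.split_by_class(decomps)
        assert len(parts["positive"]) + len(parts["negative"]) == 6

    def test_membership_and_orientation(self):
        pos = correct(0.9, 1, contributions=(0.5, -0.2))
        neg = correct(0.8, 0, contributions=(0.5, -0.2))
        parts = hots.split_by_class([pos, neg])
        np.testing.assert_array_equal(parts["positive"][0].contributions, [0.5, -0.2])
        # class-0 members are re-expressed as class-0 log odds
        np.testing.assert_array_equal(parts["negative"][0].contributions, [-0.5, 0.2])


class TestAggregateWeights:
    def test_single_decomposition_is_identity(self):
        d = correct(0.9, 1, contributions=(0.3, -0.1))
        np.testing.assert_allclose(hots.aggregate_weights([d]), [0.3, -0.1])

    def test_hand_average(self):
        decomps = [correct(0.9, 1, contributions=c)
                   for c in [(1.0, 0.0), (0.5, 0.5), (1.5, -0.5)]]
        np.testing.assert_allclose(hots.aggregate_weights(decomps), [1.0, 0.0])

    def test_empty_set_warns_and_zeroes(self, caplog):
        with caplog.at_level("WARNING"):
            out = hots.aggregate_weights([], feature_names=["a", "b"])
        np.testing.assert_array_equal(out, [0.0, 0.0])
        assert "no retained predictions" in caplog.text

    def test_zero_feature_stays_zero(self):
        decomps = [correct(0.9, 1, contributions=(1.0, 0.0)) for _ in range(3)]
        assert hots.aggregate_weights(decomps)[1] == 0.0


class TestInferSigns:
    def test_direct_application_of_rule(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0, 0, 1, 1])  # class-1 mean larger -> s = +1
        pos, neg = hots.infer_signs(np.array([0.8]), np.array([0.6]), X, y)
        assert pos[0] == pytest.approx(0.8)
        assert neg[0] == pytest.approx(-0.6)

    def test_equal_class_means_zeroed_with_warning(self, caplog):
        X = np.array([[1.0], [2.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        with caplog.at_level("WARNING"):
            pos, neg = hots.infer_signs(np.array([0.8]), np.array([0.6]), X, y)
        assert pos[0] == 0.0 and neg[0] == 0.0
        assert "equal class means" in caplog.text

    def test_negating_a_column_flips_both_weights(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        pos1, neg1 = hots.infer_signs(np.array([0.5, 0.4]), np.array([0.3, 0.2]), X, y)
        X2 = X.copy()
        X2[:, 1] *= -1
        pos2, neg2 = hots.infer_signs(np.array([0.5, 0.4]), np.array([0.3, 0.2]), X2, y)
        assert pos2[1] == -pos1[1] and neg2[1] == -neg1[1]
        assert pos2[0] == pos1[0] and neg2[0] == neg1[0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class means"):
            hots.infer_signs(
                np.array([1.0]), np.array([1.0]), np.array([[1.0], [2.0]]),
                np.array([1, 1]),
            )


class TestStratifiedFolds:
    def test_partition_is_disjoint_and_complete(self):
        y = np.array([0, 1] * 25)
        folds = hots.stratified_folds(y, 5, seed=3)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == 50
        assert len(np.unique(all_idx)) == 50

    def test_stratification_balance(self):
        y = np.array([0] * 40 + [1] * 10)
        for fold in hots.stratified_folds(y, 5, seed=0):
            assert y[fold].sum() == 2  # 10 positives spread over 5 folds

    def test_invariant_under_label_complement(self):
        y = (np.random.default_rng(5).random(40) < 0.4).astype(int)
        a = hots.stratified_folds(y, 4, seed=9)
        b = hots.stratified_folds(1 - y, 4, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)


@pytest.fixture(scope="module")
def planted_result():
    X, y = hots.make_synthetic(hots.SyntheticSpec(seed=1))
    return X, y, hots.run_hots(X, y, hots.HOTSConfig(seed=1))


class TestRunHots:
    def test_planted_feature_recovered(self, planted_result):
        """Feature f0 (class-1 mean higher) dominates, positive, in all folds."""
        _, _, res = planted_result
        mag = np.maximum(np.abs(res.mean_positive), np.abs(res.mean_negative))
        assert int(np.argmax(mag)) == 0
        assert res.mean_positive[0] > 0
        assert res.fold_counts[0] == 5

    def test_mean_accuracy_is_mean_of_folds(self, planted_result):
        _, _, res = planted_result
        assert res.mean_accuracy == pytest.approx(np.mean(res.per_fold_accuracy))

    def test_fold_counts_bounded_by_k(self, planted_result):
        _, _, res = planted_result
        assert (res.fold_counts >= 0).all() and (res.fold_counts <= 5).all()

    def test_label_complement_swaps_class_weight_vectors_exactly(self, planted_result):
        """Complementing the labels exchanges the two signed weight vectors.

        Oriented per-prediction weights are invariant under the complement
        (contributions negate, the predicted class flips, orientation
        negates again), the class partitions swap, and the sign rule's s
        flips while the negative class uses -s — so the positive and
        negative vectors exchange roles bitwise.
        """
        X, y, res = planted_result
        res_flip = hots.run_hots(X, 1 - y, hots.HOTSConfig(seed=1))
        np.testing.assert_array_equal(res_flip.mean_positive, res.mean_negative)
        np.testing.assert_array_equal(res_flip.mean_negative, res.mean_positive)
        np.testing.assert_array_equal(res_flip.fold_counts, res.fold_counts)
        assert res_flip.per_fold_accuracy == res.per_fold_accuracy

    def test_fold_counts_op_matches_result(self, planted_result):
        _, _, res = planted_result
        np.testing.assert_array_equal(hots.fold_counts(res), res.fold_counts)

    def test_present_only_average_geq_in_magnitude(self):
        X, y = hots.make_synthetic(hots.SyntheticSpec(n_samples=120, seed=4))
        cfg_all = hots.HOTSConfig(seed=4, train_cfg=hots.TrainConfig(n_trees=20))
        cfg_pres = hots.HOTSConfig(
            seed=4, fold_average="present", train_cfg=hots.TrainConfig(n_trees=20)
        )
        res_all = hots.run_hots(X, y, cfg_all)
        res_pres = hots.run_hots(X, y, cfg_pres)
        assert (
            np.abs(res_pres.mean_positive) >= np.abs(res_all.mean_positive) - 1e-12
        ).all()

    def test_too_few_samples_per_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        y = np.array([0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="per class"):
            hots.run_hots(X, y, hots.HOTSConfig(k_folds=5))

    def test_degenerate_labels_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValueError, match="degenerate labels"):
            hots.run_hots(X, np.ones(20, dtype=int))


class TestFoldCounts:
    def _result(self, pos_by_fold, neg_by_fold):
        per_fold = [
            hots.ClassImportance(
                positive_weights=np.asarray(p, dtype=float),
                negative_weights=np.asarray(n, dtype=float),
                n_retained_pos=1,
                n_retained_neg=1,
                fold_index=i,
            )
            for i, (p, n) in enumerate(zip(pos_by_fold, neg_by_fold))
        ]
        k = len(per_fold)
        return hots.HOTSResult(
            feature_names=["a"],
            per_fold=per_fold,
            mean_positive=np.zeros(1),
            mean_negative=np.zeros(1),
            fold_counts=np.zeros(1, dtype=int),
            per_fold_accuracy=[1.0] * k,
            mean_accuracy=1.0,
        )

    def test_zero_everywhere_counts_zero(self):
        res = self._result([[0.0]] * 5, [[0.0]] * 5)
        assert hots.fold_counts(res)[0] == 0

    def test_counts_nonzero_folds(self):
        pos = [[0.0], [0.5], [0.0], [0.1], [0.0]]
        neg = [[0.0], [0.0], [0.2], [0.0], [0.0]]
        assert hots.fold_counts(self._result(pos, neg))[0] == 3
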