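import numpy as np
import pytest

import sersclass as sc
from sersclass.crossval import (
    Classifier,
    CVResult,
    GridSpec,
    Reduction,
    cross_validate,
    knn_classify,
    make_folds,
    run_grid,
    svm_classify,
)

LABELS_51 = np.array(["control"] * 37 + ["trc"] * 14, dtype=object)


class TestMakeFolds:
    def test_study_fold_structure(self):
        plan = make_folds(LABELS_51, seed=0)
        assert plan.fold_count == 14
        for f in range(14):
            te = plan.test_indices(f)
            assert int(np.sum(LABELS_51[te] == "trc")) == 1
            assert int(np.sum(LABELS_51[te] == "control")) in (2, 3)
        sizes = sorted(np.bincount(plan.assignment).tolist())
        # 37 controls round-robin over 14 folds: nine folds of 3, five of 2
        assert sizes == [3] * 5 + [4] * 9

    def test_balanced_classes_one_each(self):
        labels = np.array(["control", "trc"] * 4, dtype=object)
        plan = make_folds(labels, fold_count=4, seed=1)
        for f in range(4):
            te = labels[plan.test_indices(f)]
            assert sorted(te) == ["control", "trc"]

    def test_seed_determinism_and_variation(self):
        a = make_folds(LABELS_51, seed=5)
        b = make_folds(LABELS_51, seed=5)
        c = make_folds(LABELS_51, seed=6)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        assert not np.array_equal(a.assignment, c.assignment)

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        perm = rng.permutation(51)
        a = make_folds(LABELS_51, seed=3)
        b = make_folds(LABELS_51[perm], seed=3)
        # same multiset of per-fold class compositions
        def comp(plan, labels):
            return sorted(
                tuple(sorted(labels[plan.test_indices(f)])) for f in range(plan.fold_count)
            )
        assert comp(a, LABELS_51) == comp(b, LABELS_51[perm])

    def test_fold_count_capped_by_minority(self):
        with pytest.raises(ValueError, match="minority"):
            make_folds(LABELS_51, fold_count=15)
        with pytest.raises(ValueError, match="absent"):
            make_folds(np.array(["control"] * 5, dtype=object))


class TestKNN:
    def test_nearest_neighbour_vote(self):
        train = np.array([[0.0], [10.0]])
        y = np.array(["control", "trc"], dtype=object)
        assert knn_classify(train, y, np.array([[1.0]]), k=1)[0] == "control"
        assert knn_classify(train, y, np.array([[9.0]]), k=1)[0] == "trc"

    def test_k1_training_accuracy_is_one_on_distinct_points(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = np.array(["control"] * 14 + ["trc"] * 6, dtype=object)
        pred = knn_classify(X, y, X, k=1)
        assert np.mean(pred == y) == 1.0

    def test_k_equal_training_size_returns_majority(self):
        X = np.array([[0.0], [1.0], [2.0], [50.0]])
        y = np.array(["control"] * 3 + ["trc"], dtype=object)
        pred = knn_classify(X, y, np.array([[100.0]]), k=4)
        assert pred[0] == "control"

    def test_even_k_vote_tie_goes_to_nearest(self):
        X = np.array([[0.0], [3.0]])
        y = np.array(["control", "trc"], dtype=object)
        assert knn_classify(X, y, np.array([[1.0]]), k=2)[0] == "control"
        assert knn_classify(X, y, np.array([[2.0]]), k=2)[0] == "trc"

    def test_distance_tie_prefers_lower_index(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array(["trc", "control"], dtype=object)
        assert knn_classify(X, y, np.array([[0.0]]), k=1)[0] == "trc"

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            knn_classify(np.empty((0, 2)), np.array([], dtype=object), np.zeros((1, 2)), k=1)


class TestSVM:
    def test_separable_clusters(self):
        X = np.array([[0.0], [0.5], [10.0], [10.5]])
        y = np.array(["control", "control", "trc", "trc"], dtype=object)
        pred = svm_classify(X, y, np.array([[1.0], [9.0]]), kernel="linear")
        assert pred.tolist() == ["control", "trc"]

    def test_duplicating_training_points_leaves_predictions_unchanged(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(4, 1, (10, 2))])
        y = np.array(["control"] * 10 + ["trc"] * 10, dtype=object)
        test = rng.normal(2, 2, (20, 2))
        base = svm_classify(X, y, test, kernel="linear")
        doubled = svm_classify(np.vstack([X, X]), np.concatenate([y, y]), test, kernel="linear")
        assert base.tolist() == doubled.tolist()

    def test_rbf_solves_xor(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array(["control", "control", "trc", "trc"], dtype=object)
        pred = svm_classify(X, y, X, kernel="rbf")
        assert np.mean(pred == y) == 1.0

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            svm_classify(np.zeros((2, 1)), np.array(["control", "trc"], dtype=object),
                         np.zeros((1, 1)), kernel="quantum")


class TestAggregation:
    def test_printed_fold_multiset_reproduces_study_numbers(self):
        res = CVResult.from_fold_accuracies([1.0] * 13 + [0.75])
        assert f"{res.cv_acc:.3f}" == "0.982"
        assert f"{res.cv_std:.3f}" == "0.064"
        res2 = CVResult.from_fold_accuracies([1.0] * 13 + [2.0 / 3.0])
        assert f"{res2.cv_acc:.3f}" == "0.976"

    def test_population_std_discriminator(self):
        # sample (n-1) std would give 0.067; the population formula gives 0.064
        accs = np.array([1.0] * 13 + [0.75])
        assert f"{np.std(accs, ddof=1):.3f}" == "0.067"
        assert f"{CVResult.from_fold_accuracies(accs).cv_std:.3f}" == "0.064"

    def test_perfect_folds(self):
        res = CVResult.from_fold_accuracies([1.0] * 14, [1.0] * 14)
        assert res.cv_acc == 1.0 and res.cv_std == 0.0 and not res.overfit

    def test_overfit_flag(self):
        res = CVResult.from_fold_accuracies([0.8] * 5, [1.0] * 5)
        assert res.overfit

    def test_invalid_accuracies_rejected(self):
        with pytest.raises(ValueError):
            CVResult.from_fold_accuracies([1.2])
        with pytest.raises(ValueError):
            CVResult.from_fold_accuracies([])


def _separable_set(n0=12, n1=6, p=8, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n0 + n1, p))
    X[n0:, :3] += gap
    labels = np.array(["control"] * n0 + ["trc"] * n1, dtype=object)
    return X, labels


class TestCrossValidate:
    def test_separable_data_perfect_cv(self):
        X, labels = _separable_set()
        plan = make_folds(labels, seed=0)
        res = cross_validate(X, labels, plan, Classifier("svm", kernel="linear"),
                             Reduction("t", 5))
        assert res.cv_acc == 1.0
        assert res.mode == "safe"

    def test_paper_mode_recorded_and_uses_full_data_selection(self):
        X, labels = _separable_set()
        plan = make_folds(labels, seed=0)
        res = cross_validate(X, labels, plan, Classifier("knn", k=1),
                             Reduction("w", 5), paper_mode=True)
        assert res.mode == "paper"
        assert res.dimensions == 5

    def test_knn1_training_accuracy_column_is_one(self):
        X, labels = _separable_set()
        plan = make_folds(labels, seed=1)
        res = cross_validate(X, labels, plan, Classifier("knn", k=1))
        assert res.train_cv == 1.0 and res.train_std == 0.0

    def test_cv_acc_is_exact_mean_of_folds(self):
        X, labels = _separable_set(gap=0.5, seed=3)
        plan = make_folds(labels, seed=3)
        res = cross_validate(X, labels, plan, Classifier("knn", k=3), Reduction("t", 4))
        assert res.cv_acc == pytest.approx(np.mean(res.fold_accuracies), abs=0)


class TestRunGrid:
    def test_cartesian_row_count_and_sorting(self, default_set):
        sset, _ = default_set
        spec = GridSpec(
            data_types=("peaks",),
            normalizations=(False,),
            reductions=(Reduction("t", 10), Reduction("w", 10)),
            classifiers=(Classifier("knn", k=1), Classifier("svm", kernel="linear")),
        )
        results = run_grid(sset, spec, seed=0, paper_mode=True)
        assert len(results) == 4
        accs = [r.cv_acc for r in results]
        assert accs == sorted(accs, reverse=True)

    def test_grid_rows_carry_overfit_flag_and_schema(self, default_set, tmp_path):
        sset, _ = default_set
        spec = GridSpec(
            data_types=("peaks",),
            normalizations=(False,),
            reductions=(Reduction("t", 10, pca_dims=3),),
            classifiers=(Classifier("knn", k=1),),
        )
        results = run_grid(sset, spec, seed=0, paper_mode=True)
        r = results[0]
        assert r.reduction_method == "t-score + PCA = 3"
        assert r.overfit == (r.train_cv > r.cv_acc)
        sc.write_results_table(results, tmp_path / "res.csv")
        header = (tmp_path / "res.csv").read_text().splitlines()[0]
        for col in ("classifier", "reduction_method", "dimensions", "cv_acc",
                    "cv_std", "train_cv", "train_std", "overfit", "mode"):
            assert col in header

    def test_empty_grid_rejected(self, default_set):
        sset, _ = default_set
        with pytest.raises(ValueError, match="empty grid"):
            run_grid(sset, GridSpec(reductions=()), seed=0)
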