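import numpy as np
import pandas as pd
import pytest

from gazemem import (
    DataError,
    FeatureDataset,
    FeatureSetSpec,
    MemSpec,
    evaluate,
    knn_classify,
    loso_split,
    n_classifier_runs,
    run_loso,
)
from gazemem.classify import _knn_predict
from oracles import knn_bruteforce, metrics_bruteforce

MSPEC = MemSpec()


def _dataset(X, y, groups, finest=512):
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    groups = np.asarray(groups)
    meta = pd.DataFrame(
        {
            "participant_id": [g.split("/")[0] for g in groups],
            "session_id": [g.split("/")[1] for g in groups],
            "stimulus_index": 0,
            "element": y,
        }
    )
    return FeatureDataset(
        X=X.reshape(len(y), -1),
        y=y,
        groups=groups,
        meta=meta,
        spec=FeatureSetSpec((finest,)),
        mem_spec=MSPEC,
    )


def _random_dataset(rng, n_sessions=4, per_class=3, n_classes=4):
    rows, labels, groups = [], [], []
    for s in range(n_sessions):
        for c in range(1, n_classes + 1):
            for _ in range(per_class):
                rows.append(rng.normal(loc=c, scale=0.5, size=2))
                labels.append(c)
                groups.append(f"p{s}/s1")
    return _dataset(np.array(rows), labels, groups)


class TestLosoSplit:
    def test_folds_partition_without_leakage(self, rng):
        ds = _random_dataset(rng, n_sessions=3)
        seen = []
        for key, train, test in loso_split(ds):
            assert set(train.groups) & set(test.groups) == set()
            assert set(test.groups) == {key}
            assert len(train) + len(test) == len(ds)
            seen.extend(test.meta.index.tolist())
        assert len(seen) == len(ds)

    def test_one_fold_per_session(self, rng):
        ds = _random_dataset(rng, n_sessions=5)
        assert len(list(loso_split(ds))) == 5

    def test_single_session_errors(self, rng):
        ds = _random_dataset(rng, n_sessions=1)
        with pytest.raises(DataError, match="at least 2"):
            list(loso_split(ds))

    def test_run_accounting(self):
        assert n_classifier_runs(46) == 322
        assert n_classifier_runs(10, [3, 7]) == 20


class TestKnn:
    def test_exact_training_point_wins_at_k1(self):
        train = _dataset([[0.1], [0.9]], [1, 2], ["a/1", "b/1"])
        test = _dataset([[0.9]], [2], ["c/1"])
        assert knn_classify(train, test, 1).tolist() == [2]

    def test_nearest_neighbour_1d(self):
        train = _dataset([[0.1], [0.9]], [1, 2], ["a/1", "b/1"])
        test = _dataset([[0.2]], [1], ["c/1"])
        assert knn_classify(train, test, 1).tolist() == [1]

    def test_k_exceeding_training_rows_errors(self):
        train = _dataset([[0.1], [0.9]], [1, 2], ["a/1", "b/1"])
        with pytest.raises(DataError, match="k="):
            knn_classify(train, train, 3)

    def test_dimension_mismatch_errors(self):
        train = _dataset([[0.1, 0.2]], [1], ["a/1"])
        test = _dataset([[0.1]], [1], ["b/1"])
        with pytest.raises(DataError, match="dimensions"):
            knn_classify(train, test, 1)

    def test_matches_bruteforce_oracle(self, rng):
        Xtr = rng.normal(size=(60, 3))
        ytr = rng.integers(1, 5, size=60)
        Xte = rng.normal(size=(25, 3))
        ours = _knn_predict(Xtr, ytr, Xte, 7)
        assert ours.tolist() == knn_bruteforce(Xtr.tolist(), ytr.tolist(), Xte.tolist(), 7)

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_matches_sklearn_when_no_ties(self, rng, k):
        from sklearn.neighbors import KNeighborsClassifier

        Xtr = rng.normal(size=(50, 2))
        ytr = rng.integers(1, 3, size=50)  # 2 classes, odd k: no vote ties
        Xte = rng.normal(size=(30, 2))
        ours = _knn_predict(Xtr, ytr, Xte, k)
        ref = KNeighborsClassifier(n_neighbors=k).fit(Xtr, ytr).predict(Xte)
        assert ours.tolist() == ref.tolist()

    def test_invariant_to_training_row_order(self, rng):
        Xtr = rng.normal(size=(40, 2))
        ytr = rng.integers(1, 4, size=40)
        Xte = rng.normal(size=(15, 2))
        base = _knn_predict(Xtr, ytr, Xte, 5)
        perm = rng.permutation(40)
        shuffled = _knn_predict(Xtr[perm], ytr[perm], Xte, 5)
        assert base.tolist() == shuffled.tolist()

    def test_vote_tie_broken_by_summed_distance_then_class(self):
        # two classes each with one neighbour at k=2; class 2 is closer
        Xtr = np.array([[0.0], [1.0]])
        ytr = np.array([1, 2])
        assert _knn_predict(Xtr, ytr, np.array([[0.9]]), 2).tolist() == [2]
        # perfectly symmetric: falls back to the lower class index
        assert _knn_predict(Xtr, ytr, np.array([[0.5]]), 2).tolist() == [1]


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([1, 2, 3, 1, 2, 3])
        folds = np.array(["a", "a", "a", "b", "b", "b"])
        rep = evaluate(y, y, folds, labels=[1, 2, 3], k=3)
        assert rep.overall_accuracy == 1.0
        assert (rep.per_segment_accuracy == 1.0).all()
        conf = rep.confusion.to_numpy()
        assert np.trace(conf) == conf.sum() == 6

    def test_sensitivity_specificity_definitional(self):
        # one-vs-rest counts TP=83, FN=17, TN=921, FP=79
        y_true = np.array([1] * 100 + [2] * 1000)
        y_pred = np.array([1] * 83 + [2] * 17 + [2] * 921 + [1] * 79)
        rep = evaluate(
            y_true, y_pred, np.zeros_like(y_true), labels=[1, 2],
            designated_class=1,
        )
        assert rep.sensitivity == pytest.approx(0.83)
        assert rep.specificity == pytest.approx(0.921)

    def test_matches_tally_oracle(self, rng):
        n = 200
        labels = [1, 2, 3, 4]
        y_true = rng.integers(1, 5, size=n)
        y_pred = rng.integers(1, 5, size=n)
        folds = rng.integers(0, 3, size=n)
        rep = evaluate(y_true, y_pred, folds, labels=labels)
        overall, per_class = metrics_bruteforce(
            y_true.tolist(), y_pred.tolist(), folds.tolist(), labels
        )
        assert rep.overall_accuracy == pytest.approx(overall)
        for c in labels:
            assert rep.per_segment_accuracy[c] == pytest.approx(per_class[c])
        # confusion rows sum to per-class truth counts
        row_sums = rep.confusion.sum(axis=1).to_numpy()
        np.testing.assert_array_equal(row_sums, np.bincount(y_true)[1:])

    def test_length_mismatch_errors(self):
        with pytest.raises(DataError):
            evaluate([1, 2], [1], [0, 0], labels=[1, 2])

    def test_balanced_per_segment_mean_equals_overall(self, rng):
        ds = _random_dataset(rng, n_sessions=4, per_class=2)
        rep = run_loso(ds, 3)
        assert rep.per_segment_accuracy.mean() == pytest.approx(
            rep.overall_accuracy
        )
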