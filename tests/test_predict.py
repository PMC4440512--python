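import numpy as np
import pandas as pd
import pytest

from alumeth.predict import (knn_classify, loocv, rank_features,
                             score_features, signal_to_noise)


def labeled_matrix(n_signal=10, n_noise=40, n_per_class=7, effect=1.0,
                   noise=0.05, seed=0):
    """Features x samples matrix with planted class-separating features."""
    rng = np.random.default_rng(seed)
    cols = [f"s{i:02d}" for i in range(2 * n_per_class)]
    labels = pd.Series(["good"] * n_per_class + ["poor"] * n_per_class,
                       index=cols)
    data = rng.normal(0.5, 0.15, size=(n_signal + n_noise, len(cols)))
    data[:n_signal, n_per_class:] += effect
    data += rng.normal(0, noise, data.shape)
    matrix = pd.DataFrame(data, columns=cols,
                          index=[f"f{i}" for i in range(n_signal + n_noise)])
    return matrix, labels


class TestSignalToNoise:
    def test_direct_formula(self):
        v = np.array([2.0, 3.0, 0.0, 1.0])
        y = np.array([0, 0, 1, 1])
        # (2.5 - 0.5) / (0.7071 + 0.7071)
        assert signal_to_noise(v, y) == pytest.approx(1.4142, abs=1e-4)

    def test_null_when_identical(self):
        v = np.array([1.0, 2.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        assert signal_to_noise(v, y) == pytest.approx(0.0)

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=10)
        y = np.array([0] * 5 + [1] * 5)
        assert signal_to_noise(v, y) == pytest.approx(
            -signal_to_noise(v, 1 - y))

    def test_sigma_floor_bounds_score(self):
        # constant classes: sd floors keep the score finite
        v = np.array([1.0, 1.0, 0.0, 0.0])
        y = np.array([0, 0, 1, 1])
        assert signal_to_noise(v, y) == pytest.approx(1.0 / 0.4)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            signal_to_noise(np.array([1.0, 2.0, 3.0]),
                            np.array([0, 1, 1]))

    def test_vectorised_scoring_matches_scalar(self):
        matrix, labels = labeled_matrix(seed=4)
        scores = score_features(matrix, labels)
        y = labels.to_numpy()
        for i in range(0, len(matrix), 7):
            assert scores[i] == pytest.approx(
                signal_to_noise(matrix.iloc[i].to_numpy(), y))


class TestKnn:
    def test_zero_distance_wins_with_k1(self):
        matrix, labels = labeled_matrix(seed=1)
        test = matrix["s01"].to_numpy(dtype=float)
        train = matrix.drop(columns=[])
        assert knn_classify(train, labels, test, k=1) == labels["s01"]

    def test_vote_tie_resolved_by_nearest(self):
        train = pd.DataFrame({"a": [0.0], "b": [1.0]},
                             index=["f"])
        labels = pd.Series({"a": "good", "b": "poor"})
        # k=2 ties the vote; nearest neighbour (a) decides
        assert knn_classify(train, labels, np.array([0.2]), k=2) == "good"

    def test_k_bounds(self):
        train = pd.DataFrame({"a": [0.0], "b": [1.0]}, index=["f"])
        labels = pd.Series({"a": "g", "b": "p"})
        with pytest.raises(ValueError):
            knn_classify(train, labels, np.array([0.5]), k=3)

    def test_agreement_with_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for trial in range(50):
            n_train, n_feat, k = 8, 5, int(rng.integers(1, 5))
            cols = [f"t{i}" for i in range(n_train)]
            train = pd.DataFrame(rng.normal(size=(n_feat, n_train)),
                                 columns=cols)
            labels = pd.Series(rng.choice(["x", "y"], n_train), index=cols)
            if labels.nunique() < 2:
                continue
            test = rng.normal(size=n_feat)
            got = knn_classify(train, labels, test, k=k)
            # oracle: exhaustive distance sort, majority vote
            dists = sorted((float(np.linalg.norm(train[c] - test)), c)
                           for c in cols)
            votes = {}
            for _, c in dists[:k]:
                votes[labels[c]] = votes.get(labels[c], 0) + 1
            best = max(votes.values())
            winners = [l for l, n in votes.items() if n == best]
            expected = winners[0] if len(winners) == 1 else labels[dists[0][1]]
            assert got == expected


class TestLoocv:
    def test_separable_signal_perfect_accuracy(self):
        matrix, labels = labeled_matrix(effect=1.5, noise=0.02, seed=3)
        report = loocv(matrix, labels, k=3, n_features=10)
        assert report.accuracy == 1.0
        assert report.fisher_p < 0.01

    def test_no_leakage_on_label_independent_features(self):
        # features carry no label information; the leakage-free protocol
        # must hover around chance over label permutations
        rng = np.random.default_rng(8)
        matrix, labels = labeled_matrix(n_signal=0, n_noise=40, effect=0.0,
                                        seed=8)
        accs = []
        for _ in range(20):
            perm = pd.Series(rng.permutation(labels.to_numpy()),
                             index=labels.index)
            accs.append(loocv(matrix, perm, k=3, n_features=10).accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.2

    def test_global_selection_mode_runs(self):
        matrix, labels = labeled_matrix(seed=5)
        report = loocv(matrix, labels, k=3, n_features=10,
                       fold_internal_selection=False)
        assert 0.0 <= report.accuracy <= 1.0

    def test_deterministic(self):
        matrix, labels = labeled_matrix(seed=9)
        a = loocv(matrix, labels, k=3, n_features=15)
        b = loocv(matrix, labels, k=3, n_features=15)
        assert a.predictions == b.predictions
        assert a.accuracy == b.accuracy

    def test_table_margins_match_class_sizes(self):
        matrix, labels = labeled_matrix(seed=10)
        report = loocv(matrix, labels, k=3, n_features=10)
        col_sums = [report.table[0][j] + report.table[1][j] for j in (0, 1)]
        assert col_sums == [7, 7]
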