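"""Split/oversample contracts, one-vs-one AUC against the O(n^2)
concordance oracle, and end-to-end behaviour of the random-forest
sex-role classifier."""

import numpy as np
import pandas as pd
import pytest

from enterotools import classifier, io
from enterotools.classifier import (
    cv_tune,
    macro_auc,
    oversample,
    pairwise_auc,
    permutation_importance,
    run_classifier,
    select_features,
    split_train_test,
    train_rf,
)
from enterotools.io import RelativeProfileSet


@pytest.fixture
def role_labels():
    rng = np.random.default_rng(0)
    ids = [f"S{i:03d}" for i in range(95)]
    labels = np.array(["insertive_only"] * 33 + ["versatile"] * 46
                      + ["receptive_only"] * 16)
    rng.shuffle(labels)
    return ids, labels


class TestSplit:
    def test_sizes_and_disjointness(self, role_labels):
        ids, labels = role_labels
        train, test = split_train_test(ids, labels, 0.7, seed=1)
        assert len(train) + len(test) == 95
        assert 65 <= len(train) <= 68
        assert not set(train) & set(test)
        assert set(train) | set(test) == set(ids)

    def test_determinism(self, role_labels):
        ids, labels = role_labels
        assert split_train_test(ids, labels, seed=5) == \
            split_train_test(ids, labels, seed=5)
        assert split_train_test(ids, labels, seed=5) != \
            split_train_test(ids, labels, seed=6)

    def test_stratification_within_one_sample(self, role_labels):
        ids, labels = role_labels
        train, _ = split_train_test(ids, labels, 0.7, seed=2)
        lab = dict(zip(ids, labels))
        for cls, total in zip(*np.unique(labels, return_counts=True)):
            in_train = sum(lab[t] == cls for t in train)
            assert abs(in_train - 0.7 * total) <= 1.0

    def test_every_class_in_both_sides(self, role_labels):
        ids, labels = role_labels
        lab = dict(zip(ids, labels))
        for seed in range(10):
            train, test = split_train_test(ids, labels, 0.7, seed=seed)
            assert {lab[t] for t in train} == set(labels)
            assert {lab[t] for t in test} == set(labels)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="2 samples per class"):
            split_train_test(["a", "b", "c"], ["x", "x", "y"])


class TestOversample:
    def test_balances_to_majority(self):
        ids = [f"s{i}" for i in range(17)]
        labels = pd.Series(["A"] * 10 + ["B"] * 5 + ["C"] * 2, index=ids)
        out = oversample(ids, labels, seed=0)
        counts = labels.loc[out].value_counts()
        assert counts["A"] == counts["B"] == counts["C"] == 10
        assert set(out) <= set(ids)  # duplication only, no invention

    def test_balanced_input_unchanged(self):
        ids = list("abcd")
        labels = pd.Series(["A", "A", "B", "B"], index=ids)
        assert sorted(oversample(ids, labels, seed=3)) == sorted(ids)

    def test_never_touches_test_ids(self, role_labels):
        ids, labels = role_labels
        series = pd.Series(labels, index=ids)
        train, test = split_train_test(ids, labels, seed=4)
        augmented = oversample(train, series, seed=4)
        assert not set(augmented) & set(test)


class TestSelectFeatures:
    def _profiles(self, arr, genera):
        return RelativeProfileSet(
            genera, [f"S{i}" for i in range(arr.shape[0])], arr)

    def test_union_semantics(self):
        rng = np.random.default_rng(1)
        arr = rng.dirichlet(np.ones(30), size=20)
        prof = self._profiles(arr, [f"g{i:02d}" for i in range(30)])
        labels = np.repeat([0, 1], 10)
        feats = select_features(prof, labels, n_per_cluster=10)
        assert 10 <= len(feats) <= 20
        assert len(feats) == len(set(feats))

    def test_shared_top_genera_no_duplicates(self):
        arr = np.tile(np.linspace(10, 1, 10), (6, 1))
        arr /= arr.sum(axis=1, keepdims=True)
        prof = self._profiles(arr, [f"g{i}" for i in range(10)])
        feats = select_features(prof, np.repeat([0, 1], 3), n_per_cluster=5)
        assert len(feats) == 5  # identical clusters share the top list

    def test_synthetic_dominants_included(self, default_dataset, default_profiles):
        feats = select_features(default_profiles, default_dataset.true_labels)
        assert "Phocaeicola" in feats and "Segatella" in feats

    def test_fewer_genera_than_requested_warns(self):
        arr = np.full((4, 3), 1 / 3)
        prof = self._profiles(arr, ["a", "b", "c"])
        with pytest.warns(UserWarning, match="available"):
            feats = select_features(prof, np.repeat([0, 1], 2), n_per_cluster=10)
        assert sorted(feats) == ["a", "b", "c"]


def auc_concordance_oracle(scores, positive):
    """O(n^2) count of concordant pairs, ties 1/2."""
    pos = np.asarray(scores)[positive]
    neg = np.asarray(scores)[~np.asarray(positive)]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestPairwiseAUC:
    def _prob(self, scores):
        scores = np.asarray(scores, dtype=float)
        return np.column_stack([scores, 1 - scores, np.zeros_like(scores)])

    def test_perfect_separation(self):
        prob = self._prob([0.9, 0.8, 0.2, 0.1])
        y = np.array(["a", "a", "b", "b"])
        assert pairwise_auc(prob, y, ["a", "b", "c"], "a", "b") == 1.0

    def test_all_ties_half(self):
        prob = self._prob([0.5] * 6)
        y = np.array(["a", "a", "a", "b", "b", "b"])
        assert pairwise_auc(prob, y, ["a", "b", "c"], "a", "b") == 0.5

    def test_matches_concordance_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(4, 200))
            scores = rng.choice(np.linspace(0, 1, 20), size=n)  # forces ties
            y = rng.choice(["a", "b"], size=n)
            if len(np.unique(y)) < 2:
                continue
            auc = pairwise_auc(self._prob(scores), y, ["a", "b", "c"], "a", "b")
            assert auc == pytest.approx(
                auc_concordance_oracle(scores, y == "a"), abs=1e-12)

    def test_restricts_to_the_two_classes(self):
        prob = self._prob([0.9, 0.1, 0.5])
        y = np.array(["a", "b", "c"])
        assert pairwise_auc(prob, y, ["a", "b", "c"], "a", "b") == 1.0

    def test_absent_class_warns_nan(self):
        prob = self._prob([0.9, 0.8])
        y = np.array(["a", "a"])
        with pytest.warns(UserWarning, match="absent"):
            assert np.isnan(pairwise_auc(prob, y, ["a", "b", "c"], "a", "b"))


class TestMacroAUC:
    def test_printed_pairwise_values(self):
        assert macro_auc([0.5036, 0.6400, 0.6929]) == \
            pytest.approx(0.6121666666, abs=1e-9)

    def test_all_half(self):
        assert macro_auc([0.5, 0.5, 0.5]) == 0.5

    def test_permutation_invariant(self):
        assert macro_auc([0.2, 0.9, 0.6]) == pytest.approx(
            macro_auc([0.9, 0.6, 0.2]), abs=1e-15)

    def test_missing_pair_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            macro_auc({("a", "b"): 0.7, ("a", "c"): float("nan")})


class TestTrainRF:
    def test_separable_toy_data(self):
        X = np.array([[0, 0], [0, 1], [5, 5], [5, 6]] * 5, dtype=float)
        y = np.array(["lo", "lo", "hi", "hi"] * 5)
        model = train_rf(X, y, ntree=50, mtry=1, seed=0)
        assert (model.predict(X) == y).all()

    def test_probability_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        y = rng.choice(["a", "b", "c"], 30)
        model = train_rf(X, y, ntree=20, mtry=2, seed=0)
        np.testing.assert_allclose(model.predict_proba(X).sum(axis=1), 1.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        X, y = rng.normal(size=(40, 3)), rng.choice(["a", "b"], 40)
        p1 = train_rf(X, y, ntree=30, mtry=1, seed=9).predict_proba(X)
        p2 = train_rf(X, y, ntree=30, mtry=1, seed=9).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_mtry_exceeding_features_rejected(self):
        with pytest.raises(ValueError, match="mtry"):
            train_rf(np.ones((10, 2)), np.r_[np.zeros(5), np.ones(5)], mtry=3)

    def test_pure_noise_auc_near_half(self):
        rng = np.random.default_rng(5)
        aucs = []
        for rep in range(20):
            X = rng.normal(size=(80, 3))
            y = rng.choice(["a", "b"], 80)
            model = train_rf(X[:60], y[:60], ntree=50, mtry=1, seed=rep)
            prob = model.predict_proba(X[60:])
            aucs.append(pairwise_auc(prob, y[60:], list(model.classes_), "a", "b"))
        assert np.nanmean(aucs) == pytest.approx(0.5, abs=0.1)


class TestCVTune:
    def test_single_point_grid(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 3))
        y = rng.choice(["a", "b"], 50)
        params = cv_tune(X, y, grid={"ntree": (77,), "mtry": (2,)}, seed=0)
        assert params == {"ntree": 77, "mtry": 2}

    def test_paper_hyperparameters_in_default_grid(self):
        assert 200 in classifier.DEFAULT_GRID["ntree"]
        # mtry grid is derived from the feature count and always contains 1
        X = np.random.default_rng(0).normal(size=(40, 5))
        y = np.array(["a", "b"] * 20)
        params = cv_tune(X, y, grid={"ntree": (10,), "mtry": (1,)}, seed=0)
        assert params["mtry"] == 1

    def test_seed_reproducible(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 3))
        y = rng.choice(["a", "b", "c"], 60)
        grid = {"ntree": (20, 40), "mtry": (1, 2)}
        assert cv_tune(X, y, grid=grid, seed=3) == cv_tune(X, y, grid=grid, seed=3)

    def test_informative_features_reach_high_cv_auc(self):
        rng = np.random.default_rng(8)
        y = np.repeat(["a", "b", "c"], 30)
        X = rng.normal(size=(90, 3)) + 3 * np.column_stack(
            [(y == "a"), (y == "b"), (y == "c")]).astype(float)
        grid = {"ntree": (100,), "mtry": (1, 2)}
        params = cv_tune(X, y, grid=grid, seed=0)
        score = classifier._cv_macro_auc(X, y, params["ntree"], params["mtry"],
                                         folds=5, seed=0)
        assert score > 0.8

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            cv_tune(np.ones((10, 2)), np.array(["a", "b"] * 5),
                    grid={"ntree": (), "mtry": (1,)})


class TestPermutationImportance:
    def test_informative_feature_ranks_first_and_noise_near_zero(self):
        rng = np.random.default_rng(9)
        n = 200
        y = rng.choice(["a", "b"], n)
        signal = (y == "a").astype(float) + rng.normal(0, 0.3, n)
        X = np.column_stack([signal, rng.normal(size=n), rng.normal(size=n)])
        model = train_rf(X[:140], y[:140], ntree=100, mtry=1, seed=0)
        model.feature_names = ["signal", "noise1", "noise2"]
        imp = permutation_importance(model, X[140:], y[140:], n_repeats=10, seed=0)
        assert imp.index[0] == "signal"
        assert abs(imp["noise1"]) < 0.1 and abs(imp["noise2"]) < 0.1

    def test_seed_reproducible(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 3))
        y = rng.choice(["a", "b"], 60)
        model = train_rf(X, y, ntree=20, mtry=1, seed=0)
        i1 = permutation_importance(model, X, y, n_repeats=3, seed=2)
        i2 = permutation_importance(model, X, y, n_repeats=3, seed=2)
        pd.testing.assert_series_equal(i1, i2)


class TestEndToEnd:
    def test_report_invariants(self, default_dataset, default_profiles):
        report = run_classifier(
            default_profiles, default_dataset.metadata["sex_role"],
            default_dataset.true_labels, tune=False, seed=0)
        assert report.macro_auc == pytest.approx(
            np.mean(list(report.pairwise_auc.values())))
        assert all(0 <= v <= 1 for v in report.pairwise_auc.values())
        assert len(report.pairwise_auc) == 3
        assert set(report.test_sample_ids) <= set(default_dataset.table.sample_ids)
        train = set(default_dataset.table.sample_ids) - set(report.test_sample_ids)
        assert train | set(report.test_sample_ids) == set(default_dataset.table.sample_ids)

    def test_coupled_signal_beats_permuted_null(self):
        """Sex role is coupled to the enterotype axis, so the classifier
        beats its permuted-label null on average across replicate cohorts.
        Cohorts of 300 give the test-set AUC enough precision for the gap
        to be resolvable; at n = 95 the 29-sample test set drowns it."""
        from enterotools import io, simulate

        real, null = [], []
        for seed in range(6):
            ds = simulate.generate(
                simulate.GeneratorConfig(seed=200 + seed, n_samples=300))
            prof = io.to_relative(ds.table)
            roles = ds.metadata["sex_role"]
            rep = run_classifier(prof, roles, ds.true_labels, tune=False,
                                 seed=seed, n_repeats=0)
            rng = np.random.default_rng(seed)
            permuted = pd.Series(rng.permutation(roles.to_numpy()),
                                 index=roles.index)
            rep0 = run_classifier(prof, permuted, ds.true_labels, tune=False,
                                  seed=seed, n_repeats=0)
            real.append(rep.macro_auc)
            null.append(rep0.macro_auc)
        assert np.mean(real) - np.mean(null) > 0.1
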