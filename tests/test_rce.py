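"""Recursive cluster elimination SVM: scoring, elimination, significance."""

import numpy as np
import pytest
from scipy import stats

from causalbold import (
    BinomialNullConfig,
    FeatureTable,
    RceConfig,
    binomial_significance,
    bonferroni_adjust,
    classification_metrics,
    eliminate_bottom,
    initial_cluster_count,
    run_rce,
    score_cluster,
)
from causalbold._svm import svm_fit, svm_predict


def make_table(n_per_class=15, n_features=40, n_informative=4, d=1.5, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    labels = np.array(["ASD"] * n_per_class + ["TD"] * n_per_class)
    x = rng.normal(size=(n, n_features))
    x[labels == "TD", :n_informative] += d
    return FeatureTable(
        matrix=x,
        feature_names=[f"f{i}" for i in range(n_features)],
        labels=labels,
    )


class TestLinearSvmWorker:
    def test_decisions_agree_with_sklearn_svc(self, rng):
        """The internal dual coordinate-descent solver must reproduce
        sklearn's linear SVC decision boundary on small problems."""
        from sklearn.svm import SVC

        agree = []
        for _ in range(50):
            d = int(rng.integers(1, 6))
            x = rng.normal(size=(22, d))
            y = np.array([-1.0] * 11 + [1.0] * 11)
            x[y > 0] += rng.normal(0.4, 0.4, size=d)
            xt = rng.normal(size=(10, d))
            w = svm_fit(x, y)
            mine = svm_predict(w, xt)
            ref = SVC(kernel="linear", C=1.0).fit(x, y).predict(xt)
            agree.append(np.mean(mine == ref))
        assert np.mean(agree) > 0.93

    def test_fit_is_deterministic(self, rng):
        x = rng.normal(size=(20, 3))
        y = np.array([-1.0] * 10 + [1.0] * 10)
        assert np.array_equal(svm_fit(x, y), svm_fit(x, y))


class TestInitialClusterCount:
    def test_single_feature_gives_one(self):
        assert initial_cluster_count(np.random.default_rng(0).normal(size=(1, 10))) == 1

    def test_duplicate_patterns_force_reduction(self):
        rng = np.random.default_rng(1)
        patterns = rng.normal(size=(3, 12))
        points = np.vstack([patterns, patterns])  # 6 features, 3 distinct
        assert initial_cluster_count(points, seed=0) <= 3

    def test_well_separated_features_keep_full_count(self):
        hits = 0
        for seed in range(10):
            points = 10 * np.eye(8) + np.random.default_rng(seed).normal(
                scale=0.01, size=(8, 8)
            )
            hits += initial_cluster_count(points, seed=seed) == 8
        assert hits >= 9


class TestScoreCluster:
    def test_perfectly_separating_feature_scores_one(self):
        labels = np.array(["ASD"] * 10 + ["TD"] * 10)
        feature = np.where(labels == "ASD", 1.0, -1.0)[:, None]
        score = score_cluster(feature, labels, RceConfig(n_reps=3), seed=0)
        assert score == 1.0

    def test_label_independent_feature_scores_near_chance(self):
        labels = np.array(["ASD"] * 15 + ["TD"] * 15)
        in_band = 0
        for seed in range(40):
            feature = np.random.default_rng(seed).normal(size=(30, 1))
            s = score_cluster(feature, labels, RceConfig(n_reps=5), seed=seed)
            in_band += 0.3 <= s <= 0.7
        # a null feature occasionally separates 30 subjects by luck
        # (realized |d| up to ~1), so ~8% of draws fall outside the band
        assert in_band >= 36

    def test_score_is_deterministic_and_bounded(self, rng):
        labels = np.array(["ASD"] * 12 + ["TD"] * 12)
        sub = rng.normal(size=(24, 3))
        a = score_cluster(sub, labels, RceConfig(n_reps=4), seed=3)
        b = score_cluster(sub, labels, RceConfig(n_reps=4), seed=3)
        assert a == b and 0.0 <= a <= 1.0


class TestEliminateBottom:
    def test_ten_clusters_lose_exactly_one(self):
        survivors = eliminate_bottom(list(np.linspace(0, 1, 10)), 0.10)
        assert len(survivors) == 9
        assert 0 not in survivors

    def test_twenty_five_clusters_lose_three(self):
        scores = list(np.linspace(0, 1, 25))
        assert len(eliminate_bottom(scores, 0.10)) == 22

    def test_ties_remove_smaller_index_first(self):
        survivors = eliminate_bottom([0.5, 0.5, 0.9, 0.5], 0.25)
        assert survivors == [1, 2, 3]


class TestClassificationMetrics:
    def test_all_correct(self):
        y = np.array(["ASD", "TD", "ASD"])
        assert classification_metrics(y, y) == (1.0, 1.0, 1.0)

    def test_degenerate_all_td_predictor(self):
        actual = np.array(["ASD"] * 5 + ["TD"] * 5)
        predicted = np.array(["TD"] * 10)
        assert classification_metrics(predicted, actual) == (0.5, 0.0, 1.0)

    def test_mixed_counts(self):
        actual = np.array(["ASD"] * 15 + ["TD"] * 15)
        predicted = actual.copy()
        predicted[:2] = "TD"   # 13/15 ASD correct
        predicted[15] = "ASD"  # 14/15 TD correct
        acc, sens, spec = classification_metrics(predicted, actual)
        assert (acc, sens, spec) == (27 / 30, 13 / 15, 14 / 15)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(np.array([]), np.array([]))


class TestBinomialSignificance:
    @pytest.mark.parametrize(
        "accuracy,expected",
        [
            (0.855, 2.97e-5),
            (0.892, 4.22e-6),
            (0.945, 4.34e-7),
            (0.959, 2.89e-8),
        ],
    )
    def test_reported_accuracy_p_pairs(self, accuracy, expected):
        p = binomial_significance(accuracy, BinomialNullConfig(eta=30))
        assert p == pytest.approx(expected, rel=5e-3)

    def test_perfect_accuracy_is_two_to_minus_eta(self):
        p = binomial_significance(1.0, BinomialNullConfig(eta=30))
        assert p == pytest.approx(2.0**-30, rel=1e-12)

    def test_chance_accuracy(self):
        p = binomial_significance(0.5, BinomialNullConfig(eta=30))
        assert p == pytest.approx(0.57223, abs=5e-6)

    def test_matches_brute_force_tail_sum_up_to_eta_64(self):
        import math

        for eta in (5, 17, 30, 64):
            null = BinomialNullConfig(eta=eta, rho=0.5)
            for accuracy in np.linspace(0, 1, 23):
                successes = int(np.floor(accuracy * eta + 0.5))
                brute = sum(
                    math.comb(eta, k) * 0.5**eta for k in range(successes, eta + 1)
                )
                assert binomial_significance(accuracy, null) == pytest.approx(
                    brute, abs=1e-12
                )


class TestBonferroni:
    def test_adjustment_and_flags(self):
        adjusted, flags = bonferroni_adjust([0.01] * 23, alpha=0.05)
        assert adjusted[0] == pytest.approx(0.23)
        assert not flags[0]
        adjusted, flags = bonferroni_adjust([0.001] * 23, alpha=0.05)
        assert adjusted[0] == pytest.approx(0.023)
        assert flags[0]

    def test_capped_at_one(self):
        adjusted, _ = bonferroni_adjust([0.9, 0.2, 0.2, 0.2, 0.2])
        assert adjusted[0] == 1.0


class TestRunRce:
    def test_cluster_count_strictly_decreases_to_two(self):
        table = make_table(seed=1)
        result = run_rce(table, RceConfig(n_splits=2, n_reps=2, seed=1))
        counts = [lp.n_clusters for lp in result.loops]
        assert all(a > b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 2

    def test_result_is_deterministic(self):
        table = make_table(seed=2)
        cfg = RceConfig(n_splits=2, n_reps=2, seed=5)
        a = run_rce(table, cfg)
        b = run_rce(table, cfg)
        assert [lp.accuracy for lp in a.loops] == [lp.accuracy for lp in b.loops]
        assert [f.name for f in a.final_features] == [f.name for f in b.final_features]

    def test_informative_features_enriched_among_survivors(self):
        table = make_table(n_features=60, n_informative=6, d=2.0, seed=3)
        result = run_rce(table, RceConfig(n_splits=4, n_reps=10, seed=3))
        informative = {f"f{i}" for i in range(6)}
        frac = np.mean([f.name in informative for f in result.final_features])
        assert frac >= 0.5
        assert result.final_loop.accuracy > 0.7

    def test_informative_fraction_grows_across_loops(self):
        # enrichment: the share of truly informative features among the
        # survivors rises from start to finish (median over seeds)
        start, end = [], []
        for seed in range(5):
            table = make_table(n_features=50, n_informative=5, d=2.0, seed=seed)
            result = run_rce(table, RceConfig(n_splits=2, n_reps=5, seed=seed))
            for split in result.per_split:
                first = split["loops"][0]["active_features"]
                last = split["loops"][-1]["active_features"]
                start.append(np.mean([f < 5 for f in first]))
                end.append(np.mean([f < 5 for f in last]))
        assert np.median(end) > np.median(start)

    def test_all_null_features_give_no_significant_loop(self):
        hits = 0
        for seed in range(5):
            table = make_table(n_features=40, n_informative=0, seed=seed)
            result = run_rce(table, RceConfig(n_splits=3, n_reps=3, seed=seed))
            hits += not any(lp.significant_after_bonferroni for lp in result.loops)
        assert hits >= 4

    def test_test_subjects_never_enter_training(self):
        table = make_table(seed=4)
        result = run_rce(table, RceConfig(n_splits=3, n_reps=2, seed=4))
        for split in result.per_split:
            assert not set(split["train_idx"]) & set(split["test_idx"])
            assert len(split["train_idx"]) + len(split["test_idx"]) == table.n_subjects

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            FeatureTable(
                matrix=np.zeros((4, 3)),
                feature_names=["a", "b", "c"],
                labels=np.array(["ASD"] * 4),
            )
        with pytest.raises(ValueError):
            FeatureTable(
                matrix=np.full((4, 2), np.nan),
                feature_names=["a", "b"],
                labels=np.array(["ASD", "ASD", "TD", "TD"]),
            )
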