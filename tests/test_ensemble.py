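"""Ensemble feature selection: importance extraction, aggregation,
reduction arithmetic and the recursion contract."""

import numpy as np
import pandas as pd
import pytest

from immunoselect import (
    CLASSIFIER_FAMILIES,
    CohortConfig,
    FeatureTable,
    RFEConfig,
    aggregate_rankings,
    extract_importance,
    generate_cohort,
    recursive_selection,
    reduce_features,
    run_classifier_cv,
    select_optimal,
)
from immunoselect.ensemble import (
    ConfigError,
    EnsembleRanking,
    Iteration,
    NoFurtherReduction,
    RFETrace,
    RunResult,
    effective_folds,
    make_classifier,
)

from conftest import separable_table, small_schema


# ---------------------------------------------------------------------------
# independent brute-force re-implementation of the aggregation rule,
# written as explicit loops with no shared code
def brute_force_aggregate(importances):
    """importances: list of per-run lists, all over the same features."""
    n_runs = len(importances)
    n_feat = len(importances[0])
    scores = []
    for j in range(n_feat):
        contributing = 0
        total = 0.0
        for run in importances:
            if run[j] > 0:
                contributing += 1
            total += run[j]
        freq = contributing / n_runs
        mean_imp = total / n_runs
        scores.append(mean_imp * freq)
    return scores


class TestAggregateRankings:
    def test_hand_computed_example(self):
        runs = [
            RunResult("ridge", 0, ("f1", "f2", "f3"),
                      np.ones(2), np.array([0.6, 0.4, 0.0])),
            RunResult("ridge", 1, ("f1", "f2", "f3"),
                      np.ones(2), np.array([0.5, 0.0, 0.5])),
        ]
        ranking = aggregate_rankings(runs)
        np.testing.assert_allclose(ranking.scores, [0.55, 0.10, 0.125], atol=1e-12)
        assert ranking.ordered() == ["f1", "f3", "f2"]

    def test_single_run_score_is_importance(self):
        run = RunResult("ridge", 0, ("a", "b"), np.ones(2), np.array([0.7, 0.3]))
        ranking = aggregate_rankings([run])
        np.testing.assert_allclose(ranking.scores, [0.7, 0.3])

    def test_all_zero_importances_order_lexicographic(self):
        runs = [RunResult("ridge", r, ("z", "a", "m"), np.ones(2), np.zeros(3))
                for r in range(3)]
        ranking = aggregate_rankings(runs)
        assert (ranking.scores == 0).all()
        assert ranking.ordered() == ["a", "m", "z"]

    def test_mismatched_feature_sets_rejected(self):
        runs = [
            RunResult("ridge", 0, ("a", "b"), np.ones(2), np.array([0.5, 0.5])),
            RunResult("ridge", 1, ("a", "c"), np.ones(2), np.array([0.5, 0.5])),
        ]
        with pytest.raises(ValueError):
            aggregate_rankings(runs)

    def test_matches_brute_force_on_random_instances(self):
        """Oracle equivalence on 100 random small instances to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_runs = int(rng.integers(1, 6))
            n_feat = int(rng.integers(1, 7))
            raw = rng.uniform(size=(n_runs, n_feat))
            raw[rng.uniform(size=raw.shape) < 0.3] = 0.0  # sparse contributions
            # normalize nonzero rows like real importance vectors
            rows = []
            for row in raw:
                s = row.sum()
                rows.append(row / s if s > 0 else row)
            features = tuple(f"f{j}" for j in range(n_feat))
            runs = [
                RunResult("ridge", r, features, np.ones(2), np.asarray(rows[r]))
                for r in range(n_runs)
            ]
            ranking = aggregate_rankings(runs)
            expected = brute_force_aggregate(rows)
            np.testing.assert_allclose(ranking.scores, expected, atol=1e-12)


class TestExtractImportance:
    def test_linear_coefficients_absolute_and_normalized(self):
        class FakeLinear:
            coef_ = np.array([[2.0, -2.0, 0.0]])

        np.testing.assert_allclose(
            extract_importance(FakeLinear()), [0.5, 0.5, 0.0]
        )

    def test_output_sums_to_one_or_is_zero(self):
        class FakeTree:
            feature_importances_ = np.array([0.2, 0.3, 0.5])

        class FakeDead:
            coef_ = np.array([[0.0, 0.0]])

        assert extract_importance(FakeTree()).sum() == pytest.approx(1.0)
        assert extract_importance(FakeDead()).sum() == 0.0

    def test_unsupported_model_rejected(self):
        with pytest.raises(ConfigError):
            extract_importance(object())

    @pytest.mark.parametrize("family", CLASSIFIER_FAMILIES)
    def test_informative_feature_tops_every_family(self, family):
        """On separable data with one real marker among noise, every
        family assigns that marker the maximum importance."""
        rng = np.random.default_rng(0)
        n = 20
        X = pd.DataFrame({
            "marker": np.r_[np.zeros(10), np.ones(10)] + rng.normal(0, 0.05, n),
            "n1": rng.normal(size=n),
            "n2": rng.normal(size=n),
        }, index=[f"s{i}" for i in range(n)])
        group = pd.Series(["control"] * 10 + ["antibiotic"] * 10, index=X.index)
        table = FeatureTable(X, group)
        wins = 0
        for seed in range(5):
            run = run_classifier_cv(table, list(X.columns), family, seed, 5)
            wins += int(np.argmax(run.importance) == 0)
        assert wins >= 4


class TestRunClassifierCV:
    @pytest.mark.parametrize("family", CLASSIFIER_FAMILIES)
    def test_separable_toy_is_perfect(self, family):
        table = separable_table(6)
        run = run_classifier_cv(table, ["marker"], family, 0, 6)
        assert (run.fold_accuracies == 1.0).all()

    def test_minority_class_caps_fold_count(self, default_cohort, caplog):
        table, _ = default_cohort
        import logging
        with caplog.at_level(logging.INFO, logger="immunoselect.ensemble"):
            run = run_classifier_cv(table, table.feature_names[:5], "ridge", 0, 10)
        assert len(run.fold_accuracies) == 8  # minority group has 8 members
        assert any("8 folds" in r.message for r in caplog.records)

    def test_pure_noise_accuracy_near_half(self):
        rng = np.random.default_rng(3)
        n = 60
        data = pd.DataFrame(rng.normal(size=(n, 5)),
                            columns=[f"x{i}" for i in range(5)],
                            index=[f"s{i}" for i in range(n)])
        group = pd.Series(["control"] * 30 + ["antibiotic"] * 30, index=data.index)
        table = FeatureTable(data, group)
        accs = [run_classifier_cv(table, list(data.columns), "ridge", s, 5)
                .fold_accuracies.mean() for s in range(20)]
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_unknown_family_rejected(self, toy_table):
        with pytest.raises(ConfigError):
            run_classifier_cv(toy_table, ["sep"], "perceptron", 0, 3)


def _ranking(names):
    n = len(names)
    scores = np.linspace(1.0, 0.1, n)
    return EnsembleRanking(tuple(names), scores, np.ones(n), scores)


class TestReduceFeatures:
    @pytest.mark.parametrize(
        "n, expected", [(129, 103), (5, 4), (2, 1), (103, 82), (82, 65)]
    )
    def test_floor_arithmetic(self, n, expected):
        names = [f"f{i:03d}" for i in range(n)]
        kept = reduce_features(_ranking(names), names, 0.20)
        assert len(kept) == expected

    def test_keeps_top_scored(self):
        names = ["a", "b", "c", "d", "e"]
        kept = reduce_features(_ranking(names), names, 0.20)
        assert kept == ["a", "b", "c", "d"]

    def test_single_feature_signals_stop(self):
        with pytest.raises(NoFurtherReduction):
            reduce_features(_ranking(["a"]), ["a"], 0.20)


def _trace(entries):
    iterations = []
    for size, acc in entries:
        feats = tuple(f"f{i}" for i in range(size))
        iterations.append(Iteration(feats, {"ridge": acc}, acc, _ranking(list(feats))))
    return RFETrace(iterations)


class TestSelectOptimal:
    def test_smallest_qualifying_set(self):
        trace = _trace([(8, 0.95), (6, 0.93), (4, 0.91), (3, 0.85)])
        sel = select_optimal(trace, 0.90)
        assert sel.n_features == 4
        assert sel.cutoff_met

    def test_fallback_to_argmax_when_cutoff_unmet(self):
        trace = _trace([(8, 0.70), (6, 0.80), (4, 0.75)])
        sel = select_optimal(trace, 0.90)
        assert not sel.cutoff_met
        assert sel.n_features == 6
        assert sel.global_accuracy == 0.80

    def test_sizes_strictly_decreasing_enforced(self):
        with pytest.raises(ValueError):
            _trace([(4, 0.9), (4, 0.8)])


class TestRecursion:
    def test_iteration_sizes_and_determinism(self):
        """Sizes follow repeated 20% floor reduction down to 1, and the
        same base seed reproduces the identical trace."""
        schema = small_schema(6, 2, 2)  # 10 features
        cfg = CohortConfig(n_control=6, n_treated=5, schema=schema,
                           informative_features=("spleen_f0",), seed=2)
        table, _ = generate_cohort(cfg)
        rfe = RFEConfig(n_repeats=2, n_folds=4, base_seed=9)
        t1 = recursive_selection(table, rfe)
        t2 = recursive_selection(table, rfe)
        assert t1.sizes() == [10, 8, 6, 4, 3, 2, 1]
        assert t1.to_dict() == t2.to_dict()

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            RFEConfig(reduction_fraction=1.5)
        with pytest.raises(ConfigError):
            RFEConfig(accuracy_cutoff=0.0)
        with pytest.raises(ConfigError):
            RFEConfig(n_folds=1)

    def test_classifier_factory_covers_all_families(self):
        for family in CLASSIFIER_FAMILIES:
            clf = make_classifier(family, 0)
            assert hasattr(clf, "fit")

    def test_effective_folds_fallback(self):
        y = np.array([0] * 11 + [1] * 8)
        assert effective_folds(y, 10) == 8
        assert effective_folds(y, 5) == 5
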