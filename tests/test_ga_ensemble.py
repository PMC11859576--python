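import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import joblib
from sklearn.ensemble import AdaBoostClassifier

from imbga.core_data import Dataset
from imbga.ga_ensemble import (
    CHROMOSOME_LENGTH,
    Chromosome,
    GAConfig,
    GPConfig,
    StackFitness,
    default_pool,
    exhaustive_search,
    fit_stack,
    ga_optimize,
    grid_search,
    multipoint_crossover,
    multipoint_mutation,
    predict,
    roulette_select,
)
from tests.conftest import make_imbalanced


@pytest.fixture(scope="module")
def small_data():
    return make_imbalanced(n_min=40, n_maj=110, sep=1.8, n_features=4, seed=13)


@pytest.fixture(scope="module")
def pool():
    return default_pool()


@pytest.fixture(scope="module")
def fitness(small_data, pool):
    return StackFitness(small_data, pool, cv_folds=3, rng_seed=5)


def chrom(*bits):
    return Chromosome(np.array(bits))


class TestChromosome:
    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            Chromosome(np.ones(7, dtype=int))

    def test_selected_indices(self):
        c = chrom(1, 0, 0, 1, 0, 0, 0, 0, 0, 1)
        assert c.selected_indices().tolist() == [0, 3, 9]


class TestRouletteSelection:
    def test_uniform_fitness_gives_quarter_probabilities(self, rng):
        pop = [chrom(*([1] + [0] * 9)) for _ in range(4)]
        for i, c in enumerate(pop):
            c.bits = np.zeros(10, dtype=int)
            c.bits[i] = 1
        picks = roulette_select(pop, [1, 1, 1, 1], 100_000, rng)
        freqs = np.bincount([int(c.selected_indices()[0]) for c in picks], minlength=4) / 1e5
        np.testing.assert_allclose(freqs, 0.25, atol=0.01)

    def test_one_three_fitness_matches_law(self, rng):
        pop = [chrom(1, *[0] * 9), chrom(0, 1, *[0] * 8)]
        picks = roulette_select(pop, [1, 3], 100_000, rng)
        freq1 = np.mean([c.bits[1] == 1 for c in picks])
        assert freq1 == pytest.approx(0.75, abs=0.01)

    def test_zero_draws_gives_empty(self, rng):
        assert roulette_select([chrom(1, *[0] * 9)], [1.0], 0, rng) == []

    def test_all_zero_fitness_uniform_with_warning(self, rng):
        pop = [chrom(1, *[0] * 9), chrom(0, 1, *[0] * 8)]
        with pytest.warns(UserWarning, match="zero"):
            picks = roulette_select(pop, [0.0, 0.0], 10, rng)
        assert len(picks) == 10

    def test_negative_fitness_rejected(self, rng):
        with pytest.raises(ValueError):
            roulette_select([chrom(1, *[0] * 9)], [-1.0], 1, rng)


class TestCrossover:
    def test_identical_parents_unchanged(self, rng):
        p = chrom(1, 0, 1, 0, 1, 0, 1, 0, 1, 0)
        a, b = multipoint_crossover(p, p, 3, rng)
        assert a.bits.tolist() == p.bits.tolist() == b.bits.tolist()

    def test_single_cut_at_five_forced(self, rng):
        a, b = multipoint_crossover(
            chrom(*[1] * 10), chrom(*[0] * 10), [5], rng
        )
        assert a.bits.tolist() == [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        assert b.bits.tolist() == [0, 0, 0, 0, 0, 1, 1, 1, 1, 1]

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.integers(0, 1), min_size=10, max_size=10),
        st.lists(st.integers(0, 1), min_size=10, max_size=10),
        st.integers(1, 9),
        st.integers(0, 2**31 - 1),
    )
    def test_per_position_bit_conservation(self, pa, pb, k, seed):
        rng = np.random.default_rng(seed)
        a, b = multipoint_crossover(chrom(*pa), chrom(*pb), k, rng)
        for pos in range(10):
            assert sorted([a.bits[pos], b.bits[pos]]) == sorted([pa[pos], pb[pos]])

    def test_too_many_cuts_rejected(self, rng):
        with pytest.raises(ValueError):
            multipoint_crossover(chrom(*[1] * 10), chrom(*[0] * 10), 10, rng)


class TestMutation:
    def test_rate_zero_identity(self, rng):
        c = chrom(1, 0, 1, 1, 0, 0, 0, 1, 0, 1)
        assert multipoint_mutation(c, 0.0, rng).bits.tolist() == c.bits.tolist()

    def test_rate_one_complements(self, rng):
        c = chrom(1, 0, 1, 1, 0, 0, 0, 1, 0, 1)
        assert multipoint_mutation(c, 1.0, rng).bits.tolist() == (1 - c.bits).tolist()

    def test_all_zero_result_repaired(self, rng):
        c = chrom(1, 1, 1, 1, 1, 1, 1, 1, 1, 1)
        out = multipoint_mutation(c, 1.0, rng)
        assert out.n_selected == 1  # complement is all-zero, one bit restored

    def test_expected_flip_count_binomial(self):
        rng = np.random.default_rng(0)
        base = chrom(*[1] * 10)  # repair can never trigger from all-ones at low rate
        flips = [
            int(np.sum(multipoint_mutation(base, 0.1, rng).bits != base.bits))
            for _ in range(100_000)
        ]
        assert np.mean(flips) == pytest.approx(1.0, abs=0.03)


class TestStacking:
    def test_single_member_stack_matches_member_cv_auc(self, small_data, pool, fitness):
        # meta over one column is a monotone map, so the single-member stack
        # scores like the member itself under the same folds
        idx = pool.names.index("logistic")
        bits = np.zeros(10, dtype=int)
        bits[idx] = 1
        fit_val = fitness(Chromosome(bits))
        assert fit_val == pytest.approx(fitness.member_cv_scores()[idx], abs=0.02)

    def test_perfect_feature_gives_perfect_fitness(self, pool):
        rng = np.random.default_rng(2)
        y = rng.permutation([0] * 40 + [1] * 80)
        X = np.column_stack([y.astype(float), rng.normal(size=len(y))])
        fit = StackFitness(Dataset(X, y), pool, cv_folds=3, rng_seed=0)
        assert fit(Chromosome(np.ones(10, dtype=int))) == pytest.approx(1.0)

    def test_oof_matrix_deterministic(self, small_data, pool):
        f1 = StackFitness(small_data, pool, 3, rng_seed=9)
        f2 = StackFitness(small_data, pool, 3, rng_seed=9)
        for a, b in zip(f1.folds, f2.folds):
            np.testing.assert_array_equal(a["Z_tr"], b["Z_tr"])
            np.testing.assert_array_equal(a["P_te"], b["P_te"])

    def test_all_zero_chromosome_rejected(self, small_data, pool):
        with pytest.raises(ValueError, match="no classifiers"):
            fit_stack(small_data, Chromosome(np.zeros(10, dtype=int)), pool, 3, 0)

    def test_predict_dimension_mismatch_names_features(self, small_data, pool):
        model = fit_stack(small_data, chrom(0, 0, 0, 1, 0, 0, 1, 0, 0, 0), pool, 3, 0)
        with pytest.raises(ValueError, match="feature columns"):
            predict(model, np.zeros((3, 7)))

    def test_predictions_are_probabilities(self, small_data, pool):
        model = fit_stack(small_data, chrom(0, 0, 0, 1, 0, 0, 1, 0, 0, 0), pool, 3, 0)
        p = predict(model, small_data.X)
        assert np.all((p > 0) & (p < 1))

    def test_serialization_round_trip(self, small_data, pool, tmp_path):
        model = fit_stack(small_data, chrom(0, 1, 0, 1, 0, 0, 0, 0, 0, 0), pool, 3, 0)
        path = tmp_path / "model.joblib"
        joblib.dump(model, path)
        reloaded = joblib.load(path)
        np.testing.assert_array_equal(
            predict(model, small_data.X), predict(reloaded, small_data.X)
        )


class TestGeneticSearch:
    def test_best_ever_history_non_decreasing(self, small_data, pool, fitness):
        _, hist = ga_optimize(
            small_data, pool, GAConfig(population_size=8, generations=6, rng_seed=3),
            cv_folds=3, fitness=fitness,
        )
        assert all(b2 >= b1 for b1, b2 in zip(hist["best_ever"], hist["best_ever"][1:]))

    def test_elitism_never_loses_best_initial(self, small_data, pool, fitness):
        best, hist = ga_optimize(
            small_data, pool, GAConfig(population_size=6, generations=5, rng_seed=11),
            cv_folds=3, fitness=fitness,
        )
        assert fitness(best) >= hist["best"][0]

    def test_ga_matches_exhaustive_on_shared_fitness(self, small_data, pool, fitness):
        _, best_val = exhaustive_search(small_data, pool, fitness=fitness)
        best, hist = ga_optimize(
            small_data, pool,
            GAConfig(population_size=20, generations=15, rng_seed=7),
            cv_folds=3, fitness=fitness,
        )
        assert best_val - fitness(best) <= 0.01

    def test_zero_generation_budget_returns_initial_best(self, small_data, pool, fitness):
        best, hist = ga_optimize(
            small_data, pool, GAConfig(population_size=5, generations=0, rng_seed=1),
            cv_folds=3, fitness=fitness,
        )
        assert len(hist["best"]) == 1
        assert fitness(best) == hist["best"][0]


class TestBoostingContract:
    def test_staged_decisions_are_cumulative_weighted_sums(self, small_data):
        """The boosting member's decision value is the weight-normalized sum
        of its weak learners' votes, accumulated stage by stage."""
        ada = AdaBoostClassifier(n_estimators=12, random_state=0)
        ada.fit(small_data.X, small_data.y)
        X = small_data.X[:20]
        weights = ada.estimator_weights_[: len(ada.estimators_)]
        votes = np.array(
            [np.where(w.predict(X) == ada.classes_[1], 1.0, -1.0) for w in ada.estimators_]
        )
        staged = list(ada.staged_decision_function(X))
        k_classes = len(ada.classes_)
        scale = k_classes / (k_classes - 1)  # SAMME's constant vote scaling
        for z, dec in enumerate(staged, start=1):
            manual = (weights[:z, None] * votes[:z]).sum(axis=0) / weights[:z].sum()
            np.testing.assert_allclose(dec, scale * manual, atol=1e-9)


class TestGridSearch:
    def test_single_point_grid_returned(self, small_data, pool):
        spec = pool.members[pool.names.index("logistic")]
        res = grid_search(spec, small_data, {"C": [1.0]}, cv_folds=3)
        assert res["params"] == {"C": 1.0}
        assert res["n_combinations"] == 1

    def test_degenerate_setting_loses(self, small_data, pool):
        # C=1e-8 regularizes logistic to a constant model; C=1 must win
        spec = pool.members[pool.names.index("logistic")]
        res = grid_search(spec, small_data, {"C": [1e-8, 1.0]}, cv_folds=3)
        assert res["params"] == {"C": 1.0}

    def test_full_enumeration_count(self, small_data, pool):
        spec = pool.members[pool.names.index("knn")]
        res = grid_search(
            spec, small_data, {"n_neighbors": [3, 5, 7], "weights": ["uniform", "distance"]},
            cv_folds=3,
        )
        assert res["n_combinations"] == 6

    def test_empty_grid_rejected(self, small_data, pool):
        with pytest.raises(ValueError, match="empty"):
            grid_search(pool.members[0], small_data, {}, cv_folds=3)


class TestGPConfig:
    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            GPConfig(noise_variance=-1.0)

    def test_kernel_includes_noise_term(self):
        k = GPConfig(noise_variance=0.5).kernel()
        assert "WhiteKernel" in repr(k)
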