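"""Architecture sizing, codebook initialisation, LVQ2.1 training and
nearest-codebook prediction."""

import numpy as np
import pytest

from eggscan.lvq import (LVQModel, TrainConfig, init_codebooks, predict,
                         size_competitive_layer, train_lvq21)


class TestSizing:
    def test_default_offset_reproduces_ten(self):
        assert size_competitive_layer(1, 2) == 10

    def test_small_offset_hand_value(self):
        # round(sqrt(3) + 1) = round(2.732) = 3
        assert size_competitive_layer(1, 2, a=1) == 3

    @pytest.mark.parametrize("a", [0, 11, -3])
    def test_offset_outside_range_raises(self, a):
        with pytest.raises(ValueError, match="1, 10"):
            size_competitive_layer(1, 2, a=a)

    def test_input_and_output_minimums(self):
        with pytest.raises(ValueError):
            size_competitive_layer(0, 2)
        with pytest.raises(ValueError):
            size_competitive_layer(1, 1)


def _two_class(rng, n_per=30, mean_a=0.0, mean_b=10.0, sd=0.5):
    X = np.concatenate([rng.normal(mean_a, sd, n_per),
                        rng.normal(mean_b, sd, n_per)])
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return X, y


class TestInit:
    def test_equal_classes_split_codebooks_evenly(self, rng):
        X, y = _two_class(rng)
        model = init_codebooks(X, y, m=10, seed=0)
        counts = dict(zip(*np.unique(model.codebook_classes,
                                     return_counts=True)))
        assert counts == {"a": 5, "b": 5}

    def test_minimum_one_codebook_per_class(self, rng):
        X, y = _two_class(rng)
        model = init_codebooks(X, y, m=2, seed=0)
        assert sorted(model.codebook_classes) == ["a", "b"]

    def test_proportional_allocation(self, rng):
        X = np.concatenate([rng.normal(0, 1, 60), rng.normal(5, 1, 30)])
        y = np.array(["a"] * 60 + ["b"] * 30)
        model = init_codebooks(X, y, m=9, seed=0)
        counts = dict(zip(*np.unique(model.codebook_classes,
                                     return_counts=True)))
        assert counts == {"a": 6, "b": 3}

    def test_zero_jitter_puts_codebooks_at_class_means(self, rng):
        X, y = _two_class(rng)
        model = init_codebooks(X, y, m=4, seed=0, jitter_scale=0.0)
        for cls in ("a", "b"):
            mean = X[y == cls].mean()
            np.testing.assert_allclose(
                model.codebooks[model.codebook_classes == cls], mean)

    def test_class_with_zero_samples_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            init_codebooks(np.zeros(4), np.array(["a"] * 4), m=4)


class TestTraining:
    def test_separable_classes_reach_zero_error_and_perfect_holdout(self, rng):
        X, y = _two_class(rng, n_per=30)
        model = init_codebooks(X, y, m=10, seed=1)
        train_lvq21(model, X, y, TrainConfig(seed=1))
        assert model.trained
        assert model.training_error == 0.0
        X_test, y_test = _two_class(np.random.default_rng(99), n_per=40)
        assert (predict(model, X_test) == y_test).all()

    def test_zero_learning_rate_is_identity(self, rng):
        X, y = _two_class(rng)
        model = init_codebooks(X, y, m=6, seed=2)
        before = model.codebooks.copy()
        train_lvq21(model, X, y, TrainConfig(learning_rate=0.0, seed=2))
        np.testing.assert_array_equal(model.codebooks, before)

    def test_inseparable_data_terminates_and_records_error(self, rng):
        X = rng.normal(0, 1, 40)
        y = np.array(["a", "b"] * 20)  # identical class distributions
        model = init_codebooks(X, y, m=6, seed=3)
        train_lvq21(model, X, y, TrainConfig(max_epochs=20, seed=3))
        assert model.trained
        assert 0.0 <= model.training_error <= 1.0
        assert model.training_error > 0.01  # never hit the goal

    def test_class_multiset_conserved_by_training(self, rng):
        X, y = _two_class(rng)
        model = init_codebooks(X, y, m=10, seed=4)
        before = sorted(model.codebook_classes)
        train_lvq21(model, X, y, TrainConfig(seed=4))
        assert sorted(model.codebook_classes) == before

    def test_training_is_deterministic(self, rng):
        X, y = _two_class(rng, mean_b=2.0, sd=1.0)

        def run():
            model = init_codebooks(X, y, m=10, seed=5)
            train_lvq21(model, X, y, TrainConfig(seed=5))
            return model.codebooks.copy(), predict(model, X)

        cb1, p1 = run()
        cb2, p2 = run()
        np.testing.assert_array_equal(cb1, cb2)
        assert (p1 == p2).all()

    def test_paired_update_pulls_correct_codebook_closer(self):
        # hand-built valid LVQ2.1 pair: nearest is wrong, runner-up correct,
        # sample inside the relative window
        from eggscan.lvq import LVQArchitecture

        model = LVQModel(
            codebooks=np.array([[1.0], [-1.1]]),
            codebook_classes=np.array(["wrong", "right"]),
            architecture=LVQArchitecture(n=1, m=2, l=2),
        )
        x = np.array([0.0])
        d_right_before = abs(model.codebooks[1, 0] - x[0])
        d_wrong_before = abs(model.codebooks[0, 0] - x[0])
        train_lvq21(model, np.array([x[0]]), np.array(["right"]),
                    TrainConfig(learning_rate=0.2, max_epochs=1, seed=0,
                                error_goal=0.0))
        assert abs(model.codebooks[1, 0] - x[0]) < d_right_before
        assert abs(model.codebooks[0, 0] - x[0]) > d_wrong_before

    def test_six_sigma_separation_99_percent_holdout_across_seeds(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = _two_class(rng, n_per=50, mean_a=0.0, mean_b=6.0, sd=1.0)
            model = init_codebooks(X, y, m=10, seed=seed)
            train_lvq21(model, X, y, TrainConfig(seed=seed))
            rng_test = np.random.default_rng(1000 + seed)
            X_test, y_test = _two_class(rng_test, n_per=100, mean_a=0.0,
                                        mean_b=6.0, sd=1.0)
            acc = float(np.mean(predict(model, X_test) == y_test))
            assert acc >= 0.99


class TestPredict:
    def test_exact_codebook_match(self, rng):
        X, y = _two_class(rng)
        model = init_codebooks(X, y, m=4, seed=6)
        for k in range(4):
            assert predict(model, model.codebooks[k]) == \
                model.codebook_classes[k]

    def test_equidistant_tie_breaks_to_lower_index(self):
        from eggscan.lvq import LVQArchitecture

        model = LVQModel(
            codebooks=np.array([[1.0], [-1.0]]),
            codebook_classes=np.array(["hi", "lo"]),
            architecture=LVQArchitecture(n=1, m=2, l=2),
        )
        assert predict(model, np.array(0.0)) == "hi"

    def test_matches_brute_force_scan_on_1000_cases(self):
        from eggscan.lvq import LVQArchitecture

        rng = np.random.default_rng(77)
        m, n = 12, 3
        model = LVQModel(
            codebooks=rng.normal(size=(m, n)),
            codebook_classes=rng.choice(["a", "b", "c"], size=m),
            architecture=LVQArchitecture(n=n, m=m, l=3),
        )
        X = rng.normal(size=(1000, n))
        got = predict(model, X)
        for i in range(1000):
            best, best_d = 0, np.inf
            for k in range(m):
                d = float(((X[i] - model.codebooks[k]) ** 2).sum())
                if d < best_d:  # strict: first minimiser wins ties
                    best, best_d = k, d
            assert got[i] == model.codebook_classes[best]

    def test_dimension_mismatch_raises(self, rng):
        X, y = _two_class(rng)
        model = init_codebooks(X, y, m=4, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros((5, 3)))
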