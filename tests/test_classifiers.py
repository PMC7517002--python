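"""OvO SVM introspection, gain-ratio tree, and the ELM closed-form fit."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from emosig.classifiers import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    decision_from_values,
    gain_ratio,
    predict_elm,
    svm_decide,
    train_dt,
    train_elm,
    train_svm,
)
from oracles import naive_gain_ratio


def blobs(rng, centers, n=20, scale=0.3):
    X = np.vstack([rng.normal(c, scale, size=(n, len(c))) for c in centers])
    y = np.repeat([f"c{k}" for k in range(len(centers))], n)
    return X, y


SMALL_C = (2.0**-1, 2.0**1, 2.0**3)
SMALL_G = (2.0**-3, 2.0**-1, 2.0**1)


class TestSvm:
    def test_separable_two_class_fits_perfectly(self, rng):
        X, y = blobs(rng, [(0, 0), (5, 5)])
        model = train_svm(X, y, SMALL_C, SMALL_G)
        assert np.mean(model.estimator.predict(X) == y) == 1.0

    def test_four_classes_give_six_pairwise_models(self, rng):
        X, y = blobs(rng, [(0, 0), (5, 0), (0, 5), (5, 5)])
        model = train_svm(X, y, SMALL_C, SMALL_G)
        assert len(model.pairs) == 6
        pd = svm_decide(model, X[0])
        assert len(pd.pair_values) == 6

    def test_grid_search_is_deterministic_and_stays_in_grid(self, rng):
        X, y = blobs(rng, [(0, 0), (2, 2), (4, 0)], scale=0.8)
        m1 = train_svm(X, y, SMALL_C, SMALL_G)
        m2 = train_svm(X, y, SMALL_C, SMALL_G)
        assert (m1.C, m1.gamma) == (m2.C, m2.gamma)
        assert m1.C in SMALL_C and m1.gamma in SMALL_G

    def test_tie_breaks_toward_smallest_C_then_gamma(self, rng):
        # perfectly separable data: many grid points reach the same CV
        # accuracy, so the winner must be the smallest (C, gamma)
        X, y = blobs(rng, [(0, 0), (50, 50)], scale=0.1)
        model = train_svm(X, y, SMALL_C, SMALL_G)
        best_acc = max(acc for *_ , acc in model.grid_record)
        candidates = [
            (C, g) for C, g, acc in model.grid_record if acc == best_acc
        ]
        assert (model.C, model.gamma) == min(candidates)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            train_svm(np.zeros((5, 2)), np.array(["a"] * 5))

    def test_default_grids_match_declared_ranges(self):
        assert DEFAULT_C_GRID[0] == 2.0**-5 and DEFAULT_C_GRID[-1] == 2.0**15
        assert DEFAULT_GAMMA_GRID[0] == 2.0**-15 and DEFAULT_GAMMA_GRID[-1] == 2.0**3

    def test_dimension_mismatch_rejected(self, rng):
        X, y = blobs(rng, [(0, 0), (5, 5)])
        model = train_svm(X, y, SMALL_C, SMALL_G)
        with pytest.raises(ValueError, match="dimension"):
            svm_decide(model, np.zeros(7))


class TestPairwiseDecision:
    def test_unanimous_winner_gets_three_votes(self):
        # all three pairs involving A favor A; remaining pairs arbitrary
        pd = decision_from_values("ABCD", [1.0, 1.0, 1.0, 0.5, 0.5, 0.5])
        assert pd.votes["A"] == 3
        assert pd.top == "A"

    def test_votes_conserved_in_given_example(self):
        # f_AB>0, f_AC>0, f_AD<0, f_BC>0, f_BD>0, f_CD>0
        pd = decision_from_values("ABCD", [0.3, 0.2, -0.1, 0.4, 0.6, 0.2])
        assert sum(pd.votes.values()) == 6
        assert pd.votes == {"A": 2, "B": 2, "C": 1, "D": 1}

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=6, max_size=6))
    def test_votes_always_sum_to_six(self, values):
        pd = decision_from_values("ABCD", values)
        assert sum(pd.votes.values()) == 6
        assert all(0 <= v <= 3 for v in pd.votes.values())

    def test_ranking_breaks_vote_ties_by_signed_margin(self):
        # A and B both take 2 votes; B's favor sum is larger
        pd = decision_from_values("ABCD", [-0.9, 0.1, 0.1, 1.0, -1.0, 0.5])
        assert pd.votes["A"] == pd.votes["B"] == 2
        assert pd.top == "B"


class TestDecisionTree:
    def test_pure_input_gives_single_leaf(self):
        model = train_dt(np.random.default_rng(0).normal(size=(10, 3)), ["a"] * 10)
        assert model.root.is_leaf and model.root.label == "a"

    def test_single_feature_threshold_split(self):
        X = np.array([[-3.0], [-2.0], [-1.0], [1.0], [2.0], [3.0]])
        y = np.array(["neg", "neg", "neg", "pos", "pos", "pos"])
        model = train_dt(X, y)
        assert not model.root.is_leaf
        assert model.root.threshold == pytest.approx(0.0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_root_gain_ratio_matches_hand_computation(self):
        # 8 samples, 2 features; feature 0 separates imperfectly, feature 1
        # perfectly -- the root split must pick feature 1 at its best
        # threshold, and the reported score must equal the from-definition
        # oracle value.
        X = np.array([
            [1.0, 0.2], [2.0, 0.3], [3.0, 0.9], [4.0, 0.1],
            [5.0, 0.8], [6.0, 0.7], [7.0, 0.2], [8.0, 0.95],
        ])
        y = np.array(["A", "A", "B", "A", "B", "B", "A", "B"])
        gr0, thr0 = gain_ratio(X[:, 0], y)
        gr1, thr1 = gain_ratio(X[:, 1], y)
        assert gr0 == pytest.approx(naive_gain_ratio(X[:, 0], y, thr0), abs=1e-12)
        assert gr1 == pytest.approx(naive_gain_ratio(X[:, 1], y, thr1), abs=1e-12)
        assert gr1 == pytest.approx(1.0)  # perfect binary split
        assert thr1 == pytest.approx(0.5)
        model = train_dt(X, y)
        assert model.root.feature == 1
        assert np.mean(model.predict(X) == y) == 1.0

    def test_training_accuracy_nondecreasing_as_epsilon_shrinks(self, rng):
        X = rng.normal(size=(60, 4))
        y = np.where(X[:, 0] + 0.5 * X[:, 2] + 0.3 * rng.normal(size=60) > 0, "p", "n")
        accs = []
        for eps in (0.5, 0.1, 1e-7):
            model = train_dt(X, y, epsilon=eps)
            accs.append(np.mean(model.predict(X) == y))
        assert accs == sorted(accs)

    def test_large_epsilon_gives_majority_leaf(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.array(["a"] * 20 + ["b"] * 10)
        model = train_dt(X, y, epsilon=10.0)
        assert model.root.is_leaf and model.root.label == "a"

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_dt(np.zeros((0, 2)), np.array([]))


class TestElm:
    def test_square_full_rank_system_fits_exactly(self, rng):
        X = rng.normal(size=(30, 5))
        y = np.array(["a", "b", "c"] * 10)
        model = train_elm(X, y, M=30, seed=1)
        H = model.hidden(X)
        Y = np.zeros((30, 3))
        Y[np.arange(30), [model.classes.index(v) for v in y]] = 1.0
        assert np.linalg.norm(H @ model.beta - Y) < 1e-6
        assert np.mean(model.predict(X) == y) == 1.0

    def test_same_seed_reproduces_weights(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array(["a", "b"] * 10)
        m1 = train_elm(X, y, M=15, seed=42)
        m2 = train_elm(X, y, M=15, seed=42)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(m1.biases, m2.biases)
        np.testing.assert_array_equal(m1.beta, m2.beta)

    def test_hidden_weights_drawn_uniform_pm1(self, rng):
        X = rng.normal(size=(10, 4))
        model = train_elm(X, np.array(["a", "b"] * 5), M=200, seed=0)
        assert model.weights.min() >= -1.0 and model.weights.max() <= 1.0
        assert model.biases.min() >= -1.0 and model.biases.max() <= 1.0

    def test_separable_blobs_high_training_accuracy(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = blobs(rng, [(0, 0), (4, 4), (0, 4)], n=20, scale=0.5)
            model = train_elm(X, y, M=50, seed=seed)
            accs.append(np.mean(model.predict(X) == y))
        assert np.mean(accs) >= 0.95

    def test_residual_is_least_squares_minimal(self, rng):
        X = rng.normal(size=(40, 6))
        y = np.array(["a", "b", "c", "d"] * 10)
        model = train_elm(X, y, M=12, seed=3)
        H = model.hidden(X)
        Y = np.zeros((40, 4))
        Y[np.arange(40), [model.classes.index(v) for v in y]] = 1.0
        beta_lstsq, *_ = np.linalg.lstsq(H, Y, rcond=None)
        r_model = np.linalg.norm(H @ model.beta - Y)
        r_lstsq = np.linalg.norm(H @ beta_lstsq - Y)
        assert r_model == pytest.approx(r_lstsq, abs=1e-8)

    def test_zero_hidden_size_rejected(self, rng):
        with pytest.raises(ValueError, match="M"):
            train_elm(rng.normal(size=(5, 2)), np.array(["a", "b", "a", "b", "a"]), M=0)

    def test_predict_single_vector(self, rng):
        X, y = blobs(rng, [(0, 0), (6, 6)], n=15, scale=0.3)
        model = train_elm(X, y, M=30, seed=0)
        assert predict_elm(model, X[0]) == y[0]

    def test_rbf_activation_variant(self, rng):
        X, y = blobs(rng, [(0, 0), (5, 5)], n=15, scale=0.4)
        model = train_elm(X, y, M=40, seed=0, activation="rbf")
        assert np.mean(model.predict(X) == y) >= 0.9
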