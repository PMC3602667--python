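"""MyC tree, base-learner dispatch, conditional risk, and MetaCost."""

import numpy as np
import pytest

from emrcase import (
    BaseLearnerSpec,
    CostMatrix,
    conditional_risk_relabel,
    metacost_train,
    myc_predict,
    myc_train,
    train_base,
)
from emrcase.features import chi_square_statistic
from emrcase.learners import NEGATIVE, POSITIVE


def greedy_oracle(X, y, alpha=0.05, used=frozenset()):
    """Exhaustive-search greedy reference: score every unused feature with the
    closed-form 2x2 statistic, recurse like the tree does, return the
    prediction function as a dict over observed rows."""
    from scipy import stats

    X, y = np.asarray(X), np.asarray(y)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    majority = POSITIVE if n_pos >= n_neg else NEGATIVE
    if n_pos == 0 or n_neg == 0 or len(used) == X.shape[1]:
        return majority
    best, best_stat = None, -1.0
    for j in range(X.shape[1]):
        if j in used:
            continue
        a = int(((X[:, j] == 1) & (y == 1)).sum())
        b = int(((X[:, j] == 1) & (y == 0)).sum())
        stat, _ = chi_square_statistic(a, b, n_pos - a, n_neg - b)
        if stat > best_stat:
            best, best_stat = j, stat
    if not best_stat > stats.chi2.isf(alpha, 1):
        return majority
    present = X[:, best] == 1
    if present.all() or not present.any():
        return majority
    return {
        "feature": best,
        "absent": greedy_oracle(X[~present], y[~present], alpha, used | {best}),
        "present": greedy_oracle(X[present], y[present], alpha, used | {best}),
    }


def oracle_predict(node, x):
    while isinstance(node, dict):
        node = node["present"] if x[node["feature"]] else node["absent"]
    return node


class TestMyc:
    def test_perfect_separator_gives_one_split(self):
        X = np.array([[1, 0]] * 5 + [[0, 1]] * 5)
        y = np.array([1] * 5 + [0] * 5)
        tree = myc_train(X, y)
        assert tree.depth() == 1 and tree.n_leaves() == 2
        assert (tree.predict(X) == y).all()

    def test_uninformative_features_give_single_majority_leaf(self):
        X = np.array([[1], [0], [1], [0], [1], [0]])
        y = np.array([1, 1, 0, 0, 1, 0])  # feature independent of label
        tree = myc_train(X, y)
        assert tree.depth() == 0
        assert tree.root.label == POSITIVE  # 3-3 tie resolves positive

    def test_agrees_with_brute_force_greedy_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            X = rng.integers(0, 2, size=(20, 5))
            y = ((X[:, 0] & X[:, 1]) | (rng.random(20) < 0.15)).astype(int)
            if len(np.unique(y)) < 2:
                continue
            tree = myc_train(X, y)
            oracle = greedy_oracle(X, y)
            for x in X:
                assert myc_predict(tree, x) == oracle_predict(oracle, x)

    def test_training_replay_self_consistency(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(40, 6))
        y = (X[:, 2] | (rng.random(40) < 0.1)).astype(int)
        tree = myc_train(X, y)
        # every training example reaches a leaf whose recorded counts include it
        preds = tree.predict(X)
        assert set(np.unique(preds)) <= {0, 1}
        for x, pred in zip(X, preds):
            assert myc_predict(tree, x) == pred

    def test_order_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.integers(0, 2, size=(30, 4))
        y = (X[:, 1] ^ (rng.random(30) < 0.2)).astype(int)
        perm = rng.permutation(30)
        t1, t2 = myc_train(X, y), myc_train(X[perm], y[perm])
        grid = np.array(np.meshgrid(*[[0, 1]] * 4)).T.reshape(-1, 4)
        assert (t1.predict(grid) == t2.predict(grid)).all()

    def test_depth_bounded_by_feature_count(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 2, size=(200, 3))
        y = rng.integers(0, 2, size=200)
        assert myc_train(X, y).depth() <= 3

    def test_zero_vector_follows_absent_branch(self):
        X = np.array([[1]] * 5 + [[0]] * 5)
        y = np.array([1] * 5 + [0] * 5)
        tree = myc_train(X, y)
        assert myc_predict(tree, np.array([0])) == NEGATIVE

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            myc_train(np.empty((0, 2)), np.empty(0))

    def test_laplace_leaf_probabilities(self):
        X = np.array([[1]] * 4 + [[0]] * 6)
        y = np.array([1] * 4 + [0] * 6)
        tree = myc_train(X, y)
        p = tree.predict_proba_positive(np.array([[1], [0]]))
        assert p[0] == pytest.approx(5 / 6)   # (4+1)/(4+2)
        assert p[1] == pytest.approx(1 / 8)   # (0+1)/(6+2)


class TestBaseDispatch:
    @pytest.mark.parametrize("family", ["myc", "decision_tree", "rule_inducer", "linear_margin"])
    def test_separable_toy_data_fit_perfectly(self, family):
        X = np.array([[1, 0]] * 6 + [[0, 1]] * 6)
        y = np.array([1] * 6 + [0] * 6)
        model = train_base(BaseLearnerSpec(family), X, y)
        assert (model.predict(X) == y).all()

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            BaseLearnerSpec("boosted_stumps")

    def test_single_class_training_degenerates_to_constant(self):
        model = train_base(BaseLearnerSpec("myc"), np.array([[0], [1]]), np.array([1, 1]))
        assert (model.predict(np.array([[0], [1]])) == 1).all()


class TestConditionalRisk:
    def test_two_term_risk_arithmetic(self):
        # risk(pos) = 0.7 * 1 < risk(neg) = 0.3 * 10
        assert conditional_risk_relabel(0.3, CostMatrix(cost_fn=10)) == POSITIVE

    def test_unit_costs_pick_majority(self):
        assert conditional_risk_relabel(0.3, CostMatrix(cost_fn=1)) == NEGATIVE
        assert conditional_risk_relabel(0.8, CostMatrix(cost_fn=1)) == POSITIVE

    def test_tie_resolves_positive(self):
        assert conditional_risk_relabel(0.5, CostMatrix(cost_fn=1)) == POSITIVE

    def test_probability_validated(self):
        with pytest.raises(ValueError):
            conditional_risk_relabel(1.2, CostMatrix(cost_fn=1))

    def test_cost_matrix_contract(self):
        cm = CostMatrix(cost_fn=25.0)
        assert cm.cost(POSITIVE, POSITIVE) == 0
        assert cm.cost(NEGATIVE, POSITIVE) == 25.0
        assert cm.cost(POSITIVE, NEGATIVE) == 1.0
        with pytest.raises(ValueError):
            CostMatrix(cost_fn=-1)


class TestMetaCost:
    def _imbalanced_data(self, seed=0, n=300, p_pos=0.12):
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < p_pos).astype(int)
        X = np.zeros((n, 6), dtype=np.int8)
        for i in range(n):
            if y[i]:
                X[i, rng.integers(0, 3)] = 1
            if rng.random() < 0.25:
                X[i, rng.integers(2, 6)] = 1
        return X, y

    def test_unit_costs_keep_correctly_voted_labels(self):
        X, y = self._imbalanced_data()
        model = metacost_train(BaseLearnerSpec("myc"), X, y, CostMatrix(cost_fn=1),
                               n_resamples=10, rng=1)
        vote_label = (model.vote_fraction >= 0.5).astype(int)
        agree = vote_label == y
        assert (model.relabeled_y[agree] == y[agree]).all()

    def test_relabeled_positive_count_non_decreasing_in_cost(self):
        X, y = self._imbalanced_data(seed=4)
        counts = []
        for c in (1, 10, 25, 50, 100, 200, 400, 800, 1000):
            model = metacost_train(BaseLearnerSpec("myc"), X, y,
                                   CostMatrix(cost_fn=float(c)), n_resamples=10, rng=7)
            counts.append(int(model.relabeled_y.sum()))
        assert counts == sorted(counts)

    def test_extreme_cost_relabels_nearly_everything_positive(self):
        X, y = self._imbalanced_data(seed=2)
        model = metacost_train(BaseLearnerSpec("myc"), X, y,
                               CostMatrix(cost_fn=1000.0), n_resamples=10, rng=3)
        assert model.relabeled_y.mean() > 0.95

    def test_fixed_seed_reproducible(self):
        X, y = self._imbalanced_data(seed=9)
        runs = [
            metacost_train(BaseLearnerSpec("myc"), X, y, CostMatrix(cost_fn=50),
                           n_resamples=5, rng=123).relabeled_y
            for _ in range(2)
        ]
        assert (runs[0] == runs[1]).all()

    def test_resample_count_validated(self):
        with pytest.raises(ValueError):
            metacost_train(BaseLearnerSpec("myc"), np.array([[1]]), np.array([1]),
                           CostMatrix(cost_fn=1), n_resamples=0)
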