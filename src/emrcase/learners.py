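"""Base learners, the MyC chi-square decision tree, and MetaCost.

MyC is a greedy binary decision tree in the ID3 family: at each node it
splits on the unused feature with the largest chi-square association
(presence vs label) among those significant at ``alpha``, and stops when
the node is pure, no feature is significant, or no features remain.  Leaf
labels are the node majority, ties resolving to the positive class — the
pipeline's objective is sensitivity-first.

MetaCost makes any base learner cost-sensitive without modifying it: it
trains an ensemble on bootstrap resamples, estimates each training
example's probability of being positive as the fraction of ensemble models
voting positive, relabels every example to minimize conditional risk under
the cost matrix, and retrains the base learner on the relabeled data.

External tree / rule / linear-margin learners plug in behind the
:class:`TrainedModel` contract; their internals are off-the-shelf
(scikit-learn) — only MyC and MetaCost are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np

from .features import DEFAULT_ALPHA

POSITIVE, NEGATIVE = 1, 0

#: Misclassification-cost grid swept in the cost-sensitive experiments.
COST_GRID = (1, 10, 25, 50, 100, 200, 400, 800, 1000)

FAMILIES = ("myc", "decision_tree", "rule_inducer", "linear_margin")


@dataclass(frozen=True)
class CostMatrix:
    """Misclassification costs; correct predictions cost 0.

    ``cost_fn`` is the cost of predicting negative for a true positive (the
    swept parameter); ``cost_fp`` the converse, fixed at 1 by convention.
    """

    cost_fn: float
    cost_fp: float = 1.0

    def __post_init__(self) -> None:
        if self.cost_fn < 0 or self.cost_fp < 0:
            raise ValueError("costs must be non-negative")

    def cost(self, predicted: int, actual: int) -> float:
        if predicted == actual:
            return 0.0
        return self.cost_fn if actual == POSITIVE else self.cost_fp


@dataclass(frozen=True)
class BaseLearnerSpec:
    """Which base-learner family to train, plus family hyperparameters."""

    family: str = "myc"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}; choose from {FAMILIES}")


class TrainedModel:
    """Deterministic prediction contract: binary feature matrix -> labels.

    ``predict_proba_positive`` is the optional class-probability contract;
    the default degrades to hard 0/1 votes.
    """

    def predict(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        return (self.predict(X) == POSITIVE).astype(np.float64)


# ---------------------------------------------------------------------------
# MyC
# ---------------------------------------------------------------------------

@dataclass
class MycNode:
    """Tree node: a leaf (label + class counts) or an internal split."""

    label: int | None = None
    counts: tuple[int, int] = (0, 0)  # (n_negative, n_positive)
    feature: int | None = None
    absent: "MycNode | None" = None
    present: "MycNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class MycTree(TrainedModel):
    root: MycNode
    alpha: float = DEFAULT_ALPHA
    n_features: int = 0

    def predict_one(self, x: np.ndarray) -> int:
        node = self.root
        while not node.is_leaf:
            node = node.present if x[node.feature] else node.absent
        return node.label

    def _leaf_of(self, x: np.ndarray) -> MycNode:
        node = self.root
        while not node.is_leaf:
            node = node.present if x[node.feature] else node.absent
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        return np.fromiter((self.predict_one(x) for x in X), dtype=np.int64, count=len(X))

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        """Laplace-corrected leaf frequency of the positive class.

        The +1/+2 correction keeps pure leaves off the 0/1 boundary, the
        standard choice for probability-estimation trees: a large pure
        negative leaf is more confidently negative than a small one.
        """
        X = np.asarray(X)
        out = np.empty(len(X), dtype=np.float64)
        for i, x in enumerate(X):
            n_neg, n_pos = self._leaf_of(x).counts
            out[i] = (n_pos + 1) / (n_neg + n_pos + 2)
        return out

    def depth(self) -> int:
        def _d(node: MycNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.absent), _d(node.present))

        return _d(self.root)

    def n_leaves(self) -> int:
        def _n(node: MycNode) -> int:
            if node.is_leaf:
                return 1
            return _n(node.absent) + _n(node.present)

        return _n(self.root)


def _majority(y: np.ndarray) -> tuple[int, tuple[int, int]]:
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    label = POSITIVE if n_pos >= n_neg else NEGATIVE  # tie -> positive
    return label, (n_neg, n_pos)


def _node_chi2(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 2x2 chi-square (presence vs label) for every feature at a node."""
    n = len(y)
    n_pos = float(y.sum())
    n_neg = n - n_pos
    a = (X[y == 1].sum(axis=0)).astype(np.float64)  # positive, token present
    b = (X[y == 0].sum(axis=0)).astype(np.float64)  # negative, token present
    c = n_pos - a
    d = n_neg - b
    r1, r2 = a + b, c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / (r1 * r2 * n_pos * n_neg)
    stat = np.where((r1 == 0) | (r2 == 0) | (n_pos == 0) | (n_neg == 0), 0.0, stat)
    return stat, r1


def myc_train(X: np.ndarray, y: np.ndarray, alpha: float = DEFAULT_ALPHA) -> MycTree:
    """Grow a MyC tree on a binary feature matrix.

    Split choice at a node is the unused feature with the largest
    chi-square statistic, provided its p-value beats ``alpha`` (1 df);
    equal statistics break toward the lower feature index.  No feature
    repeats on a root-to-leaf path, so depth <= number of features.
    """
    from scipy import stats as _st

    X = np.asarray(X, dtype=np.int8)
    y = np.asarray(y, dtype=np.int8)
    if X.ndim != 2 or len(X) != len(y) or len(y) == 0:
        raise ValueError("X must be a non-empty (n, d) matrix aligned with y")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    # chi-square critical value at alpha, 1 df: compare statistics directly
    crit = float(_st.chi2.isf(alpha, df=1))

    def grow(idx: np.ndarray, used: frozenset[int]) -> MycNode:
        ysub = y[idx]
        label, counts = _majority(ysub)
        if counts[0] == 0 or counts[1] == 0 or len(used) == X.shape[1]:
            return MycNode(label=label, counts=counts)
        stat, _ = _node_chi2(X[idx], ysub)
        if used:
            stat = stat.copy()
            stat[list(used)] = -np.inf
        best = int(np.argmax(stat))
        if not stat[best] > crit:
            return MycNode(label=label, counts=counts)
        mask = X[idx, best] == 1
        if not mask.any() or mask.all():  # degenerate split, stop
            return MycNode(label=label, counts=counts)
        used2 = used | {best}
        return MycNode(
            label=None,
            counts=counts,
            feature=best,
            absent=grow(idx[~mask], used2),
            present=grow(idx[mask], used2),
        )

    root = grow(np.arange(len(y)), frozenset())
    return MycTree(root=root, alpha=alpha, n_features=X.shape[1])


def myc_predict(tree: MycTree, x: np.ndarray) -> int:
    """Follow presence/absence branches to a leaf; return its label."""
    return tree.predict_one(np.asarray(x))


# ---------------------------------------------------------------------------
# External base learners (scikit-learn backed)
# ---------------------------------------------------------------------------

class _SklearnModel(TrainedModel):
    def __init__(self, estimator):
        self._est = estimator

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 1:
            X = X[None, :]
        return np.asarray(self._est.predict(X), dtype=np.int64)

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X))
        if hasattr(self._est, "predict_proba"):
            proba = self._est.predict_proba(X)
            pos_col = list(self._est.classes_).index(POSITIVE)
            return np.asarray(proba[:, pos_col], dtype=np.float64)
        return super().predict_proba_positive(X)


class _ConstantModel(TrainedModel):
    """Single-class training data degenerates to a constant predictor."""

    def __init__(self, label: int):
        self.label = int(label)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(np.atleast_2d(X)), self.label, dtype=np.int64)


def train_base(spec: BaseLearnerSpec, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    """Dispatch to MyC or a conforming scikit-learn learner.

    ``decision_tree`` and ``rule_inducer`` are backed by CART trees (a
    tree's root-to-leaf paths read as an ordered rule set); ``linear_margin``
    is a linear-kernel soft-margin SVM with c = 4.
    """
    X = np.asarray(X, dtype=np.int8)
    y = np.asarray(y, dtype=np.int64)
    if len(np.unique(y)) < 2:
        return _ConstantModel(y[0] if len(y) else NEGATIVE)
    hp = dict(BaseLearnerSpec(spec.family, spec.hyperparameters).hyperparameters)
    if spec.family == "myc":
        return myc_train(X, y, alpha=float(hp.pop("alpha", DEFAULT_ALPHA)))
    if X.shape[1] == 0:
        label, _ = _majority(y)
        return _ConstantModel(label)
    if spec.family == "decision_tree":
        from sklearn.tree import DecisionTreeClassifier

        est = DecisionTreeClassifier(random_state=0, **hp)
    elif spec.family == "rule_inducer":
        from sklearn.tree import DecisionTreeClassifier

        hp.setdefault("criterion", "entropy")
        est = DecisionTreeClassifier(random_state=0, **hp)
    elif spec.family == "linear_margin":
        from sklearn.svm import LinearSVC

        hp.setdefault("C", 4.0)
        est = LinearSVC(random_state=0, **hp)
    else:  # pragma: no cover - guarded by BaseLearnerSpec
        raise ValueError(f"unknown family {spec.family!r}")
    est.fit(X, y)
    return _SklearnModel(est)


# ---------------------------------------------------------------------------
# MetaCost
# ---------------------------------------------------------------------------

def conditional_risk_relabel(p_positive: float, cost: CostMatrix) -> int:
    """Label minimizing expected misclassification cost; ties go positive.

    Risk of predicting positive is ``(1 - p) * cost_fp``; of predicting
    negative, ``p * cost_fn``.
    """
    if not 0 <= p_positive <= 1:
        raise ValueError("p_positive must be a probability")
    risk_pos = (1.0 - p_positive) * cost.cost_fp
    risk_neg = p_positive * cost.cost_fn
    return POSITIVE if risk_pos <= risk_neg else NEGATIVE


@dataclass
class MetaCostModel(TrainedModel):
    """Final relabel-trained model plus the relabeling diagnostics."""

    final_model: TrainedModel
    relabeled_y: np.ndarray
    vote_fraction: np.ndarray
    cost: CostMatrix
    n_resamples: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.final_model.predict(X)


def metacost_train(
    base: BaseLearnerSpec,
    X: np.ndarray,
    y: np.ndarray,
    cost: CostMatrix,
    n_resamples: int = 10,
    rng: Union[np.random.Generator, int, None] = None,
) -> MetaCostModel:
    """Cost-sensitive meta-learning by bootstrap ensemble and risk relabeling.

    Draws ``n_resamples`` bootstrap samples (with replacement, size n),
    trains the base learner on each, estimates P(positive | x) for every
    training example by averaging the models' class-probability estimates
    (leaf frequencies for trees; learners without probabilities contribute
    hard 0/1 votes) — all models score all examples — relabels by
    conditional risk, and trains the final base model on the relabeled
    data.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=np.int8)
    y = np.asarray(y, dtype=np.int64)
    n = len(y)
    votes = np.zeros(n, dtype=np.float64)
    for r in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        try:
            model = train_base(base, X[idx], y[idx])
        except Exception as exc:  # noqa: BLE001 - annotate the failing resample
            raise RuntimeError(f"base learner failed on bootstrap resample {r}") from exc
        votes += model.predict_proba_positive(X)
    p_pos = votes / n_resamples
    relabeled = np.fromiter(
        (conditional_risk_relabel(p, cost) for p in p_pos), dtype=np.int64, count=n
    )
    final = train_base(base, X, relabeled)
    return MetaCostModel(
        final_model=final,
        relabeled_y=relabeled,
        vote_fraction=p_pos,
        cost=cost,
        n_resamples=n_resamples,
    )
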