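"""The three base learners of the committee, with the introspection the
referral strategy needs.

* :func:`train_svm` — one-vs-one RBF-SVM with (C, gamma) chosen by grid
  search over stratified cross-validation.  :func:`svm_decide` exposes the
  signed pairwise decision values and per-class vote tallies that the
  referral rule consumes.
* :func:`train_dt` — a gain-ratio decision tree for continuous features:
  binary threshold splits at midpoints of sorted unique values, scored by
  information gain divided by split information (the C4.5 criterion), grown
  until nodes are pure or the best gain ratio falls below a threshold.
* :func:`train_elm` — an extreme learning machine: random fixed hidden
  layer, output weights solved in closed form through the Moore-Penrose
  pseudo-inverse against one-hot targets.

Sign convention for pairwise decision values (verified against libsvm): for
the ordered class pair (i, j) with i before j in sorted class order, a
positive value favors class *i*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "SvmModel",
    "PairwiseDecision",
    "train_svm",
    "svm_decide",
    "DtModel",
    "train_dt",
    "ElmModel",
    "train_elm",
    "predict_elm",
]

# Exponential grids: C in 2^-5..2^15, gamma in 2^-15..2^3, step 2^2.
DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** k for k in range(-15, 4, 2))


# ---------------------------------------------------------------------------
# one-vs-one RBF-SVM


@dataclass
class SvmModel:
    estimator: SVC
    classes: tuple
    C: float
    gamma: float
    grid_record: list = field(default_factory=list)  # (C, gamma, cv_accuracy)

    @property
    def pairs(self) -> list[tuple]:
        """Ordered class pairs matching the decision-function columns."""
        return list(combinations(self.classes, 2))


def train_svm(
    X,
    y,
    c_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    cv_folds: int = 5,
) -> SvmModel:
    """Grid-search (C, gamma) by stratified CV accuracy and refit on all data.

    Ties are broken toward the smallest C, then the smallest gamma.  The
    search is deterministic (folds are unshuffled), so identical inputs
    select identical hyperparameters.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("SVM training requires at least 2 classes")
    counts = [np.sum(y == c) for c in classes]
    folds = min(cv_folds, min(counts))
    record = []
    best = None
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=False)
        splits = list(skf.split(X, y))
        for C in sorted(c_grid):
            for gamma in sorted(gamma_grid):
                correct = 0
                for tr, te in splits:
                    clf = SVC(kernel="rbf", C=C, gamma=gamma)
                    clf.fit(X[tr], y[tr])
                    correct += int(np.sum(clf.predict(X[te]) == y[te]))
                acc = correct / len(y)
                record.append((C, gamma, acc))
                if best is None or acc > best[2]:
                    best = (C, gamma, acc)
        C, gamma = best[0], best[1]
    else:  # too few samples per class to cross-validate: take grid medians
        C = sorted(c_grid)[len(c_grid) // 2]
        gamma = sorted(gamma_grid)[len(gamma_grid) // 2]
    est = SVC(kernel="rbf", C=C, gamma=gamma, decision_function_shape="ovo")
    est.fit(X, y)
    return SvmModel(
        estimator=est,
        classes=tuple(est.classes_),
        C=C,
        gamma=gamma,
        grid_record=record,
    )


@dataclass
class PairwiseDecision:
    """OvO decision values and vote tallies for one sample.

    ``pair_values[(i, j)]`` is the signed decision value of the binary
    classifier for the ordered pair; positive favors ``i``.  Each pair casts
    exactly one vote, so votes sum to k(k-1)/2.  ``ranking`` orders classes
    by votes, ties broken by the summed signed decision values in the
    class's favor.
    """

    classes: tuple
    pair_values: dict
    votes: dict
    ranking: list

    @property
    def top(self):
        return self.ranking[0]

    @property
    def second(self):
        return self.ranking[1]

    def values_involving(self, cls) -> list[float]:
        """|decision values| of the k-1 pairwise models involving a class."""
        return [
            abs(v) for (i, j), v in self.pair_values.items() if cls in (i, j)
        ]


def decision_from_values(classes, values) -> PairwiseDecision:
    """Build votes and ranking from raw OvO decision values.

    ``values`` follows the canonical column order: pairs (i, j) for i < j in
    class order, positive favoring the first class.  Zero values vote for
    the first class of the pair.
    """
    classes = tuple(classes)
    pairs = list(combinations(classes, 2))
    if len(values) != len(pairs):
        raise ValueError(f"expected {len(pairs)} decision values, got {len(values)}")
    pair_values = dict(zip(pairs, (float(v) for v in values)))
    votes = {c: 0 for c in classes}
    favor = {c: 0.0 for c in classes}
    for (i, j), v in pair_values.items():
        votes[i if v >= 0 else j] += 1
        favor[i] += v
        favor[j] -= v
    ranking = sorted(classes, key=lambda c: (-votes[c], -favor[c]))
    return PairwiseDecision(
        classes=classes, pair_values=pair_values, votes=votes, ranking=ranking
    )


def svm_decide(model: SvmModel, x) -> PairwiseDecision:
    """Pairwise decision values, votes and class ranking for one sample."""
    x = np.asarray(x, float).reshape(1, -1)
    if x.shape[1] != model.estimator.n_features_in_:
        raise ValueError(
            f"feature dimension {x.shape[1]} != model's "
            f"{model.estimator.n_features_in_}"
        )
    values = model.estimator.decision_function(x)[0]
    return decision_from_values(model.classes, np.atleast_1d(values))


# ---------------------------------------------------------------------------
# gain-ratio decision tree


@dataclass
class DtNode:
    feature: int | None = None
    threshold: float | None = None
    left: "DtNode | None" = None   # samples with value <= threshold
    right: "DtNode | None" = None  # samples with value > threshold
    label: object | None = None    # set on leaves

    @property
    def is_leaf(self) -> bool:
        return self.label is not None


@dataclass
class DtModel:
    root: DtNode
    classes: tuple
    epsilon: float

    def predict_one(self, x):
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.label

    def predict(self, X):
        X = np.asarray(X, float)
        return np.array([self.predict_one(row) for row in X])


def _entropy_bits(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log2(p)))


def _best_threshold(x: np.ndarray, y_codes: np.ndarray, n_classes: int):
    """Best (gain_ratio, threshold) of binary splits on one feature.

    Candidate thresholds are midpoints of consecutive sorted unique values;
    entropies on both sides are computed from cumulative class counts in one
    sorted pass.
    """
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y_codes[order]
    n = len(xs)
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), ys] = 1.0
    cum = np.cumsum(onehot, axis=0)  # class counts in the first i+1 samples
    # split after position i is valid when xs[i] < xs[i+1]
    valid = np.nonzero(xs[:-1] < xs[1:])[0]
    if len(valid) == 0:
        return None
    total = cum[-1]
    h_parent = _entropy_bits(total)
    best = None
    for i in valid:
        left = cum[i]
        right = total - left
        nl, nr = i + 1, n - i - 1
        gain = h_parent - (nl * _entropy_bits(left) + nr * _entropy_bits(right)) / n
        split_info = _entropy_bits(np.array([nl, nr]))
        gr = gain / split_info if split_info > 0 else 0.0
        thr = (xs[i] + xs[i + 1]) / 2.0
        if best is None or gr > best[0]:
            best = (gr, thr)
    return best


def train_dt(X, y, epsilon: float = 1e-7) -> DtModel:
    """Grow a gain-ratio tree on continuous features.

    Recursion stops at pure nodes, nodes with no valid split (all feature
    values identical), or when the best gain ratio drops below ``epsilon``
    (majority leaf).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty training set")
    classes = tuple(np.unique(y))
    code = {c: k for k, c in enumerate(classes)}
    y_codes = np.array([code[v] for v in y])

    def majority(codes: np.ndarray):
        counts = np.bincount(codes, minlength=len(classes))
        return classes[int(np.argmax(counts))]

    def grow(rows: np.ndarray) -> DtNode:
        codes = y_codes[rows]
        if np.all(codes == codes[0]):
            return DtNode(label=classes[codes[0]])
        best = None
        for f in range(X.shape[1]):
            cand = _best_threshold(X[rows, f], codes, len(classes))
            if cand is not None and (best is None or cand[0] > best[1]):
                best = (f, cand[0], cand[1])
        if best is None or best[1] < epsilon:
            return DtNode(label=majority(codes))
        f, _, thr = best
        mask = X[rows, f] <= thr
        return DtNode(
            feature=f,
            threshold=thr,
            left=grow(rows[mask]),
            right=grow(rows[~mask]),
        )

    return DtModel(root=grow(np.arange(len(y))), classes=classes, epsilon=epsilon)


def gain_ratio(x, y) -> tuple[float, float]:
    """Best (gain ratio, threshold) for one continuous feature — the split
    score the tree uses, exposed for inspection."""
    y = np.asarray(y)
    classes = tuple(np.unique(y))
    code = {c: k for k, c in enumerate(classes)}
    best = _best_threshold(
        np.asarray(x, float), np.array([code[v] for v in y]), len(classes)
    )
    if best is None:
        return 0.0, math.nan
    return best


# ---------------------------------------------------------------------------
# extreme learning machine


@dataclass
class ElmModel:
    weights: np.ndarray  # (M, d) input-to-hidden
    biases: np.ndarray   # (M,)
    beta: np.ndarray     # (M, k) hidden-to-output
    classes: tuple
    activation: str
    seed: int

    def hidden(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        if self.activation == "sigmoid":
            z = X @ self.weights.T + self.biases
            return 1.0 / (1.0 + np.exp(-z))
        if self.activation == "rbf":
            d2 = ((X[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2)
            return np.exp(-np.abs(self.biases) * d2)
        raise ValueError(f"unknown activation {self.activation!r}")

    def decision(self, X) -> np.ndarray:
        return self.hidden(X) @ self.beta

    def predict(self, X):
        scores = self.decision(X)
        return np.array([self.classes[i] for i in np.argmax(scores, axis=1)])


def train_elm(X, y, M: int, seed: int = 0, activation: str = "sigmoid") -> ElmModel:
    """Fit an ELM: random uniform(-1, 1) hidden layer, closed-form output.

    The hidden activations H of the N training samples are assembled and the
    output weights solve the least-squares system H beta = Y (one-hot Y)
    through the Moore-Penrose pseudo-inverse, the minimum-norm minimizer of
    ||H beta - Y||.
    """
    if M < 1:
        raise ValueError(f"hidden size M must be >= 1, got {M}")
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = tuple(np.unique(y))
    rng = np.random.default_rng(seed)
    weights = rng.uniform(-1.0, 1.0, size=(M, X.shape[1]))
    biases = rng.uniform(-1.0, 1.0, size=M)
    model = ElmModel(
        weights=weights,
        biases=biases,
        beta=np.zeros((M, len(classes))),
        classes=classes,
        activation=activation,
        seed=seed,
    )
    H = model.hidden(X)
    Y = np.zeros((len(y), len(classes)))
    code = {c: k for k, c in enumerate(classes)}
    Y[np.arange(len(y)), [code[v] for v in y]] = 1.0
    model.beta = np.linalg.pinv(H) @ Y
    return model


def predict_elm(model: ElmModel, x):
    """Class prediction for a single feature vector."""
    return model.predict(np.asarray(x, float).reshape(1, -1))[0]
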