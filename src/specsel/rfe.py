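"""Linear maximum-margin classification with recursive feature elimination.

SVM-RFE trains a linear soft-margin classifier, scores each feature by its
squared weight summed over the one-vs-one binary problems,
c_i = sum_pairs w_i^2, eliminates the lowest-scoring feature(s), and
repeats on the survivors.  The final ranking is the reverse elimination
order: the last survivor is the most discriminative feature in the
multivariate sense, capturing features whose value shows only jointly
with others.

Features are standardized with training-fold statistics before each fit;
squared weights are only comparable on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .ranking import RankedFeatureList

__all__ = ["LinearMaxMargin", "RFERanking", "train_linear_maxmargin", "rfe_rank"]


@dataclass
class LinearMaxMargin:
    """One-vs-one linear soft-margin classifiers with manual voting."""

    classes: tuple[str, ...]
    pairs: tuple[tuple[int, int], ...]
    weights: np.ndarray        # (n_pairs, p)
    intercepts: np.ndarray     # (n_pairs,)
    mean: np.ndarray           # training standardization
    scale: np.ndarray

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.atleast_2d(X) - self.mean) / self.scale
        return Xs @ self.weights.T + self.intercepts

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Pairwise voting; ties broken by summed decision values."""
        dec = self.decision_values(X)
        n, G = dec.shape[0], len(self.classes)
        votes = np.zeros((n, G))
        margin = np.zeros((n, G))
        for k, (a, b) in enumerate(self.pairs):
            win_a = dec[:, k] > 0
            votes[win_a, a] += 1
            votes[~win_a, b] += 1
            margin[:, a] += dec[:, k]
            margin[:, b] -= dec[:, k]
        # among vote leaders, prefer the largest summed decision value
        leaders = votes == votes.max(axis=1, keepdims=True)
        best = np.argmax(np.where(leaders, margin, -np.inf), axis=1)
        return np.array([self.classes[i] for i in best])

    def squared_weight_criterion(self) -> np.ndarray:
        """c_i = sum over binary problems of w_i^2 (on standardized scale)."""
        return (self.weights ** 2).sum(axis=0)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return mean, scale


def train_linear_maxmargin(X: np.ndarray, labels: np.ndarray,
                           C: float = 1.0) -> LinearMaxMargin:
    """Train one-vs-one linear soft-margin classifiers.

    Samples are standardized with the training statistics of ``X``.  The
    per-pair weight vectors and intercepts are recovered from the dual
    solution, so the squared-weight elimination criterion is exact.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if C <= 0:
        raise ValueError("C must be > 0")
    classes = tuple(dict.fromkeys(labels))
    if len(classes) < 2:
        raise ValueError("need >=2 classes in the training data")
    mean, scale = _standardize(X)
    Xs = (X - mean) / scale
    pairs, weights, intercepts = [], [], []
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            mask = (labels == classes[a]) | (labels == classes[b])
            yb = np.where(labels[mask] == classes[a], 1.0, -1.0)
            clf = SVC(kernel="linear", C=C)
            clf.fit(Xs[mask], yb)
            sign = 1.0 if clf.classes_[1] == 1.0 else -1.0
            pairs.append((a, b))
            weights.append(sign * clf.coef_[0])
            intercepts.append(sign * clf.intercept_[0])
    return LinearMaxMargin(
        classes=classes, pairs=tuple(pairs),
        weights=np.array(weights), intercepts=np.array(intercepts),
        mean=mean, scale=scale,
    )


@dataclass(frozen=True)
class RFERanking:
    """Elimination record: first eliminated ... last survivor."""

    elimination_order: tuple[str, ...]
    criterion_trace: tuple[float, ...]   # c_i of each feature when removed
    elimination_round: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.elimination_order)) != len(self.elimination_order):
            raise ValueError("elimination order must be a permutation")

    @property
    def ranking(self) -> tuple[str, ...]:
        """Best-first feature ranking (reverse elimination order)."""
        return tuple(reversed(self.elimination_order))

    def to_ranked_list(self, n_selected: int = 0) -> RankedFeatureList:
        order = self.ranking
        trace = dict(zip(self.elimination_order, self.criterion_trace))
        return RankedFeatureList(
            method_name="svm_rfe",
            protein_ids=order,
            scores=tuple(trace[f] for f in order),
            n_selected=n_selected,
        )


def rfe_rank(X: np.ndarray, labels: np.ndarray, C: float = 1.0,
             step_fraction: float = 0.1, exact_below: int = 200,
             feature_ids: tuple[str, ...] | None = None) -> RFERanking:
    """Recursive feature elimination under the squared-weight criterion.

    Removes ``step_fraction`` of the surviving features per round while
    more than ``exact_below`` survive, then one feature per round, which
    bounds runtime on thousands of features yet keeps single-feature
    resolution where the optimal subset lives.  Ties in c_i eliminate the
    lexicographically larger feature id first, making the ranking
    deterministic and independent of input feature order.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need >=2 features to rank")
    if not (0 < step_fraction <= 0.5):
        raise ValueError("step_fraction must lie in (0, 0.5]")
    if feature_ids is None:
        feature_ids = tuple(f"f{i}" for i in range(p))
    surviving = list(range(p))
    eliminated: list[str] = []
    trace: list[float] = []
    rounds: list[int] = []
    rnd = 0
    while len(surviving) > 1:
        rnd += 1
        model = train_linear_maxmargin(X[:, surviving], labels, C=C)
        crit = model.squared_weight_criterion()
        n_sur = len(surviving)
        step = 1 if n_sur <= exact_below else max(int(n_sur * step_fraction), 1)
        step = min(step, n_sur - 1)
        # worst first: lowest criterion, ties -> larger id eliminated first
        order = sorted(range(n_sur),
                       key=lambda i: (crit[i], _RevStr(feature_ids[surviving[i]])))
        worst = order[:step]
        eliminated.extend(feature_ids[surviving[i]] for i in worst)
        trace.extend(float(crit[i]) for i in worst)
        rounds.extend([rnd] * step)
        for i in sorted(worst, reverse=True):
            del surviving[i]
    eliminated.append(feature_ids[surviving[0]])
    trace.append(np.inf)
    rounds.append(rnd + 1)
    return RFERanking(tuple(eliminated), tuple(trace), tuple(rounds))


class _RevStr(str):
    """String with reversed ordering (larger ids sort first)."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)
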