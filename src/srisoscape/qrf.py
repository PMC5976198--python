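"""Quantile regression forest for spatially explicit uncertainty.

Where a point random forest averages tree outputs, a quantile regression
forest keeps the full set of training responses in each leaf and reads
conditional quantiles off the weighted empirical response distribution
(Meinshausen weights: uniform within the query's leaf of each tree,
averaged over trees).  The 2.5th and 97.5th conditional percentiles give
a 95% prediction interval whose width is the published uncertainty
surface; empirical coverage on held-out sites audits its calibration.

Trees are grown on explicit bootstrap resamples so the in-bag bookkeeping
is owned here: each tree's leaf lists contain exactly its in-bag training
rows (out-of-bag rows are excluded, the standard estimator).  Quantile
inversion uses the left-continuous generalized inverse: the smallest
response value whose cumulative weight reaches the requested probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .samples import RegressionMatrix


@dataclass
class QuantileForest:
    """Fitted quantile regression forest."""

    trees: list
    inbag_indices: list[np.ndarray]      # per tree, bootstrap row indices
    y_sorted: np.ndarray                 # training responses, ascending
    order: np.ndarray                    # argsort of the original responses
    n_train: int
    seed: int

    # per tree, arrays mapping sorted-by-leaf structure for fast lookup
    _leaf_sorted: list[np.ndarray] = field(default_factory=list, repr=False)
    _row_sorted: list[np.ndarray] = field(default_factory=list, repr=False)

    def leaf_responses(self, t: int) -> dict[int, np.ndarray]:
        """Leaf id -> training response values (in-bag) for tree ``t``."""
        leaves = self._leaf_sorted[t]
        rows = self._row_sorted[t]
        out: dict[int, np.ndarray] = {}
        for leaf in np.unique(leaves):
            sel = rows[np.searchsorted(leaves, leaf, "left"):
                       np.searchsorted(leaves, leaf, "right")]
            out[int(leaf)] = self.y_all[sel]
        return out

    @property
    def y_all(self) -> np.ndarray:
        inv = np.empty_like(self.order)
        inv[self.order] = np.arange(len(self.order))
        return self.y_sorted[inv]


def fit_qrf(
    matrix: RegressionMatrix | None = None,
    n_estimators: int = 500,
    min_samples_leaf: int = 10,
    max_features: float | int | str = 0.333,
    seed: int = 0,
    X=None,
    y=None,
    bootstrap: bool = True,
) -> QuantileForest:
    """Grow a quantile regression forest.

    Accepts either a :class:`RegressionMatrix` or raw ``X``/``y`` arrays.
    Trees are grown as in the point forest except for the terminal node
    size: quantile trees keep ``min_samples_leaf=10`` responses per leaf
    (the quantregForest default nodesize) because fully-grown trees
    concentrate leaf distributions on too few responses and undercover.
    Each tree records which bootstrap rows it saw, so conditional
    distributions use in-bag rows only.
    """
    if matrix is not None:
        X, y = matrix.X, matrix.y
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < max(2, min_samples_leaf):
        raise ValueError("fewer training rows than the leaf-size floor")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    trees, inbag, leaf_sorted, row_sorted = [], [], [], []
    order = np.argsort(y, kind="stable")
    qf = QuantileForest([], [], y[order], order, n, seed)
    for t in range(n_estimators):
        idx = rng.integers(0, n, n) if bootstrap else np.arange(n)
        tree = DecisionTreeRegressor(
            min_samples_leaf=min_samples_leaf,
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        leaves = tree.apply(X[idx]).astype(np.int64)
        srt = np.argsort(leaves, kind="stable")
        trees.append(tree)
        inbag.append(idx)
        leaf_sorted.append(leaves[srt])
        row_sorted.append(idx[srt])
    qf.trees = trees
    qf.inbag_indices = inbag
    qf._leaf_sorted = leaf_sorted
    qf._row_sorted = row_sorted
    return qf


def _weights_for(qf: QuantileForest, Xq: np.ndarray) -> np.ndarray:
    """Meinshausen weight matrix (n_query, n_train), columns in y-sorted order."""
    nq = Xq.shape[0]
    n = qf.n_train
    rank = np.empty(n, dtype=np.int64)  # original row -> position in y_sorted
    rank[qf.order] = np.arange(n)
    W = np.zeros((nq, n))
    qrows = np.arange(nq)
    for t, tree in enumerate(qf.trees):
        q_leaves = tree.apply(Xq).astype(np.int64)
        leaves = qf._leaf_sorted[t]
        rows = qf._row_sorted[t]
        left = np.searchsorted(leaves, q_leaves, "left")
        right = np.searchsorted(leaves, q_leaves, "right")
        counts = right - left
        if np.any(counts == 0):  # cannot happen for in-bag-grown trees
            raise RuntimeError("query matched an empty leaf")
        total = int(counts.sum())
        flat = np.arange(total)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        within = flat - np.repeat(starts, counts)
        src = np.repeat(left, counts) + within
        cols = rank[rows[src]]
        rws = np.repeat(qrows, counts)
        # np.add.at, not fancy +=: bootstrap-duplicated rows hit the same
        # (query, column) cell and their contributions must accumulate
        np.add.at(W, (rws, cols), np.repeat(1.0 / counts, counts))
    W /= len(qf.trees)
    return W


def predict_quantiles(qf: QuantileForest, Xq, probs, tile: int = 2048) -> np.ndarray:
    """Conditional quantiles at each query point.

    Returns an array of shape (n_query, len(probs)); each row is
    non-decreasing in prob.  Inversion is the left-continuous generalized
    inverse of the weighted ECDF of training responses.
    """
    probs = np.asarray(probs, dtype=float)
    if np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("probs must lie strictly inside (0, 1)")
    if np.any(np.diff(probs) < 0):
        raise ValueError("probs must be sorted ascending")
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    out = np.empty((Xq.shape[0], probs.size))
    for start in range(0, Xq.shape[0], tile):
        chunk = Xq[start:start + tile]
        W = _weights_for(qf, chunk)
        cum = np.cumsum(W, axis=1)
        cum /= cum[:, -1:]
        for i in range(chunk.shape[0]):
            pos = np.searchsorted(cum[i], probs - 1e-12, side="left")
            out[start + i] = qf.y_sorted[np.minimum(pos, qf.n_train - 1)]
    return out


def predict_mean(qf: QuantileForest, Xq, tile: int = 2048) -> np.ndarray:
    """Point prediction: the weighted mean of training responses (equals the
    average of tree-mean predictions for these weights)."""
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    out = np.empty(Xq.shape[0])
    for start in range(0, Xq.shape[0], tile):
        W = _weights_for(qf, Xq[start:start + tile])
        out[start:start + W.shape[0]] = W @ qf.y_sorted
    return out


def coverage(
    qf: QuantileForest,
    X_heldout,
    y_heldout,
    level: float = 0.95,
) -> float:
    """Fraction of held-out observations inside the central ``level`` interval."""
    y_heldout = np.asarray(y_heldout, dtype=float)
    if y_heldout.size == 0:
        raise ValueError("empty held-out set")
    alpha = (1.0 - level) / 2.0
    q = predict_quantiles(qf, X_heldout, [alpha, 1.0 - alpha])
    inside = (y_heldout >= q[:, 0]) & (y_heldout <= q[:, 1])
    return float(inside.mean())
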