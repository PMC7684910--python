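"""Quantile regression forest: leaf-co-membership weights over a CART ensemble.

A regression forest is grown on bootstrap samples exactly as in the
standard random-forest algorithm, but prediction keeps the whole response
distribution of each leaf rather than its mean.  For a query point x,
every training observation i receives the weight

    w_i(x) = (1 / n_trees) * sum_t  m_ti * 1{i in leaf_t(x)} / M_t(leaf_t(x))

where ``m_ti`` is i's bootstrap multiplicity in tree t and ``M_t(l)`` the
total in-bag multiplicity of leaf l.  The conditional tau-quantile is the
left-continuous inverse of the weighted empirical CDF of the training
responses.  Out-of-bag (OOB) predictions for a training row average only
over trees whose bootstrap sample excluded that row, giving an internal
error estimate without a held-out set.

Individual trees are fitted with scikit-learn's CART implementation;
the bootstrap bookkeeping, weight derivation, ECDF inversion and
permutation importance are implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from . import schema
from .metrics import average_quantile_loss, _check_tau

__all__ = [
    "ForestParams",
    "FittedForest",
    "fit_forest",
    "leaf_weights",
    "conditional_quantile",
    "oob_quantile_predictions",
    "oob_mean_predictions",
    "permutation_importance",
]


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters.

    ``mtry`` is the number of candidate split features per node (defaults
    to ceil(d/3) of the encoded design, the regression-forest convention);
    ``min_node_size`` the minimum terminal-node size; bootstrap is with
    replacement at full sample size.
    """

    n_trees: int = 1000
    mtry: int | None = None
    min_node_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.min_node_size < 1:
            raise ValueError(f"min_node_size must be >= 1, got {self.min_node_size}")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError(f"mtry must be >= 1, got {self.mtry}")


@dataclass
class FittedForest:
    """Fitted ensemble plus the bookkeeping QRF weights need.

    ``inbag[t, i]`` is the bootstrap multiplicity of training row i in
    tree t (each row of ``inbag`` sums to n); ``leaf_train[t, i]`` the
    leaf id of row i under tree t.  Rows with ``inbag[t, i] == 0`` are
    out-of-bag for tree t.
    """

    params: ForestParams
    trees: list[DecisionTreeRegressor]
    inbag: np.ndarray
    leaf_train: np.ndarray
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    groups: dict[str, list[int]]
    covariates: list[str]
    _caches: list["_TreeCache"] = field(default_factory=list, repr=False)

    @property
    def n_samples(self) -> int:
        return self.y.size

    def encode(self, table: pd.DataFrame) -> np.ndarray:
        """Encode a covariate table with this forest's design (column order,
        reference levels)."""
        X, names, _ = schema.encode_design(table, self.covariates)
        if names != self.feature_names:
            raise ValueError(
                f"covariate columns {names} do not match the fitted design "
                f"{self.feature_names}"
            )
        return X

    def summary(self) -> dict:
        """Structured-text summary: per-tree leaf counts and sizes."""
        return {
            "n_trees": self.params.n_trees,
            "n_samples": int(self.n_samples),
            "n_features": len(self.feature_names),
            "mtry": self.params.mtry or _default_mtry(len(self.feature_names)),
            "min_node_size": self.params.min_node_size,
            "seed": self.params.seed,
            "leaves_per_tree": [int(t.get_n_leaves()) for t in self.trees],
        }


def _default_mtry(d: int) -> int:
    return max(1, math.ceil(d / 3))


def fit_forest(
    table: pd.DataFrame,
    params: ForestParams | None = None,
    covariates: list[str] | None = None,
    response: str = schema.RESPONSE,
) -> FittedForest:
    """Grow a regression forest by binary recursive splitting on bootstrap samples.

    Categorical covariates are one-hot encoded against their reference
    levels (a documented, deterministic scheme shared with the linear
    quantile-regression design).  Reproducible given ``params.seed``.
    """
    if params is None:
        params = ForestParams()
    if len(table) == 0:
        raise ValueError("empty table")
    if covariates is None:
        covariates = [c for c in schema.COVARIATES if c in table.columns]
        covariates += [
            c for c in table.columns if c not in covariates and c != response
        ]
    if not covariates:
        raise ValueError("no covariates to fit on")
    X, names, groups = schema.encode_design(table, covariates)
    y = pd.to_numeric(table[response]).to_numpy(dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    mtry = params.mtry or _default_mtry(d)
    mtry = min(mtry, d)

    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    trees: list[DecisionTreeRegressor] = []
    inbag = np.empty((params.n_trees, n), dtype=np.int32)
    leaf_train = np.empty((params.n_trees, n), dtype=np.int64)
    for t in range(params.n_trees):
        idx = rng.integers(0, n, size=n)
        inbag[t] = np.bincount(idx, minlength=n)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=params.min_node_size,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        leaf_train[t] = tree.apply(X)

    forest = FittedForest(
        params=params,
        trees=trees,
        inbag=inbag,
        leaf_train=leaf_train,
        X=X,
        y=y,
        feature_names=names,
        groups=groups,
        covariates=list(covariates),
    )
    forest._caches = [
        _TreeCache.build(leaf_train[t], inbag[t], y) for t in range(params.n_trees)
    ]
    return forest


@dataclass
class _TreeCache:
    """Per-tree leaf membership in flat-array form for fast weight lookups.

    ``members_flat``/``w_flat`` list the in-bag rows of every leaf
    consecutively (weights are bootstrap multiplicities normalized to sum
    1 within the leaf); ``starts``/``counts`` index that flat layout per
    sorted unique leaf id.
    """

    leaves: np.ndarray
    starts: np.ndarray
    counts: np.ndarray
    members_flat: np.ndarray
    w_flat: np.ndarray
    leaf_mean: np.ndarray

    @classmethod
    def build(cls, leaf_ids: np.ndarray, mult: np.ndarray, y: np.ndarray) -> "_TreeCache":
        leaves, inv = np.unique(leaf_ids, return_inverse=True)
        tot = np.bincount(inv, weights=mult)
        keep = mult > 0
        order = np.argsort(inv[keep], kind="stable")
        members_flat = np.flatnonzero(keep)[order]
        w_flat = (mult[members_flat] / tot[inv[members_flat]]).astype(float)
        counts = np.bincount(inv[keep], minlength=leaves.size)
        starts = np.r_[0, np.cumsum(counts[:-1])]
        leaf_mean = np.bincount(inv, weights=mult * y) / np.maximum(tot, 1e-300)
        return cls(leaves, starts, counts, members_flat, w_flat, leaf_mean)

    def scatter_indices(self, leaf_eval: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """For evaluation rows with leaf ids ``leaf_eval``: flat arrays
        (row_repeat, member_index, weight) of all weight contributions."""
        pos = np.searchsorted(self.leaves, leaf_eval)
        cnt = self.counts[pos]
        total = int(cnt.sum())
        offs = np.repeat(np.cumsum(cnt) - cnt, cnt)
        within = np.arange(total) - offs
        flat = np.repeat(self.starts[pos], cnt) + within
        rows_rep = np.repeat(np.arange(leaf_eval.size), cnt)
        return rows_rep, self.members_flat[flat], self.w_flat[flat]


def _apply_tree(tree: DecisionTreeRegressor, X32: np.ndarray) -> np.ndarray:
    # bypass sklearn's per-call validation; X32 must be C-contiguous float32
    return tree.tree_.apply(X32)


def _as32(X: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(X, dtype=np.float32)


def _weights_matrix(forest: FittedForest, Xq: np.ndarray) -> np.ndarray:
    """(m, n) QRF weight matrix for query design rows ``Xq``."""
    n = forest.n_samples
    m = Xq.shape[0]
    W = np.zeros((m, n))
    Xq32 = _as32(Xq)
    for t, tree in enumerate(forest.trees):
        leaf_q = _apply_tree(tree, Xq32)
        rows_rep, members, w = forest._caches[t].scatter_indices(leaf_q)
        np.add.at(W, (rows_rep, members), w)
    W /= len(forest.trees)
    return W


def leaf_weights(forest: FittedForest, x: pd.DataFrame | pd.Series | dict) -> np.ndarray:
    """Per-training-observation weight vector w_i(x) for a single query point.

    Nonnegative, sums to 1 (each tree distributes total weight 1 over the
    in-bag members of the leaf containing x).
    """
    Xq = _encode_query(forest, x)
    if Xq.shape[0] != 1:
        raise ValueError("leaf_weights expects a single query point")
    return _weights_matrix(forest, Xq)[0]


def _encode_query(forest: FittedForest, x) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        df = x
    elif isinstance(x, (pd.Series, dict)):
        df = pd.DataFrame([dict(x)])
    else:
        arr = np.atleast_2d(np.asarray(x, dtype=float))
        if arr.shape[1] != forest.X.shape[1]:
            raise ValueError(
                f"encoded query has {arr.shape[1]} columns, design has {forest.X.shape[1]}"
            )
        return arr
    missing = [c for c in forest.covariates if c not in df.columns]
    if missing:
        raise ValueError(f"query is missing covariates {missing}")
    return forest.encode(df)


def _invert_weighted_ecdf(
    W: np.ndarray, y: np.ndarray, taus: np.ndarray, tol: float = 1e-10
) -> np.ndarray:
    """Left-continuous inverse of weighted ECDFs: smallest training response
    whose cumulative weight reaches tau.  Returns shape (m, len(taus))."""
    order = np.argsort(y, kind="stable")
    ys = y[order]
    cum = np.cumsum(W[:, order], axis=1)
    out = np.empty((W.shape[0], taus.size))
    for j, tau in enumerate(taus):
        idx = np.argmax(cum >= tau - tol, axis=1)
        out[:, j] = ys[idx]
    return out


def conditional_quantile(forest: FittedForest, x, tau) -> float | np.ndarray:
    """Conditional tau-quantile(s) at query point(s) x.

    ``x`` may be a covariate mapping / one-row frame (single point) or a
    multi-row frame; ``tau`` a scalar or sequence.  Scalar in, scalar out.
    """
    taus = np.atleast_1d(np.asarray(tau, dtype=float))
    for t in taus:
        _check_tau(float(t))
    Xq = _encode_query(forest, x)
    W = _weights_matrix(forest, Xq)
    out = _invert_weighted_ecdf(W, forest.y, taus)
    if np.isscalar(tau) and Xq.shape[0] == 1:
        return float(out[0, 0])
    if np.isscalar(tau):
        return out[:, 0]
    if Xq.shape[0] == 1:
        return out[0]
    return out


def _oob_weight_matrix(
    forest: FittedForest, X_eval: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(n, n) OOB weight matrix and per-row OOB tree counts.

    Row i averages the leaf-co-membership weights over the trees where i
    is out-of-bag; i's own contribution is automatically zero there (its
    multiplicity is zero).  ``X_eval`` substitutes the design rows at
    evaluation time (used by permutation importance); leaf membership of
    the *training* observations is unchanged.
    """
    n = forest.n_samples
    W = np.zeros((n, n))
    cnt = np.zeros(n, dtype=np.int64)
    X32 = None if X_eval is None else _as32(X_eval)
    for t, tree in enumerate(forest.trees):
        mult = forest.inbag[t]
        oob = np.flatnonzero(mult == 0)
        if oob.size == 0:
            continue
        cnt[oob] += 1
        if X32 is None:
            leaf_eval = forest.leaf_train[t][oob]
        else:
            leaf_eval = _apply_tree(tree, X32[oob])
        rows_rep, members, w = forest._caches[t].scatter_indices(leaf_eval)
        np.add.at(W, (oob[rows_rep], members), w)
    ok = cnt > 0
    W[ok] /= cnt[ok, None]
    return W, cnt


def oob_quantile_predictions(
    forest: FittedForest, tau: float, X_eval: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """OOB conditional tau-quantile per training row.

    Returns ``(pred, mask)``; ``mask[i]`` is False (and ``pred[i]`` NaN,
    with a warning) for rows that were in-bag in every tree — vanishingly
    rare once n_trees is large, since P(in-bag everywhere) ~ (1 - e^-1)^T.
    """
    _check_tau(tau)
    W, cnt = _oob_weight_matrix(forest, X_eval)
    mask = cnt > 0
    pred = np.full(forest.n_samples, np.nan)
    if mask.any():
        pred[mask] = _invert_weighted_ecdf(W[mask], forest.y, np.array([tau]))[:, 0]
    if (~mask).any():
        warnings.warn(
            f"{int((~mask).sum())} rows were in-bag in every tree and are "
            "masked from OOB predictions",
            stacklevel=2,
        )
    return pred, mask


def oob_mean_predictions(
    forest: FittedForest, X_eval: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """OOB mean prediction per training row (classic random-forest OOB).

    Equals the QRF-weighted mean sum_i w_i(x) y_i but computed from
    per-leaf bootstrap-weighted means, which is much cheaper.
    """
    n = forest.n_samples
    pred_sum = np.zeros(n)
    cnt = np.zeros(n, dtype=np.int64)
    X32 = None if X_eval is None else _as32(X_eval)
    for t, tree in enumerate(forest.trees):
        mult = forest.inbag[t]
        oob = np.flatnonzero(mult == 0)
        if oob.size == 0:
            continue
        cache = forest._caches[t]
        if X32 is None:
            leaf_eval = forest.leaf_train[t][oob]
        else:
            leaf_eval = _apply_tree(tree, X32[oob])
        pos = np.searchsorted(cache.leaves, leaf_eval)
        pred_sum[oob] += cache.leaf_mean[pos]
        cnt[oob] += 1
    mask = cnt > 0
    pred = np.full(n, np.nan)
    pred[mask] = pred_sum[mask] / cnt[mask]
    return pred, mask


def permutation_importance(
    forest: FittedForest,
    mode: str = "mse",
    tau: float | None = None,
    seed: int = 0,
    n_repeats: int = 1,
) -> pd.Series:
    """Covariate-level permutation importance from OOB error increase.

    For each covariate, all of its design columns are jointly shuffled by
    one shared row permutation (so categorical levels stay coherent) and
    the OOB error is recomputed; importance is permuted error minus
    baseline error, averaged over ``n_repeats`` independent permutations.
    ``mode="mse"`` scores mean squared error of the OOB mean prediction;
    ``mode="pinball"`` scores OOB average quantile loss at ``tau``.
    """
    if mode not in ("mse", "pinball"):
        raise ValueError(f"mode must be 'mse' or 'pinball', got {mode!r}")
    if mode == "pinball":
        if tau is None:
            raise ValueError("pinball mode requires tau")
        _check_tau(tau)
    if n_repeats < 1:
        raise ValueError(f"n_repeats must be >= 1, got {n_repeats}")

    def _error(X_eval: np.ndarray | None) -> float:
        if mode == "mse":
            pred, mask = oob_mean_predictions(forest, X_eval)
            return float(np.mean((forest.y[mask] - pred[mask]) ** 2))
        pred, mask = oob_quantile_predictions(forest, tau, X_eval)
        return average_quantile_loss(forest.y[mask], pred[mask], tau)

    baseline = _error(None)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scores = dict.fromkeys(forest.covariates, 0.0)
    n = forest.n_samples
    for _ in range(n_repeats):
        for cov in forest.covariates:
            perm = rng.permutation(n)
            cols = forest.groups[cov]
            Xp = forest.X.copy()
            Xp[:, cols] = forest.X[np.ix_(perm, cols)]
            scores[cov] += (_error(Xp) - baseline) / n_repeats
    return pd.Series(scores, name=f"importance_{mode}")
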