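import numpy as np
import pandas as pd
import pytest

from qrfcost.forest import (
    ForestParams,
    _TreeCache,
    _invert_weighted_ecdf,
    conditional_quantile,
    fit_forest,
    leaf_weights,
    oob_mean_predictions,
    oob_quantile_predictions,
    permutation_importance,
)
from qrfcost.metrics import sample_quantile_inf
from qrfcost.synthetic import default_config, generate_episodes


# --- brute-force oracles ---------------------------------------------------

def brute_weights(forest, x_encoded):
    """Exhaustive enumeration of leaf-co-membership weights over trees."""
    n = forest.n_samples
    w = np.zeros(n)
    for t, tree in enumerate(forest.trees):
        leaf_x = int(tree.apply(np.atleast_2d(x_encoded))[0])
        members = [
            i
            for i in range(n)
            if forest.leaf_train[t][i] == leaf_x and forest.inbag[t][i] > 0
        ]
        tot = sum(int(forest.inbag[t][i]) for i in members)
        for i in members:
            w[i] += forest.inbag[t][i] / tot
    return w / len(forest.trees)


def brute_quantile(w, y, tau):
    """Direct inversion of the explicitly accumulated weighted ECDF."""
    acc = 0.0
    for yi, wi in sorted(zip(y, w)):
        acc += wi
        if acc >= tau - 1e-12:
            return yi
    return max(y)


def brute_oob_quantile(forest, i, tau):
    n = forest.n_samples
    w = np.zeros(n)
    cnt = 0
    for t in range(len(forest.trees)):
        if forest.inbag[t][i] != 0:
            continue
        cnt += 1
        leaf = forest.leaf_train[t][i]
        members = [
            j
            for j in range(n)
            if forest.leaf_train[t][j] == leaf and forest.inbag[t][j] > 0
        ]
        tot = sum(int(forest.inbag[t][j]) for j in members)
        for j in members:
            w[j] += forest.inbag[t][j] / tot
    if cnt == 0:
        return None
    return brute_quantile(w / cnt, forest.y, tau)


# --- fitting ---------------------------------------------------------------

def test_min_node_size_bound_forces_root_leaves():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"x1": rng.normal(size=10), "cost": rng.normal(size=10)})
    forest = fit_forest(df, ForestParams(n_trees=5, min_node_size=10, seed=1))
    assert all(t.get_n_leaves() == 1 for t in forest.trees)


def test_fit_is_deterministic_given_seed(small_table):
    p = ForestParams(n_trees=10, seed=4)
    f1 = fit_forest(small_table, p)
    f2 = fit_forest(small_table, p)
    np.testing.assert_array_equal(f1.inbag, f2.inbag)
    np.testing.assert_array_equal(f1.leaf_train, f2.leaf_train)


def test_inbag_rows_sum_to_n(small_table):
    forest = fit_forest(small_table, ForestParams(n_trees=8, seed=2))
    np.testing.assert_array_equal(forest.inbag.sum(axis=1), len(small_table))


def test_perfectly_separable_response_recovered(toy_split_table):
    forest = fit_forest(
        toy_split_table, ForestParams(n_trees=30, min_node_size=1, seed=3)
    )
    for xv, yv in [(0.0, 5.0), (1.0, 15.0)]:
        q = conditional_quantile(forest, np.array([[xv]]), 0.5)
        assert q == pytest.approx(yv)


def test_empty_table_rejected():
    with pytest.raises(ValueError, match="empty"):
        fit_forest(pd.DataFrame({"x1": [], "cost": []}), ForestParams(n_trees=2))


def test_constant_response_gives_single_leaf_trees():
    df = pd.DataFrame({"x1": np.arange(30.0), "cost": np.full(30, 7.0)})
    forest = fit_forest(df, ForestParams(n_trees=4, min_node_size=1, seed=0))
    assert all(t.get_n_leaves() == 1 for t in forest.trees)
    assert conditional_quantile(forest, np.array([[3.0]]), 0.9) == 7.0


# --- weights ---------------------------------------------------------------

def test_root_leaf_weights_proportional_to_multiplicity():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"x1": rng.normal(size=12), "cost": rng.normal(size=12)})
    forest = fit_forest(df, ForestParams(n_trees=1, min_node_size=12, seed=5))
    w = leaf_weights(forest, np.array([0.0]))
    np.testing.assert_allclose(w, forest.inbag[0] / 12.0, atol=1e-12)


def test_uniform_weights_when_all_multiplicities_one():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"x1": rng.normal(size=12), "cost": rng.normal(size=12)})
    forest = fit_forest(df, ForestParams(n_trees=1, min_node_size=12, seed=5))
    forest.inbag = np.ones_like(forest.inbag)
    forest._caches = [_TreeCache.build(forest.leaf_train[0], forest.inbag[0], forest.y)]
    w = leaf_weights(forest, np.array([0.0]))
    np.testing.assert_allclose(w, np.full(12, 1 / 12), atol=1e-12)


def test_weights_sum_to_one_and_match_brute_force(small_table):
    forest = fit_forest(
        small_table.head(50), ForestParams(n_trees=3, min_node_size=5, seed=6)
    )
    rng = np.random.default_rng(2)
    for _ in range(5):
        x = forest.X[rng.integers(0, 50)] + rng.normal(scale=0.1, size=forest.X.shape[1])
        w = leaf_weights(forest, x)
        assert w.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(w >= 0)
        np.testing.assert_allclose(w, brute_weights(forest, x), atol=1e-12)


def test_missing_covariate_rejected(small_table):
    forest = fit_forest(small_table.head(40), ForestParams(n_trees=2, seed=0))
    with pytest.raises(ValueError, match="missing covariates"):
        leaf_weights(forest, {"age": 70.0})


# --- quantile inversion ----------------------------------------------------

def test_inversion_at_atoms_uses_infimum():
    W = np.array([[0.5, 0.5]])
    y = np.array([1.0, 3.0])
    assert _invert_weighted_ecdf(W, y, np.array([0.5]))[0, 0] == 1.0
    assert _invert_weighted_ecdf(W, y, np.array([0.51]))[0, 0] == 3.0


def test_upper_tail_returns_max_response(small_table):
    # root-leaf trees give every training point positive weight
    forest = fit_forest(small_table.head(30), ForestParams(n_trees=5, min_node_size=30, seed=1))
    q = conditional_quantile(forest, forest.X[:1], 0.999)
    assert q == forest.y.max()


def test_conditional_quantile_matches_brute_force_ecdf(small_table):
    forest = fit_forest(
        small_table.head(50), ForestParams(n_trees=3, min_node_size=5, seed=9)
    )
    rng = np.random.default_rng(8)
    taus = np.arange(0.1, 0.91, 0.1)
    for _ in range(5):
        x = forest.X[rng.integers(0, 50)]
        w = brute_weights(forest, x)
        for tau in taus:
            expected = brute_quantile(w, forest.y, tau)
            assert conditional_quantile(forest, np.atleast_2d(x), float(tau)) == expected


def test_conditional_quantile_nondecreasing_in_tau(small_table):
    forest = fit_forest(small_table, ForestParams(n_trees=20, seed=3))
    taus = np.linspace(0.05, 0.95, 19)
    rng = np.random.default_rng(4)
    for _ in range(10):
        x = forest.X[rng.integers(0, forest.n_samples)]
        q = conditional_quantile(forest, np.atleast_2d(x), taus)
        assert np.all(np.diff(q) >= 0)


def test_bad_tau_rejected(small_table):
    forest = fit_forest(small_table.head(20), ForestParams(n_trees=2, seed=0))
    with pytest.raises(ValueError, match="tau"):
        conditional_quantile(forest, forest.X[:1], 1.2)


# --- out-of-bag ------------------------------------------------------------

def test_oob_matches_brute_force(toy_split_table):
    forest = fit_forest(
        toy_split_table, ForestParams(n_trees=6, min_node_size=10, seed=11)
    )
    pred, mask = oob_quantile_predictions(forest, 0.7)
    for i in range(len(toy_split_table)):
        expected = brute_oob_quantile(forest, i, 0.7)
        if expected is None:
            assert not mask[i]
        else:
            assert pred[i] == expected


def test_oob_deterministic_and_unmasked_with_many_trees(small_table):
    p = ForestParams(n_trees=100, seed=12)
    f1 = fit_forest(small_table, p)
    f2 = fit_forest(small_table, p)
    q1, m1 = oob_quantile_predictions(f1, 0.9)
    q2, m2 = oob_quantile_predictions(f2, 0.9)
    np.testing.assert_array_equal(q1, q2)
    assert m1.all()  # P(in-bag everywhere) ~ (1 - 1/e)^100


def test_oob_root_leaf_forest_approximates_unconditional_quantile():
    rng = np.random.default_rng(13)
    df = pd.DataFrame({"x1": rng.normal(size=20), "cost": rng.normal(size=20)})
    forest = fit_forest(df, ForestParams(n_trees=400, min_node_size=20, seed=14))
    pred, mask = oob_quantile_predictions(forest, 0.5)
    y = df["cost"].to_numpy()
    for i in np.flatnonzero(mask)[:5]:
        others = np.delete(y, i)
        assert abs(pred[i] - sample_quantile_inf(others, 0.5)) <= np.ptp(y) * 0.2


def test_oob_masks_rows_inbag_everywhere():
    rng = np.random.default_rng(15)
    df = pd.DataFrame({"x1": rng.normal(size=15), "cost": rng.normal(size=15)})
    forest = fit_forest(df, ForestParams(n_trees=1, min_node_size=15, seed=16))
    with pytest.warns(UserWarning, match="masked"):
        pred, mask = oob_quantile_predictions(forest, 0.5)
    np.testing.assert_array_equal(mask, forest.inbag[0] == 0)
    assert np.isnan(pred[~mask]).all()


# --- permutation importance ------------------------------------------------

def test_importance_of_independent_covariate_is_negligible():
    """A covariate independent of the response earns essentially zero
    importance; averaged over 20 permutation seeds it is within 2% of the
    signal covariate's score (the residual reflects the forest's own mild
    overfit to the noise column, not predictive value)."""
    rng = np.random.default_rng(17)
    n = 600
    df = pd.DataFrame(
        {
            "signal": rng.normal(size=n),
            "junk": rng.normal(size=n),
        }
    )
    df["cost"] = 3.0 * df["signal"] + rng.normal(size=n)
    # mtry = d so splits prefer the signal; junk splits are pure noise
    forest = fit_forest(df, ForestParams(n_trees=60, mtry=2, min_node_size=25, seed=18))
    scores = pd.concat(
        [permutation_importance(forest, "mse", seed=s) for s in range(20)], axis=1
    ).mean(axis=1)
    assert abs(scores["junk"]) <= 0.02 * scores["signal"]


def test_duplicated_signal_shares_importance():
    rng = np.random.default_rng(19)
    x = rng.integers(0, 2, size=300).astype(float)
    df = pd.DataFrame(
        {"a": x, "b": x, "cost": 10.0 * x + rng.normal(size=300)}
    )
    forest = fit_forest(df, ForestParams(n_trees=80, min_node_size=5, seed=20))
    imp = permutation_importance(forest, "mse", seed=21, n_repeats=5)
    assert imp["a"] > 0
    assert imp["b"] > 0


def test_chemo_drug_dominates_pinball_importance():
    """The dominant cost driver earns the top upper-tail importance score."""
    wins = 0
    for seed in range(5):
        df = generate_episodes(default_config(n_episodes=600, seed=seed))
        forest = fit_forest(df, ForestParams(n_trees=100, seed=seed))
        imp = permutation_importance(forest, "pinball", tau=0.9, seed=seed)
        wins += imp.idxmax() == "chemo_drug"
    assert wins >= 4


def test_importance_mode_validation(small_table):
    forest = fit_forest(small_table.head(30), ForestParams(n_trees=2, seed=0))
    with pytest.raises(ValueError, match="mode"):
        permutation_importance(forest, "gini")
    with pytest.raises(ValueError, match="tau"):
        permutation_importance(forest, "pinball")


def test_oob_mean_equals_weighted_mean(small_table):
    forest = fit_forest(small_table.head(60), ForestParams(n_trees=25, seed=22))
    from qrfcost.forest import _oob_weight_matrix

    W, cnt = _oob_weight_matrix(forest)
    pred, mask = oob_mean_predictions(forest)
    np.testing.assert_allclose(pred[mask], (W @ forest.y)[mask], rtol=1e-10)
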