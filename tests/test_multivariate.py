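import numpy as np
import pandas as pd
import pytest

from morphonet import hca, hkmeans, pca, scale_table
from morphonet.multivariate import heatmap_order


def blobs_table(seed=0, n_per=4, sep=30.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per, 5))
    b = rng.normal(0, 1, size=(n_per, 5)) + sep
    x = np.vstack([a, b])
    return pd.DataFrame(x, index=[f"r{i}" for i in range(2 * n_per)],
                        columns=[f"m{j}" for j in range(5)])


def test_scale_table_zscores_and_idempotence():
    t = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 0.0, 1.0]}, index=list("xyz"))
    s = scale_table(t)
    np.testing.assert_allclose(s["a"], [-1.0, 0.0, 1.0])
    np.testing.assert_allclose(scale_table(s).to_numpy(), s.to_numpy(), atol=1e-12)


def test_scale_table_drops_constant_columns():
    t = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [7.0, 7.0, 7.0]})
    with pytest.warns(UserWarning, match="constant"):
        s = scale_table(t)
    assert list(s.columns) == ["a"]
    with pytest.raises(ValueError):
        scale_table(pd.DataFrame({"c": [1.0, 1.0]}))


def test_pca_perfectly_correlated_columns():
    t = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
    res = pca(t, scale=True)
    assert res.variance_explained[0] == pytest.approx(100.0)


def test_pca_matches_direct_svd_oracle():
    rng = np.random.default_rng(3)
    t = pd.DataFrame(rng.normal(size=(10, 6)),
                     index=[f"r{i}" for i in range(10)],
                     columns=[f"m{j}" for j in range(6)])
    res = pca(t, scale=False)
    # independent oracle: eigendecomposition of the covariance matrix
    x = t.to_numpy() - t.to_numpy().mean(axis=0)
    ev = np.linalg.eigvalsh(x.T @ x)[::-1]
    np.testing.assert_allclose(res.variance_explained, 100 * ev / ev.sum(), atol=1e-8)
    # reconstruction: scores @ loadings^T recovers the centered table
    np.testing.assert_allclose(res.scores.to_numpy() @ res.loadings.to_numpy().T,
                               x, atol=1e-8)


def test_pca_variance_fractions_non_increasing_and_bounded():
    t = blobs_table(seed=1)
    res = pca(t)
    v = res.variance_explained
    assert np.all(np.diff(v) <= 1e-9)
    assert v.sum() == pytest.approx(100.0)


def test_hca_identical_rows_merge_at_zero():
    t = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [8.0, 9.0]],
                     index=list("abc"), columns=["x", "y"])
    res = hca(t, k=2, scale=False)
    assert res.heights[0] == pytest.approx(0.0)
    assert res.assignments["a"] == res.assignments["b"] != res.assignments["c"]


def test_hca_two_far_pairs_matches_hand_ward():
    """Ward.D2 on two tight pairs: within-pair merges first, root height by
    the Lance-Williams recursion sqrt(2*2*2/4)*||centroid gap||."""
    t = pd.DataFrame([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]],
                     index=list("abcd"), columns=["x", "y"])
    res = hca(t, k=2, scale=False)
    np.testing.assert_allclose(sorted(res.heights[:2]), [1.0, 1.0])
    assert res.heights[2] == pytest.approx(np.sqrt(2.0) * 10.0, rel=1e-6)
    assert res.cophenetic_correlation > 0.99
    assert np.all(np.diff(res.heights) >= -1e-9)  # monotone merges


def test_hca_cophenetic_matrix_is_ultrametric():
    t = blobs_table(seed=5)
    res = hca(t, k=2)
    c = res.cophenetic_matrix().to_numpy()
    n = c.shape[0]
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert c[i, j] <= max(c[i, k], c[k, j]) + 1e-9


def test_hca_k_out_of_range():
    t = blobs_table()
    with pytest.raises(ValueError, match="out of range"):
        hca(t, k=99)


def test_hca_row_permutation_equivariance():
    t = blobs_table(seed=7)
    perm = np.random.default_rng(0).permutation(len(t))
    tp = t.iloc[perm]
    a1 = hca(t, k=2).assignments
    a2 = hca(tp, k=2).assignments
    # same partition of the same labels
    groups1 = {frozenset(a1.index[a1 == c]) for c in a1.unique()}
    groups2 = {frozenset(a2.index[a2 == c]) for c in a2.unique()}
    assert groups1 == groups2


def test_hkmeans_agrees_with_tree_cut_on_separated_blobs():
    t = blobs_table(seed=2)
    tree_cut = hca(t, k=2).assignments
    km = hkmeans(t, k=2)
    groups_tree = {frozenset(tree_cut.index[tree_cut == c]) for c in tree_cut.unique()}
    groups_km = {frozenset(km.index[km == c]) for c in km.unique()}
    assert groups_tree == groups_km
    assert hkmeans(t, k=1).nunique() == 1


def test_hkmeans_stable_across_input_row_order():
    t = blobs_table(seed=9, n_per=6)
    base = hkmeans(t, k=2)
    for seed in range(10):
        perm = np.random.default_rng(seed).permutation(len(t))
        res = hkmeans(t.iloc[perm], k=2)
        groups_a = {frozenset(base.index[base == c]) for c in base.unique()}
        groups_b = {frozenset(res.index[res == c]) for c in res.unique()}
        assert groups_a == groups_b


def test_heatmap_order_permutes_to_leaf_order():
    t = blobs_table(seed=4)
    nets = hca(t, k=2)
    meas = hca(t.T, k=2)
    ordered, row_groups, col_groups = heatmap_order(nets, meas, t)
    assert list(ordered.index) == nets.leaf_order()
    assert list(ordered.columns) == meas.leaf_order()
    assert set(ordered.index) == set(t.index)
    with pytest.raises(ValueError, match="labels"):
        heatmap_order(nets, meas, t.rename(index={"r0": "zzz"}))


def test_newick_export_parses():
    import io

    from Bio import Phylo

    t = blobs_table(seed=6)
    res = hca(t, k=2)
    tree = Phylo.read(io.StringIO(res.to_newick()), "newick")
    leaves = {leaf.name for leaf in tree.get_terminals()}
    assert leaves == set(t.index)
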