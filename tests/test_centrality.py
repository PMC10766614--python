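import networkx as nx
import numpy as np
import pytest

from morphonet import CentralityParams, centrality_suite, distance_bundle
from morphonet.centrality import (
    SUITE_MEASURES,
    betweenness,
    closeness,
    communicability_centrality,
    decay,
    eigenvector,
    information_centrality,
    integration,
    katz,
    mean_table,
    pagerank,
    power,
    subgraph_centrality,
)
from morphonet.core_model import MorphNetwork

from .conftest import complete_net, cycle_net, path_net, random_connected_net, star_net
from .oracles import brute_betweenness, expm_taylor, power_iteration_eigenvector


def vals(net, res):
    return res.as_mapping(net)


def test_betweenness_hand_values(path3):
    v = vals(path3, betweenness(path3))
    assert v["v1"] == 1.0 and v["v0"] == 0.0 and v["v2"] == 0.0


@pytest.mark.parametrize("seed", range(6))
def test_betweenness_matches_path_enumeration(seed):
    net = random_connected_net(8, 0.4, seed=seed)
    np.testing.assert_allclose(betweenness(net).values, brute_betweenness(net),
                               atol=1e-9)


def test_closeness_hand_values(path3, star3):
    assert vals(star3, closeness(star3, distance_bundle(star3)))["hub"] == 1.0
    v = vals(path3, closeness(path3, distance_bundle(path3)))
    assert v["v0"] == pytest.approx(2 / 3)
    k4 = complete_net(4)
    assert np.allclose(closeness(k4, distance_bundle(k4)).values, 1.0)


def test_eigenvector_star_and_regular(star3):
    v = vals(star3, eigenvector(star3))
    assert v["hub"] == pytest.approx(1.0)
    assert v["leaf0"] == pytest.approx(1 / np.sqrt(3))
    c6 = cycle_net(6)
    assert np.allclose(eigenvector(c6).values, 1.0)


@pytest.mark.parametrize("seed", range(5))
def test_eigenvector_matches_power_iteration(seed):
    net = random_connected_net(8, 0.45, seed=seed + 50)
    np.testing.assert_allclose(eigenvector(net).values,
                               power_iteration_eigenvector(net), atol=1e-8)


def test_katz_solve_and_limits(single_edge, star3):
    res = katz(single_edge, alpha=0.5)
    np.testing.assert_allclose(res.raw, [2.0, 2.0])
    np.testing.assert_allclose(res.values, [1.0, 1.0])
    # alpha -> 0: uniform
    near0 = katz(star3, alpha=1e-9)
    assert np.allclose(near0.values, 1.0, atol=1e-6)
    # alpha near the bound: direction approaches the principal eigenvector
    lam = np.sqrt(3)
    close = katz(star3, alpha=0.999 / lam).values
    eig = eigenvector(star3).values
    cos = close @ eig / np.linalg.norm(close) / np.linalg.norm(eig)
    assert cos > 0.9999
    with pytest.raises(ValueError, match="lambda_max"):
        katz(star3, alpha=1.0 / lam)


def test_power_hand_values(single_edge, path3):
    res = power(single_edge, CentralityParams(beta=0.2))
    np.testing.assert_allclose(res.raw, [1.25, 1.25])
    np.testing.assert_allclose(res.values, [1.0, 1.0])
    v = vals(path3, power(path3, CentralityParams(beta=0.2)))
    assert v["v1"] > v["v0"] == pytest.approx(v["v2"])
    # beta = 0 reduces to degree
    deg = power(path3, CentralityParams(beta=1e-12)).raw
    np.testing.assert_allclose(deg, [1.0, 2.0, 1.0], atol=1e-9)


def test_power_warns_beyond_spectral_bound():
    k5 = complete_net(5)  # 1/lambda_max = 0.25 < 0.3
    with pytest.warns(RuntimeWarning, match="lambda_max"):
        power(k5, CentralityParams(beta=0.3))


def test_pagerank_regular_uniform_and_star(star3):
    c6 = cycle_net(6)
    np.testing.assert_allclose(pagerank(c6).values, 1 / 6, atol=1e-9)
    res = pagerank(star3)
    v = vals(star3, res)
    assert v["hub"] > v["leaf0"]
    assert res.values.sum() == pytest.approx(1.0)
    # linear-system oracle: pi = (1-d)/n + d A^T D^-1 pi
    a = star3.adjacency()
    dinv = np.diag(1.0 / a.sum(axis=1))
    pi = np.linalg.solve(np.eye(4) - 0.85 * a.T @ dinv, 0.15 * np.ones(4) / 4)
    np.testing.assert_allclose(res.values, pi / pi.sum(), atol=1e-8)


def test_decay_hand_values(path3):
    d = distance_bundle(path3)
    v = vals(path3, decay(path3, d, CentralityParams(delta=0.5)))
    assert v["v1"] == pytest.approx(1.0)
    assert v["v0"] == pytest.approx(0.75)
    k5 = complete_net(5)
    np.testing.assert_allclose(
        decay(k5, distance_bundle(k5), CentralityParams(delta=0.5)).values, 2.0)


@pytest.mark.parametrize("seed", range(4))
def test_decay_matches_double_loop(seed):
    net = random_connected_net(8, 0.35, seed=seed + 9)
    d = distance_bundle(net)
    res = decay(net, d, CentralityParams(delta=0.5)).values
    expected = [sum(0.5 ** d.d[i, j] for j in range(8) if j != i) for i in range(8)]
    np.testing.assert_allclose(res, expected, atol=1e-12)


def test_information_centrality_properties(path3, triangle):
    tri = information_centrality(triangle).values
    assert np.allclose(tri, tri[0])
    v = vals(path3, information_centrality(path3))
    assert v["v1"] > v["v0"] == pytest.approx(v["v2"])


@pytest.mark.parametrize("seed", range(4))
def test_information_centrality_matches_networkx(seed):
    """Own Stephenson-Zelen build equals N * networkx information centrality."""
    net = random_connected_net(9, 0.4, seed=seed + 20)
    mine = information_centrality(net).values
    ref = nx.information_centrality(net.graph)
    np.testing.assert_allclose(
        mine, net.n_nodes * np.array([ref[v] for v in net.nodes]), rtol=1e-8)


def test_matrix_exponential_measures(single_edge, triangle):
    np.testing.assert_allclose(subgraph_centrality(single_edge).values,
                               np.cosh(1.0), atol=1e-10)
    np.testing.assert_allclose(communicability_centrality(single_edge).values,
                               np.e, atol=1e-10)
    np.testing.assert_allclose(subgraph_centrality(triangle).values,
                               (np.e ** 2 + 2 / np.e) / 3, atol=1e-10)


@pytest.mark.parametrize("seed", range(4))
def test_expm_measures_match_taylor_series(seed):
    net = random_connected_net(8, 0.4, seed=seed + 33)
    ref = expm_taylor(net.adjacency())
    np.testing.assert_allclose(subgraph_centrality(net).values, np.diag(ref), atol=1e-8)
    np.testing.assert_allclose(communicability_centrality(net).values,
                               ref.sum(axis=1), atol=1e-8)


def test_integration_hand_values(path3, star3):
    v = vals(star3, integration(star3, distance_bundle(star3)))
    assert v["hub"] == pytest.approx(2.0)
    p = vals(path3, integration(path3, distance_bundle(path3)))
    assert p["v1"] == pytest.approx(2.0) and p["v0"] == pytest.approx(1.5)
    k4 = complete_net(4)
    assert np.allclose(integration(k4, distance_bundle(k4)).values, 1.0)


def test_suite_complete_and_isomorphism_invariant(star3):
    suite = centrality_suite(star3)
    assert set(suite) == set(SUITE_MEASURES)
    # star center dominates every measure
    for name, res in suite.items():
        v = vals(star3, res)
        assert v["hub"] == max(v.values()), name
    # relabeled isomorphic copy: identical means
    g2 = nx.relabel_nodes(star3.graph, {"hub": "H", "leaf0": "x",
                                        "leaf1": "y", "leaf2": "z"})
    net2 = MorphNetwork("star_relab", g2)
    means = mean_table({"a": suite, "b": centrality_suite(net2)})
    np.testing.assert_allclose(means.loc["a"], means.loc["b"], atol=1e-9)


def test_suite_uniform_on_regular_graphs():
    c8 = cycle_net(8)
    suite = centrality_suite(c8)
    for name in ("eigenvector", "katz", "power", "pagerank", "subgraph",
                 "communicability", "closeness", "decay"):
        v = suite[name].values
        assert np.allclose(v, v[0]), name
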