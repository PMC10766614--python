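"""Independent brute-force oracles used only by the test suite.

Everything here is written as plain double loops over node pairs and edges,
deliberately avoiding the vectorized code paths of the package so that the
two routes to each quantity stay independent.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np


def floyd_warshall(net) -> np.ndarray:
    """All-pairs shortest paths by the classic triple loop."""
    n = net.n_nodes
    idx = {v: i for i, v in enumerate(net.nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for a, b in net.graph.edges:
        d[idx[a], idx[b]] = d[idx[b], idx[a]] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def log2(x):
    return math.log2(x)


def naive_battery(net) -> dict[str, float]:
    """The full 40-measure battery computed with naive loops."""
    n, m = net.n_nodes, net.n_edges
    nodes = net.nodes
    idx = {v: i for i, v in enumerate(nodes)}
    k = [net.graph.degree(v) for v in nodes]
    d = floyd_warshall(net)
    sigma = [sum(d[i, j] for j in range(n)) for i in range(n)]
    ecc = [max(d[i, j] for j in range(n)) for i in range(n)]
    w = sum(d[i, j] for i in range(n) for j in range(i + 1, n))
    edges = [(idx[a], idx[b]) for a, b in net.graph.edges]

    out: dict[str, float] = {}
    out["wiener"] = w
    out["harary"] = sum(1.0 / d[i, j] for i in range(n) for j in range(i + 1, n))
    out["average_distance"] = 2.0 * w / (n * (n - 1))
    mu_c = m - n + 1
    out["balaban_j"] = (m / (mu_c + 1)) * sum(
        1.0 / math.sqrt(sigma[i] * sigma[j]) for i, j in edges)
    out["mean_distance_deviation"] = sum(abs(s - 2.0 * w / n) for s in sigma) / n
    out["eccentricity"] = sum(ecc) / n
    out["centralization"] = sum(s - min(sigma) for s in sigma)
    w_path = n * (n * n - 1) / 6.0
    w_star = (n - 1) ** 2
    out["compactness"] = (w_path - w) / (w_path - w_star) if w_path > w_star else 0.0
    out["konstantinova"] = -sum(
        (s / (2 * w)) * log2(s / (2 * w)) for s in sigma if s > 0)

    out["zagreb_1"] = sum(x * x for x in k)
    out["zagreb_2"] = sum(k[i] * k[j] for i, j in edges)
    out["randic"] = sum(1.0 / math.sqrt(k[i] * k[j]) for i, j in edges)
    out["complexity_index_b"] = sum(k[i] / sigma[i] for i in range(n))
    out["normalized_edge_complexity"] = sum(k) / (n * (n - 1) / 2.0)

    # distance distribution g_k
    g: dict[int, int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            g[int(d[i, j])] = g.get(int(d[i, j]), 0) + 1
    p_tot = n * (n - 1) / 2.0
    out["bonchev_1"] = -sum((c / p_tot) * log2(c / p_tot) for c in g.values())
    out["bonchev_2"] = w * log2(w) - sum(c * kk * log2(kk) for kk, c in g.items() if kk > 1)
    out["bertz"] = 2 * m * log2(2 * m) - sum(x * log2(x) for x in k if x > 1)
    ecc_classes: dict[float, int] = {}
    for e in ecc:
        ecc_classes[e] = ecc_classes.get(e, 0) + 1
    out["radial_centric"] = -sum((c / n) * log2(c / n) for c in ecc_classes.values())

    h = []
    for i in range(n):
        layers: dict[int, int] = {}
        for j in range(n):
            layers[int(d[i, j])] = layers.get(int(d[i, j]), 0) + 1
        h.append(-sum((c / n) * log2(c / n) for c in layers.values()))
    out["graph_vertex_complexity"] = sum(h) / n
    out["information_layer"] = sum(h)

    u = [sigma[i] * log2(sigma[i])
         - sum(d[i, j] * log2(d[i, j]) for j in range(n) if d[i, j] > 1)
         for i in range(n)]
    v = [h[i] * sigma[i] for i in range(n)]

    def bal_like(wgt):
        terms = [1.0 / math.sqrt(wgt[i] * wgt[j]) for i, j in edges
                 if wgt[i] * wgt[j] > 0]
        return (m / (mu_c + 1)) * sum(terms) if terms else 0.0

    out["balaban_like_1"] = bal_like(u)
    out["balaban_like_2"] = bal_like(v)

    cls: dict[tuple, int] = {}
    for i, j in edges:
        key = (min(k[i], k[j]), max(k[i], k[j]))
        cls[key] = cls.get(key, 0) + 1
    out["edge_equality"] = sum((c / m) ** 2 for c in cls.values())

    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    lam = sorted(np.linalg.eigvalsh(a).tolist(), reverse=True)
    lap = np.diag(a.sum(axis=1)) - a
    mu = sorted(max(x, 0.0) for x in np.linalg.eigvalsh(lap).tolist())
    out["estrada"] = sum(math.exp(x) for x in lam)
    out["laplacian_estrada"] = sum(math.exp(x) for x in mu)
    out["energy"] = sum(abs(x) for x in lam)
    out["laplacian_energy"] = sum(abs(x - 2.0 * m / n) for x in mu)
    out["spectral_radius"] = lam[0]

    out["nodes"] = float(n)
    out["edges"] = float(m)
    out["diameter"] = max(ecc)
    out["radius"] = min(ecc)
    out["average_path_length"] = 2.0 * w / (n * (n - 1))
    out["average_degree"] = 2.0 * m / n
    out["average_clustering"] = naive_clustering(net)
    out["density"] = 2.0 * m / (n * (n - 1))

    out["mag"] = naive_mag(net)
    out["ce"] = naive_ce(net, d)
    out["cr"] = naive_cr(n, lam[0])
    out["odc"] = naive_odc(net)
    return out


def naive_clustering(net) -> float:
    total = 0.0
    for v in net.nodes:
        nbrs = list(net.graph.neighbors(v))
        deg = len(nbrs)
        if deg < 2:
            continue
        links = sum(1 for i in range(deg) for j in range(i + 1, deg)
                    if net.graph.has_edge(nbrs[i], nbrs[j]))
        total += 2.0 * links / (deg * (deg - 1))
    return total / net.n_nodes


def naive_mag(net) -> float:
    m2 = 2 * net.n_edges
    i_tot = r_tot = 0.0
    for a, b in net.graph.edges:
        ka, kb = net.graph.degree(a), net.graph.degree(b)
        for _ in range(2):  # both directed copies
            i_tot += (1.0 / m2) * log2(m2 / (ka * kb))
            r_tot += (1.0 / m2) * log2(ka * kb)
    denom = log2(m2) ** 2
    return 4.0 * i_tot * r_tot / denom if denom > 0 else 0.0


def naive_ce(net, d) -> float:
    n = net.n_nodes
    e = sum(1.0 / d[i, j] for i in range(n) for j in range(n) if i != j) / (n * (n - 1))
    ep = sum(1.0 / abs(i - j) for i in range(n) for j in range(n) if i != j) / (n * (n - 1))
    if ep >= 1.0:
        return 0.0
    x = (e - ep) / (1.0 - ep)
    x = min(max(x, 0.0), 1.0)
    return 4.0 * x * (1.0 - x)


def naive_cr(n, lam_max) -> float:
    lo = 2.0 * math.cos(math.pi / (n + 1))
    if n - 1 <= lo:
        return 0.0
    c = (lam_max - lo) / (n - 1 - lo)
    c = min(max(c, 0.0), 1.0)
    return 4.0 * c * (1.0 - c)


def naive_odc(net) -> float:
    k_max = max(dict(net.graph.degree).values())
    if k_max <= 1:
        return 0.0
    counts: dict[int, int] = {}
    for a, b in net.graph.edges:
        off = abs(net.graph.degree(a) - net.graph.degree(b))
        counts[off] = counts.get(off, 0) + 1
    if len(counts) <= 1:
        return 0.0
    tot = sum(counts.values())
    s = -sum((c / tot) * math.log(c / tot) for c in counts.values())
    return s / math.log(k_max)


def brute_betweenness(net) -> np.ndarray:
    """Betweenness by explicit enumeration of all shortest paths."""
    nodes = net.nodes
    idx = {v: i for i, v in enumerate(nodes)}
    scores = np.zeros(len(nodes))
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = list(nx.all_shortest_paths(net.graph, s, t))
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                scores[idx[v]] += through / len(paths)
    return scores


def power_iteration_eigenvector(net, iters=10_000, tol=1e-14) -> np.ndarray:
    a = net.adjacency()
    x = np.ones(net.n_nodes)
    for _ in range(iters):
        y = a @ x
        y = y / np.linalg.norm(y)
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    return x / x.max()


def expm_taylor(a: np.ndarray, terms: int = 40) -> np.ndarray:
    out = np.eye(a.shape[0])
    term = np.eye(a.shape[0])
    for kk in range(1, terms):
        term = term @ a / kk
        out = out + term
    return out
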