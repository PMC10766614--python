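"""Network parameters and chemical-graph topological descriptors.

The battery characterizes a whole-body morphological network with 40 scalar
invariants: 8 classical network parameters, ~28 topological descriptors from
chemical graph theory (distance-, degree-, information- and eigenvalue-based)
and, via :mod:`morphonet.complexity`, 4 normalized complexity measures.

All information-theoretic descriptors use base-2 logarithms (bits), with the
convention 0*log(0) = 0. Several descriptors the source literature names but
never defines (compactness, centralization, eccentricity aggregate,
Konstantinova, edge equality, information layer, Balaban-like variants) follow
standard reconstructions documented in docs/methods.md; the chosen variant is
recorded in :data:`VARIANTS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .core_model import DistanceBundle, MorphNetwork, distance_bundle

#: The fixed measure registry: every battery run emits exactly these names.
REGISTRY: tuple[str, ...] = (
    # distance-based descriptors
    "wiener", "harary", "balaban_j", "mean_distance_deviation", "compactness",
    "eccentricity", "centralization", "average_distance", "konstantinova",
    # degree-based descriptors
    "zagreb_1", "zagreb_2", "randic", "complexity_index_b",
    "normalized_edge_complexity",
    # information-theoretic descriptors
    "bonchev_1", "bonchev_2", "bertz", "radial_centric", "balaban_like_1",
    "balaban_like_2", "graph_vertex_complexity", "edge_equality",
    "information_layer",
    # eigenvalue-based descriptors
    "estrada", "laplacian_estrada", "energy", "laplacian_energy",
    "spectral_radius",
    # network parameters
    "nodes", "edges", "diameter", "radius", "average_path_length",
    "average_degree", "average_clustering", "density",
    # normalized complexity measures
    "mag", "ce", "cr", "odc",
)

VARIANTS = {
    "log_base": 2,
    "eccentricity": "mean over vertices",
    "centralization": "distance-based sum of (sigma_i - sigma_min)",
    "compactness": "Wiener normalized between path (0) and star (1)",
    "bonchev_1": "distance-distribution entropy",
    "bonchev_2": "magnitude-based distance information",
    "balaban_like": "u-index / x-index on local distance information",
}


def _xlog2(x: np.ndarray | float) -> np.ndarray | float:
    """x * log2(x) with the 0*log(0) = 0 convention."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log2(x[nz])
    return out if out.ndim else float(out)


def _entropy2(p: np.ndarray) -> float:
    """Shannon entropy (bits) of a probability vector, ignoring zeros."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


@dataclass
class SpectraBundle:
    """Adjacency and Laplacian spectra of a network.

    Adjacency eigenvalues are stored descending, Laplacian ascending; tiny
    negative Laplacian eigenvalues from floating point are clipped to 0.
    """

    adjacency_eigs: np.ndarray
    laplacian_eigs: np.ndarray

    @property
    def lambda_max(self) -> float:
        return float(self.adjacency_eigs[0])


def spectra_bundle(net: MorphNetwork) -> SpectraBundle:
    a = net.adjacency()
    lam = np.linalg.eigvalsh(a)[::-1]
    lap = np.diag(a.sum(axis=1)) - a
    mu = np.linalg.eigvalsh(lap)
    mu = np.clip(mu, 0.0, None)
    return SpectraBundle(adjacency_eigs=lam, laplacian_eigs=mu)


def network_parameters(net: MorphNetwork, dist: DistanceBundle) -> dict[str, float]:
    """The 8 basic parameters: N, M, diameter, radius, mean path length,
    mean degree, mean local clustering (k<2 nodes contribute 0), density."""
    n, m = net.n_nodes, net.n_edges
    return {
        "nodes": float(n),
        "edges": float(m),
        "diameter": float(dist.ecc.max()),
        "radius": float(dist.ecc.min()),
        "average_path_length": 2.0 * dist.wiener / (n * (n - 1)),
        "average_degree": 2.0 * m / n,
        "average_clustering": float(nx.average_clustering(net.graph)),
        "density": 2.0 * m / (n * (n - 1)),
    }


def path_wiener(n: int) -> float:
    """Wiener index of the n-node path: n(n^2-1)/6."""
    return n * (n * n - 1) / 6.0


def star_wiener(n: int) -> float:
    """Wiener index of the n-node star: (n-1)^2."""
    return float((n - 1) ** 2)


def distance_descriptors(net: MorphNetwork, dist: DistanceBundle) -> dict[str, float]:
    n, m = net.n_nodes, net.n_edges
    d, sigma, w = dist.d, dist.sigma, dist.wiener
    iu = np.triu_indices(n, k=1)
    du = d[iu]

    mu_c = m - n + 1  # cyclomatic number
    idx = {v: i for i, v in enumerate(net.nodes)}
    e_idx = np.array([(idx[u], idx[v]) for u, v in net.graph.edges])
    balaban_j = (m / (mu_c + 1)) * float(
        (1.0 / np.sqrt(sigma[e_idx[:, 0]] * sigma[e_idx[:, 1]])).sum()
    )

    wp, ws = path_wiener(n), star_wiener(n)
    compactness = (wp - w) / (wp - ws) if wp > ws else 0.0

    return {
        "wiener": w,
        "harary": float((1.0 / du).sum()),
        "average_distance": 2.0 * w / (n * (n - 1)),
        "balaban_j": balaban_j,
        "mean_distance_deviation": float(np.abs(sigma - 2.0 * w / n).mean()),
        "eccentricity": float(dist.ecc.mean()),
        "centralization": float((sigma - sigma.min()).sum()),
        "compactness": compactness,
        "konstantinova": _entropy2(sigma / (2.0 * w)),
    }


def degree_descriptors(net: MorphNetwork, dist: DistanceBundle) -> dict[str, float]:
    n = net.n_nodes
    k = net.degrees.astype(float)
    idx = {v: i for i, v in enumerate(net.nodes)}
    e_idx = np.array([(idx[u], idx[v]) for u, v in net.graph.edges])
    kk = k[e_idx[:, 0]] * k[e_idx[:, 1]]
    return {
        "zagreb_1": float((k ** 2).sum()),
        "zagreb_2": float(kk.sum()),
        "randic": float((1.0 / np.sqrt(kk)).sum()),
        "complexity_index_b": float((k / dist.sigma).sum()),
        # connectedness: sum of degrees over the edge count of the complete graph
        "normalized_edge_complexity": float(k.sum()) / (n * (n - 1) / 2.0),
    }


def information_descriptors(net: MorphNetwork, dist: DistanceBundle) -> dict[str, float]:
    n, m = net.n_nodes, net.n_edges
    k = net.degrees.astype(float)
    d, sigma, w = dist.d, dist.sigma, dist.wiener
    g_k = dist.pair_distance_counts
    p_total = n * (n - 1) / 2.0

    bonchev_1 = _entropy2(np.array([c / p_total for c in g_k.values()]))
    bonchev_2 = float(_xlog2(w) - sum(c * kk * np.log2(kk) for kk, c in g_k.items() if kk > 1))
    bertz = float(_xlog2(2.0 * m) - _xlog2(k).sum())

    _, ecc_counts = np.unique(dist.ecc, return_counts=True)
    radial_centric = _entropy2(ecc_counts / n)

    # per-node layer entropies H_i over n_k^i / N, including the k=0 self-layer
    h = np.array([_entropy2(dist.layer_counts(i) / n) for i in range(n)])

    # Balaban-like information indices on local distance information
    u = _xlog2(sigma) - _xlog2(d).sum(axis=1)  # u-index
    v = h * sigma                               # layer-entropy-weighted distance degree
    mu_c = m - n + 1
    idx = {lab: i for i, lab in enumerate(net.nodes)}
    e_idx = np.array([(idx[a], idx[b]) for a, b in net.graph.edges])

    def balaban_like(weights: np.ndarray) -> float:
        prod = weights[e_idx[:, 0]] * weights[e_idx[:, 1]]
        ok = prod > 0
        if not ok.any():
            return 0.0
        return (m / (mu_c + 1)) * float((1.0 / np.sqrt(prod[ok])).sum())

    # edge classes by unordered endpoint-degree pair
    pairs = {}
    for a, b in e_idx:
        key = (min(k[a], k[b]), max(k[a], k[b]))
        pairs[key] = pairs.get(key, 0) + 1
    edge_equality = float(sum((c / m) ** 2 for c in pairs.values()))

    return {
        "bonchev_1": bonchev_1,
        "bonchev_2": bonchev_2,
        "bertz": bertz,
        "radial_centric": radial_centric,
        "graph_vertex_complexity": float(h.mean()),
        "information_layer": float(h.sum()),
        "balaban_like_1": balaban_like(u),
        "balaban_like_2": balaban_like(v),
        "edge_equality": edge_equality,
    }


def spectral_descriptors(net: MorphNetwork, spectra: SpectraBundle) -> dict[str, float]:
    lam, mu = spectra.adjacency_eigs, spectra.laplacian_eigs
    mean_deg = 2.0 * net.n_edges / net.n_nodes
    return {
        "estrada": float(np.exp(lam).sum()),
        "laplacian_estrada": float(np.exp(mu).sum()),
        "energy": float(np.abs(lam).sum()),
        "laplacian_energy": float(np.abs(mu - mean_deg).sum()),
        "spectral_radius": spectra.lambda_max,
    }


def descriptor_vector(net: MorphNetwork, dist: DistanceBundle | None = None,
                      spectra: SpectraBundle | None = None) -> dict[str, float]:
    """Compute the full 40-measure battery for one network.

    Returns a dict keyed by :data:`REGISTRY` names, in registry order; the
    complexity block is delegated to :mod:`morphonet.complexity`.
    """
    from . import complexity

    if dist is None:
        dist = distance_bundle(net)
    if spectra is None:
        spectra = spectra_bundle(net)
    values: dict[str, float] = {}
    values.update(distance_descriptors(net, dist))
    values.update(degree_descriptors(net, dist))
    values.update(information_descriptors(net, dist))
    values.update(spectral_descriptors(net, spectra))
    values.update(network_parameters(net, dist))
    values.update({
        "mag": complexity.medium_articulation(net),
        "ce": complexity.efficiency_complexity(net, dist),
        "cr": complexity.graph_index_complexity(net, spectra),
        "odc": complexity.offdiagonal_complexity(net),
    })
    ordered = {name: values[name] for name in REGISTRY}
    bad = [k for k, val in ordered.items() if not np.isfinite(val)]
    if bad:
        raise ValueError(f"non-finite descriptor values for {net.name}: {bad}")
    return ordered


def measure_table(nets: Iterable[MorphNetwork]) -> pd.DataFrame:
    """Networks x measures table (rows in input order, 40 registry columns)."""
    rows = {net.name: descriptor_vector(net) for net in nets}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(REGISTRY))
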