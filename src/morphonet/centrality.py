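"""Per-node centrality suite and per-network summaries.

The suite quantifies, node by node, how much "influence" each morphological
unit exerts on the rest of the body network. The walk-based family
(eigenvector, Katz, Bonacich power, PageRank) operationalizes the
evolutionary developmental potential of a unit; the distance family
(closeness, decay, integration, information) and the path family
(betweenness) probe complementary notions of importance.

Normalization conventions: eigenvector/Katz are max-normalized (maximum
exactly 1), power is rescaled so that sum of squares equals N (the "scaled"
variant), PageRank is unit-sum, everything else is reported raw. Raw vectors
are retained on every result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .core_model import DistanceBundle, MorphNetwork, distance_bundle
from .descriptors import SpectraBundle, spectra_bundle


@dataclass
class CentralityParams:
    """Tunable parameters of the walk/distance-based measures.

    beta: Bonacich power attenuation (radius of influence; low values probe
    local structure). delta: decay parameter in (0, 1). alpha_factor: Katz
    attenuation as a fraction of 1/lambda_max. damping: PageRank damping.
    """

    beta: float = 0.2
    delta: float = 0.5
    alpha_factor: float = 0.85
    damping: float = 0.85

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError(f"decay parameter delta must lie in (0,1), got {self.delta}")
        if not 0.0 < self.damping < 1.0:
            raise ValueError(f"PageRank damping must lie in (0,1), got {self.damping}")
        if not 0.0 < self.alpha_factor < 1.0:
            raise ValueError(f"Katz alpha factor must lie in (0,1), got {self.alpha_factor}")


@dataclass
class CentralityResult:
    """Per-node values of one centrality index, in canonical node order."""

    measure: str
    values: np.ndarray
    normalization: str = "raw"
    raw: np.ndarray | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    def as_mapping(self, net: MorphNetwork) -> dict[str, float]:
        return dict(zip(net.nodes, map(float, self.values)))


def betweenness(net: MorphNetwork) -> CentralityResult:
    """Shortest-path betweenness (Brandes), unnormalized pair counts."""
    bc = nx.betweenness_centrality(net.graph, normalized=False)
    return CentralityResult("betweenness", np.array([bc[v] for v in net.nodes]))


def closeness(net: MorphNetwork, dist: DistanceBundle) -> CentralityResult:
    """Normalized closeness (N-1)/sigma_i."""
    vals = (net.n_nodes - 1) / dist.sigma
    return CentralityResult("closeness", vals, normalization="raw")


def eigenvector(net: MorphNetwork) -> CentralityResult:
    """Principal adjacency eigenvector, non-negative, max-normalized."""
    a = net.adjacency()
    w, v = np.linalg.eigh(a)
    vec = v[:, -1]
    vec = np.abs(vec)  # Perron vector of a connected graph is sign-definite
    raw = vec.copy()
    return CentralityResult("eigenvector", vec / vec.max(), "max1", raw=raw)


def katz(net: MorphNetwork, params: CentralityParams | None = None,
         alpha: float | None = None) -> CentralityResult:
    """Katz centrality x = (I - alpha*A)^{-1} 1, max-normalized.

    ``alpha`` overrides the default ``alpha_factor / lambda_max``; a value at
    or beyond the convergence bound 1/lambda_max raises."""
    params = params or CentralityParams()
    a = net.adjacency()
    lam_max = float(np.linalg.eigvalsh(a)[-1])
    if alpha is None:
        alpha = params.alpha_factor / lam_max
    if alpha >= 1.0 / lam_max:
        raise ValueError(
            f"Katz attenuation alpha={alpha:.6g} >= 1/lambda_max={1.0 / lam_max:.6g}: "
            "walk series diverges")
    raw = np.linalg.solve(np.eye(net.n_nodes) - alpha * a, np.ones(net.n_nodes))
    return CentralityResult("katz", raw / raw.max(), "max1", raw=raw)


def power(net: MorphNetwork, params: CentralityParams | None = None) -> CentralityResult:
    """Bonacich power centrality c(beta) = (I - beta*A)^{-1} A 1, scaled so
    sum(c^2) = N. A warning is emitted when beta >= 1/lambda_max (the walk
    series diverges there, but the linear system may still be solvable)."""
    params = params or CentralityParams()
    a = net.adjacency()
    n = net.n_nodes
    lam_max = float(np.linalg.eigvalsh(a)[-1])
    if params.beta >= 1.0 / lam_max:
        warnings.warn(
            f"power centrality beta={params.beta} >= 1/lambda_max={1.0 / lam_max:.6g}; "
            "computing the analytic continuation of the diverging walk series",
            RuntimeWarning, stacklevel=2)
    sys = np.eye(n) - params.beta * a
    if abs(np.linalg.det(sys)) < 1e-12:
        raise ValueError(
            f"power centrality system singular at beta={params.beta} "
            f"(1/lambda_max={1.0 / lam_max:.6g})")
    raw = np.linalg.solve(sys, a @ np.ones(n))
    scale = np.sqrt(n / (raw ** 2).sum())
    return CentralityResult("power", raw * scale, "sum_sq_n", raw=raw)


def pagerank(net: MorphNetwork, params: CentralityParams | None = None) -> CentralityResult:
    """Damped random-walk stationary distribution, unit-sum."""
    params = params or CentralityParams()
    pr = nx.pagerank(net.graph, alpha=params.damping, tol=1e-12, max_iter=500)
    return CentralityResult("pagerank", np.array([pr[v] for v in net.nodes]), "unit_sum")


def decay(net: MorphNetwork, dist: DistanceBundle,
          params: CentralityParams | None = None) -> CentralityResult:
    """Decay centrality sum_{j != i} delta^{d_ij}."""
    params = params or CentralityParams()
    d = dist.d
    vals = (params.delta ** d).sum(axis=1) - 1.0  # remove the d_ii = 0 term
    return CentralityResult("decay", vals)


def _information_matrix(net: MorphNetwork) -> np.ndarray:
    """Inverse of B = Laplacian + J (Stephenson-Zelen construction)."""
    a = net.adjacency()
    lap = np.diag(a.sum(axis=1)) - a
    return np.linalg.inv(lap + np.ones_like(a))


def information_centrality(net: MorphNetwork, variant: str = "harmonic") -> CentralityResult:
    """Stephenson-Zelen information centrality.

    ``variant="harmonic"`` (default): I_i = N / (N*C_ii + T - 2*R_i), the
    harmonic aggregate of the pairwise information I_ij = 1/(C_ii+C_jj-2C_ij).
    ``variant="trace"``: the simplified 1/C_ii form. The two behave like the
    two variants commonly reported by network toolkits.
    """
    c = _information_matrix(net)
    n = net.n_nodes
    if variant == "harmonic":
        t = np.trace(c)
        r = c.sum(axis=1)
        vals = n / (n * np.diag(c) + t - 2.0 * r)
        name = "information"
    elif variant == "trace":
        vals = 1.0 / np.diag(c)
        name = "information_trace"
    else:
        raise ValueError(f"unknown information-centrality variant {variant!r}")
    return CentralityResult(name, vals)


def subgraph_centrality(net: MorphNetwork,
                        spectra: SpectraBundle | None = None) -> CentralityResult:
    """SC_i = (exp A)_ii via dense eigendecomposition."""
    a = net.adjacency()
    w, v = np.linalg.eigh(a)
    vals = (v ** 2 * np.exp(w)).sum(axis=1)
    return CentralityResult("subgraph", vals)


def communicability_centrality(net: MorphNetwork,
                               spectra: SpectraBundle | None = None) -> CentralityResult:
    """Total communicability TC_i = sum_j (exp A)_ij."""
    a = net.adjacency()
    w, v = np.linalg.eigh(a)
    expa = (v * np.exp(w)) @ v.T
    return CentralityResult("communicability", expa.sum(axis=1))


def integration(net: MorphNetwork, dist: DistanceBundle) -> CentralityResult:
    """Valente-Foreman reverse-distance integration:
    (1/(N-1)) * sum_{j != i} (d_max + 1 - d_ij)."""
    n = net.n_nodes
    d_max = float(dist.ecc.max())
    rev = d_max + 1.0 - dist.d
    np.fill_diagonal(rev, 0.0)
    return CentralityResult("integration", rev.sum(axis=1) / (n - 1))


#: Measures included in the default suite, in display order.
SUITE_MEASURES: tuple[str, ...] = (
    "betweenness", "closeness", "eigenvector", "katz", "power", "pagerank",
    "decay", "information", "information_trace", "subgraph",
    "communicability", "integration",
)


def centrality_suite(net: MorphNetwork, params: CentralityParams | None = None,
                     dist: DistanceBundle | None = None,
                     measures: tuple[str, ...] = SUITE_MEASURES,
                     ) -> dict[str, CentralityResult]:
    """Run every requested measure; failures are flagged, not fatal."""
    params = params or CentralityParams()
    if dist is None:
        dist = distance_bundle(net)
    runners: dict[str, Callable[[], CentralityResult]] = {
        "betweenness": lambda: betweenness(net),
        "closeness": lambda: closeness(net, dist),
        "eigenvector": lambda: eigenvector(net),
        "katz": lambda: katz(net, params),
        "power": lambda: power(net, params),
        "pagerank": lambda: pagerank(net, params),
        "decay": lambda: decay(net, dist, params),
        "information": lambda: information_centrality(net, "harmonic"),
        "information_trace": lambda: information_centrality(net, "trace"),
        "subgraph": lambda: subgraph_centrality(net),
        "communicability": lambda: communicability_centrality(net),
        "integration": lambda: integration(net, dist),
    }
    out: dict[str, CentralityResult] = {}
    for name in measures:
        try:
            out[name] = runners[name]()
        except (np.linalg.LinAlgError, ValueError) as exc:  # flag, keep going
            warnings.warn(f"centrality {name!r} failed on {net.name}: {exc}",
                          RuntimeWarning, stacklevel=2)
    return out


def node_table(net: MorphNetwork, suite: Mapping[str, CentralityResult]) -> pd.DataFrame:
    """Per-node table: one row per node (canonical order), one column per measure."""
    return pd.DataFrame({name: res.values for name, res in suite.items()},
                        index=net.nodes)


def mean_table(nets_suites: Mapping[str, Mapping[str, CentralityResult]]) -> pd.DataFrame:
    """Per-network summary: one row per network, mean value per measure."""
    return pd.DataFrame({
        net_name: {m: res.mean for m, res in suite.items()}
        for net_name, suite in nets_suites.items()
    }).T
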