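"""Normalized graph complexity measures mapping a network into [0, 1].

These measures are built so that both near-empty (tree/path-like) and
near-complete graphs score low, peaking at intermediate edge densities where
intricate internal structure (modules, hierarchies) can exist:

* ``MAg`` (medium articulation): product of the redundancy R and mutual
  information I of the uniform directed-edge ensemble, normalized by its
  maximum. Since I + R = log2(2M) identically, the scale-free normalization
  4*I*R/(I+R)^2 is used.
* ``Ce`` (efficiency complexity): network efficiency E (mean inverse
  shortest-path length) rescaled between the N-path anchor (e=0) and the
  complete graph (e=1), then folded with 4e(1-e).
* ``Cr`` (graph index complexity): position of the spectral radius between
  the N-path bound 2cos(pi/(N+1)) and the complete-graph bound N-1, folded
  with 4c(1-c).
* ``OdC`` (offdiagonal complexity): entropy (natural log) of the distribution
  of degree-difference offsets in the node-node link correlation matrix,
  normalized by ln(k_max).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import DistanceBundle, MorphNetwork
from .descriptors import SpectraBundle


def edge_information_split(net: MorphNetwork) -> tuple[float, float]:
    """(I, R): mutual information and redundancy of the directed-edge ensemble.

    Each of the 2M directed edges carries weight 1/(2M); I + R = log2(2M).
    """
    k = net.degrees.astype(float)
    idx = {v: i for i, v in enumerate(net.nodes)}
    m2 = 2.0 * net.n_edges
    i_total = 0.0
    r_total = 0.0
    for a, b in net.graph.edges:
        kk = k[idx[a]] * k[idx[b]]
        i_total += 2.0 / m2 * np.log2(m2 / kk)
        r_total += 2.0 / m2 * np.log2(kk)
    return float(i_total), float(r_total)


def medium_articulation(net: MorphNetwork) -> float:
    """MAg = 4*I*R / (log2(2M))^2, in [0, 1]."""
    i, r = edge_information_split(net)
    denom = np.log2(2.0 * net.n_edges) ** 2
    if denom == 0.0:  # single edge: 2M = 2, I = 1, R = 0
        return 0.0
    return float(np.clip(4.0 * i * r / denom, 0.0, 1.0))


def efficiency(dist: DistanceBundle) -> float:
    """Mean inverse shortest-path length over ordered pairs."""
    n = dist.n
    iu = np.triu_indices(n, k=1)
    return float((1.0 / dist.d[iu]).sum()) * 2.0 / (n * (n - 1))


def path_efficiency(n: int) -> float:
    """Efficiency of the n-node path (closed form via harmonic-type sum)."""
    ks = np.arange(1, n)
    return float((2.0 * (n - ks) / ks).sum()) / (n * (n - 1))


def efficiency_complexity(net: MorphNetwork, dist: DistanceBundle) -> float:
    """Ce = 4e(1-e) with e the efficiency rescaled between path and complete anchors."""
    n = net.n_nodes
    e_path = path_efficiency(n)
    if e_path >= 1.0:  # n = 2: path and complete graph coincide
        return 0.0
    e = (efficiency(dist) - e_path) / (1.0 - e_path)
    e = float(np.clip(e, 0.0, 1.0))
    return float(np.clip(4.0 * e * (1.0 - e), 0.0, 1.0))


def graph_index_complexity(net: MorphNetwork, spectra: SpectraBundle) -> float:
    """Cr = 4c(1-c) with c locating lambda_max between the path and complete bounds."""
    n = net.n_nodes
    lo = 2.0 * np.cos(np.pi / (n + 1))
    hi = float(n - 1)
    if hi <= lo:  # n = 2
        return 0.0
    c = (spectra.lambda_max - lo) / (hi - lo)
    c = float(np.clip(c, 0.0, 1.0))
    return float(np.clip(4.0 * c * (1.0 - c), 0.0, 1.0))


def offdiagonal_complexity(net: MorphNetwork) -> float:
    """OdC: normalized entropy of degree-offset abundances a_m = sum_k c_{k,k+m}.

    c_{kl} counts edges joining a degree-k to a degree-l node (k <= l); the
    entropy of the offset distribution m = l - k uses the natural log and is
    normalized by ln(k_max). Zero when k_max <= 1 or a single offset occurs.
    """
    k = net.degrees
    idx = {v: i for i, v in enumerate(net.nodes)}
    k_max = int(k.max())
    if k_max <= 1:
        return 0.0
    offsets: dict[int, int] = {}
    for a, b in net.graph.edges:
        m = abs(int(k[idx[a]]) - int(k[idx[b]]))
        offsets[m] = offsets.get(m, 0) + 1
    if len(offsets) <= 1:
        return 0.0
    a_m = np.array(list(offsets.values()), dtype=float)
    p = a_m / a_m.sum()
    s = float(-(p * np.log(p)).sum())
    return float(np.clip(s / np.log(k_max), 0.0, 1.0))


@dataclass
class ComplexityScores:
    """The four normalized scores plus the reusable intermediates."""

    mag: float
    ce: float
    cr: float
    odc: float
    mutual_information: float
    redundancy: float
    efficiency: float
    index_r: float


def complexity_scores(net: MorphNetwork, dist: DistanceBundle,
                      spectra: SpectraBundle) -> ComplexityScores:
    i, r = edge_information_split(net)
    n = net.n_nodes
    lo = 2.0 * np.cos(np.pi / (n + 1))
    c_r = 0.0 if n <= 2 else float(
        np.clip((spectra.lambda_max - lo) / (n - 1 - lo), 0.0, 1.0))
    return ComplexityScores(
        mag=medium_articulation(net),
        ce=efficiency_complexity(net, dist),
        cr=graph_index_complexity(net, spectra),
        odc=offdiagonal_complexity(net),
        mutual_information=i,
        redundancy=r,
        efficiency=efficiency(dist),
        index_r=c_r,
    )
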