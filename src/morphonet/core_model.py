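"""Network data model, validation, file I/O and all-pairs distances.

A morphological network encodes one organism's external anatomy: nodes are
discrete morphological units (segments, articles, endites, exites, epipods,
flagellae, shields, eyes) and edges are physical articulations between them.
Networks are simple, undirected and connected, and arrive either as labeled
0/1 adjacency matrices (CSV) or from the synthetic body-plan generator.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

REGION_LABELS = ("axis", "head_shield", "appendage", "eye", "other")


class ValidationError(ValueError):
    """Raised when an adjacency matrix or graph violates the model invariants."""


@dataclass
class MorphNetwork:
    """A labeled, connected, simple undirected morphological network.

    Parameters
    ----------
    name
        Label of the organism/group (e.g. ``"Triops"``).
    graph
        ``networkx.Graph`` whose node insertion order defines the canonical
        node order used by every downstream vector and matrix.
    annotations
        Optional map node label -> anatomical region, one of
        ``axis, head_shield, appendage, eye, other``.
    """

    name: str
    graph: nx.Graph
    annotations: dict[str, str] | None = None

    def __post_init__(self) -> None:
        validate_graph(self.graph)
        if self.annotations is not None:
            bad = {r for r in self.annotations.values() if r not in REGION_LABELS}
            if bad:
                raise ValidationError(f"unknown region labels: {sorted(bad)}")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degrees(self) -> np.ndarray:
        return np.array([self.graph.degree(v) for v in self.graph.nodes], dtype=np.int64)

    def adjacency(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix in canonical node order."""
        return nx.to_numpy_array(self.graph, nodelist=self.nodes, dtype=np.float64)


@dataclass
class DistanceBundle:
    """All-pairs shortest-path structure shared by every distance-based measure.

    ``sigma`` holds the distance degrees (row sums of the distance matrix),
    ``ecc`` the eccentricities, ``wiener`` the Wiener sum over unordered pairs
    and ``pair_distance_counts`` g_k, the number of unordered pairs at
    distance k.
    """

    d: np.ndarray
    sigma: np.ndarray = field(init=False)
    ecc: np.ndarray = field(init=False)
    wiener: float = field(init=False)

    def __post_init__(self) -> None:
        d = self.d
        if not np.isfinite(d).all():
            raise ValidationError("disconnected: infinite distances present")
        self.sigma = d.sum(axis=1)
        self.ecc = d.max(axis=1) if d.shape[0] > 1 else np.zeros(1)
        self.wiener = float(d.sum()) / 2.0

    @property
    def n(self) -> int:
        return self.d.shape[0]

    @property
    def pair_distance_counts(self) -> dict[int, int]:
        """g_k: unordered node pairs at each distance k >= 1."""
        iu = np.triu_indices(self.n, k=1)
        vals, counts = np.unique(self.d[iu].astype(np.int64), return_counts=True)
        return {int(k): int(c) for k, c in zip(vals, counts)}

    def layer_counts(self, i: int) -> np.ndarray:
        """n_k^i: number of nodes at each distance k = 0..ecc_i from node i."""
        row = self.d[i].astype(np.int64)
        return np.bincount(row)


def validate_graph(g: nx.Graph) -> None:
    """Check the structural invariants of a morphological network."""
    if g.number_of_nodes() < 2:
        raise ValidationError("network must have at least 2 nodes")
    if any(g.has_edge(v, v) for v in g.nodes):
        raise ValidationError("self-loop detected")
    if not nx.is_connected(g):
        sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
        raise ValidationError(f"disconnected: component sizes {sizes}")


def _parse_matrix(rows: list[list[str]], name: str) -> tuple[list[str], np.ndarray]:
    header = rows[0][1:]
    labels = [r[0] for r in rows[1:]]
    if header != labels:
        raise ValidationError(
            f"{name}: row labels do not match column labels"
        )
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"{name}: duplicate labels {dupes}")
    n = len(labels)
    cells = np.empty((n, n), dtype=np.int64)
    for i, r in enumerate(rows[1:]):
        if len(r) - 1 != n:
            raise ValidationError(f"{name}: row {labels[i]!r} has {len(r) - 1} cells, expected {n}")
        for j, cell in enumerate(r[1:]):
            s = cell.strip()
            if s not in ("0", "1"):
                raise ValidationError(
                    f"{name}: value error at ({labels[i]!r}, {header[j]!r}): {cell!r} is not 0/1"
                )
            cells[i, j] = int(s)
    return labels, cells


def matrix_to_network(labels: Sequence[str], cells: np.ndarray, name: str = "network",
                      annotations: Mapping[str, str] | None = None) -> MorphNetwork:
    """Validate a labeled 0/1 matrix and build the corresponding network."""
    cells = np.asarray(cells)
    n = len(labels)
    if cells.shape != (n, n):
        raise ValidationError(f"{name}: matrix shape {cells.shape} does not match {n} labels")
    if len(set(labels)) != n:
        dupes = sorted({x for x in labels if list(labels).count(x) > 1})
        raise ValidationError(f"{name}: duplicate labels {dupes}")
    bad = ~np.isin(cells, (0, 1))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"{name}: value error at ({labels[i]!r}, {labels[j]!r}): {cells[i, j]!r} is not 0/1"
        )
    asym = cells != cells.T
    if asym.any():
        i, j = map(int, np.argwhere(asym)[0])
        raise ValidationError(
            f"{name}: asymmetry at cell pair ({labels[i]!r}, {labels[j]!r})"
        )
    diag = np.diagonal(cells)
    if diag.any():
        i = int(np.argwhere(diag)[0][0])
        raise ValidationError(f"{name}: self-loop on node {labels[i]!r}")
    g = nx.Graph()
    g.add_nodes_from(labels)
    ii, jj = np.nonzero(np.triu(cells, k=1))
    g.add_edges_from((labels[a], labels[b]) for a, b in zip(ii, jj))
    ann = dict(annotations) if annotations is not None else None
    return MorphNetwork(name=name, graph=g, annotations=ann)


def read_adjacency_csv(path: str | Path, name: str | None = None,
                       delimiter: str = ",") -> MorphNetwork:
    """Read a labeled symmetric 0/1 adjacency matrix from CSV.

    The first row and first column carry identical unit labels; the body is
    0/1. ``delimiter=';'`` accepts semicolon-delimited variants. Raises
    :class:`ValidationError` for asymmetry, self-loops, non-binary cells,
    duplicate labels or a disconnected graph.
    """
    path = Path(path)
    net_name = name if name is not None else path.stem
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delimiter) if r]
    if len(rows) < 3:
        raise ValidationError(f"{net_name}: matrix too small (need at least 2 nodes)")
    labels, cells = _parse_matrix(rows, net_name)
    return matrix_to_network(labels, cells, name=net_name)


def write_adjacency_csv(net: MorphNetwork, path: str | Path, delimiter: str = ",") -> None:
    """Write the labeled adjacency matrix back to CSV (round-trip inverse)."""
    labels = net.nodes
    a = net.adjacency().astype(np.int64)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow([""] + labels)
        for lab, row in zip(labels, a):
            w.writerow([lab] + [str(int(x)) for x in row])


def read_annotations_csv(path: str | Path) -> dict[str, str]:
    """Read a two-column (label, region) node-annotation table."""
    out: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh):
            if not row or row[0].lower() in ("label", "node"):
                continue
            out[row[0]] = row[1].strip()
    return out


def write_graphml(net: MorphNetwork, path: str | Path) -> None:
    """Export as standard GraphML with labels and regions as node attributes."""
    g = nx.Graph()
    for v in net.nodes:
        attrs = dict(net.graph.nodes[v])  # carry user-set node attributes
        attrs["label"] = v
        if net.annotations is not None:
            attrs["region"] = net.annotations.get(v, "other")
        g.add_node(v, **attrs)
    g.add_edges_from(net.graph.edges)
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path, name: str | None = None) -> MorphNetwork:
    g = nx.read_graphml(str(path))
    ann = {v: d["region"] for v, d in g.nodes(data=True) if "region" in d}
    clean = nx.Graph()
    clean.add_nodes_from(g.nodes)
    clean.add_edges_from(g.edges)
    return MorphNetwork(name=name or Path(path).stem, graph=clean,
                        annotations=ann or None)


def distance_bundle(net: MorphNetwork) -> DistanceBundle:
    """Breadth-first all-pairs shortest-path distances for a connected network."""
    a = csr_matrix(net.adjacency())
    ncomp, _ = connected_components(a, directed=False)
    if ncomp > 1:
        raise ValidationError("disconnected: distances undefined")
    d = shortest_path(a, method="D", directed=False, unweighted=True)
    return DistanceBundle(d=d)
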