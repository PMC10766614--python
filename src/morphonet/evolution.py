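"""Branch ordering, bifurcation-pattern classification and EDP summaries.

The first split of the Ward dendrogram defines two evolutionary branches.
Ordering each branch from the root split outward ("center-out") yields the
12-slot display layout in which measure profiles are read: a measure whose
value is minimal at the center and increases outward along both branches
shows an *ascending bifurcation*; maximal at the center and decreasing,
a *descending bifurcation*. The classifier operationalizes those visual
patterns with a per-branch Spearman rank correlation against the center-out
position, so any strictly monotone transform of the values gives the same
call.

The evolutionary developmental potential (EDP) of anatomical regions is
summarized by concentrating an influence-type centrality (typically
eigenvector) per region: the axis-concentration ratio (axis mean over
whole-network mean) and the cephalization ratio (head-shield mean over axis
mean) quantify where in the body the potential resides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import spearmanr

from .centrality import CentralityResult
from .core_model import MorphNetwork, REGION_LABELS
from .multivariate import HCAResult


@dataclass
class BranchOrdering:
    """Center-out orderings of the two root branches.

    ``left`` (the large branch) and ``right`` are ordered from the root split
    outward; ``display_order`` is left reversed followed by right — the
    left-to-right layout used for profile plots.
    """

    left: list[str]
    right: list[str]

    @property
    def display_order(self) -> list[str]:
        return list(reversed(self.left)) + list(self.right)


def _center_out(node, labels: list[str]) -> list[str]:
    """Order the leaves of a subtree from the root split outward.

    At each internal node the child with more leaves continues the branch
    "spine" (stays toward the center); ties go to the child merged at the
    lower height, then to the lexicographically smaller leaf set. Leaves that
    join the spine at lower heights therefore sit closer to the center.
    """
    if node.is_leaf():
        return [labels[node.id]]
    a, b = node.left, node.right
    key_a = (-a.get_count(), a.dist, min(_leaf_labels(a, labels)))
    key_b = (-b.get_count(), b.dist, min(_leaf_labels(b, labels)))
    inner, outer = (a, b) if key_a <= key_b else (b, a)
    return _center_out(inner, labels) + _center_out(outer, labels)


def _leaf_labels(node, labels: list[str]) -> list[str]:
    return [labels[i] for i in node.pre_order(lambda n: n.id) if i < len(labels)]


def branch_ordering(tree: HCAResult,
                    sizes: Mapping[str, float] | None = None) -> BranchOrdering:
    """Split the dendrogram at its root and order each branch center-out.

    ``sizes`` (network name -> node count) disambiguates which branch is the
    "left or large" one: the branch with the larger mean node count. Without
    sizes, the branch with more leaves (then lexicographic) is labeled left.
    """
    root = hierarchy.to_tree(tree.linkage)
    if root.is_leaf() or root.left is None or root.right is None:
        raise ValueError("tree root is not a bifurcation")
    branches = []
    for child in (root.left, root.right):
        order = _center_out(child, tree.labels)
        branches.append(order)
    if sizes is not None:
        means = [float(np.mean([sizes[x] for x in b])) for b in branches]
        left_ix = int(np.argmax(means))
    else:
        counts = [len(b) for b in branches]
        if counts[0] != counts[1]:
            left_ix = int(np.argmax(counts))
        else:
            left_ix = 0 if min(branches[0]) < min(branches[1]) else 1
    left = branches[left_ix]
    right = branches[1 - left_ix]
    return BranchOrdering(left=left, right=right)


@dataclass
class BifurcationCall:
    """Trend classification of one measure profile over the two branches."""

    measure: str
    rho_left: float
    rho_right: float
    label: str  # ascending | descending | mixed
    tau: float


def classify_bifurcation(values: Mapping[str, float], ordering: BranchOrdering,
                         tau: float = 0.3, measure: str = "measure") -> BifurcationCall:
    """Spearman rho of value vs center-out rank within each branch.

    ascending iff both rhos >= tau; descending iff both <= -tau; otherwise
    mixed. A branch that is entirely tied yields an undefined rho, reported
    as 0 with a warning.
    """

    def branch_rho(branch: Sequence[str]) -> float:
        v = np.array([values[name] for name in branch], dtype=float)
        ranks = np.arange(1, len(branch) + 1)
        if np.allclose(v, v[0]):
            warnings.warn(f"{measure}: branch values all tied; trend undefined",
                          UserWarning, stacklevel=3)
            return 0.0
        rho = spearmanr(ranks, v).statistic
        return float(rho)

    rho_l = branch_rho(ordering.left)
    rho_r = branch_rho(ordering.right)
    if rho_l >= tau and rho_r >= tau:
        label = "ascending"
    elif rho_l <= -tau and rho_r <= -tau:
        label = "descending"
    else:
        label = "mixed"
    return BifurcationCall(measure=measure, rho_left=rho_l, rho_right=rho_r,
                           label=label, tau=tau)


def classify_table(table: pd.DataFrame, ordering: BranchOrdering,
                   tau: float = 0.3) -> pd.DataFrame:
    """Bifurcation calls for every column of a networks x measures table."""
    rows = []
    for col in table.columns:
        call = classify_bifurcation(table[col].to_dict(), ordering, tau=tau,
                                    measure=col)
        rows.append({"measure": call.measure, "rho_left": call.rho_left,
                     "rho_right": call.rho_right, "label": call.label})
    return pd.DataFrame(rows).set_index("measure")


@dataclass
class EDPSummary:
    """Anatomical-region summary of one centrality index."""

    region_means: dict[str, float]
    concentration_ratio: float   # axis mean / whole-network mean
    cephalization_ratio: float   # head_shield mean / axis mean (nan if no shield)


def edp_summary(net: MorphNetwork, cent: CentralityResult,
                annotations: Mapping[str, str] | None = None) -> EDPSummary:
    """Per-region centrality means plus concentration/cephalization ratios."""
    ann = annotations if annotations is not None else net.annotations
    if ann is None:
        raise ValueError("no node annotations available")
    missing = [v for v in net.nodes if v not in ann]
    if missing:
        raise ValueError(f"unannotated nodes: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    vals = cent.as_mapping(net)
    region_means: dict[str, float] = {}
    for region in REGION_LABELS:
        members = [v for v in net.nodes if ann[v] == region]
        if members:
            region_means[region] = float(np.mean([vals[v] for v in members]))
    overall = float(np.mean(list(vals.values())))
    axis_mean = region_means.get("axis", np.nan)
    concentration = axis_mean / overall if overall != 0 else np.nan
    shield_mean = region_means.get("head_shield", np.nan)
    cephalization = shield_mean / axis_mean if axis_mean else np.nan
    return EDPSummary(region_means=region_means,
                      concentration_ratio=float(concentration),
                      cephalization_ratio=float(cephalization))
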