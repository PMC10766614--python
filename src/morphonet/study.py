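"""Reproduction harness for the original 12-network arthropod study.

The study deposited its adjacency matrices as supplementary data; this
module runs the full pipeline against a local directory of those files
(one labeled CSV per group, named ``<Group>.csv``). The printed reference
values — per-network node counts, the center-out display ordering and the
published PCA/HCA summary statistics — are recorded here as inputs for
comparison.

Because the original descriptor variants and the PCA scaling convention are
not fully specified in print, :func:`reproduce` reports both scaled and
unscaled PCA modes side by side.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core_model import read_adjacency_csv
from .descriptors import measure_table
from .evolution import BranchOrdering, classify_table
from .multivariate import hca, pca

#: Published node counts per group.
STUDY_NODE_COUNTS: dict[str, int] = {
    "Canadaspis": 601, "Waptia": 276, "Yohoia": 457, "Olenoides": 297,
    "Marrella": 569, "Martinssonia": 250, "Rehbachiella": 747,
    "Branchinecta": 288, "Triops": 929, "Lightiella": 383,
    "Speleonectes": 624, "Nebalia": 376,
}

#: Published center-out branch orderings (left/large and right/small branch).
STUDY_LEFT_BRANCH: tuple[str, ...] = (
    "Yohoia", "Canadaspis", "Triops", "Rehbachiella", "Marrella", "Speleonectes")
STUDY_RIGHT_BRANCH: tuple[str, ...] = (
    "Branchinecta", "Waptia", "Olenoides", "Martinssonia", "Nebalia", "Lightiella")

#: Published multivariate summary statistics.
STUDY_PCA_DIM1_PCT = 60.6
STUDY_PCA_DIM3_PCT = 12.2
STUDY_PCA_FIRST3_PCT = 90.6
STUDY_COPHENETIC_CORRELATION = 0.685


def study_ordering() -> BranchOrdering:
    return BranchOrdering(left=list(STUDY_LEFT_BRANCH),
                          right=list(STUDY_RIGHT_BRANCH))


def load_study_networks(data_dir: str | Path):
    """Load the supplementary adjacency matrices from ``data_dir``.

    Expects one ``<Group>.csv`` per study group; raises ``FileNotFoundError``
    listing what is missing.
    """
    data_dir = Path(data_dir)
    missing = [g for g in STUDY_NODE_COUNTS if not (data_dir / f"{g}.csv").exists()]
    if missing:
        raise FileNotFoundError(
            f"study adjacency matrices not found under {data_dir}: missing {missing}")
    return [read_adjacency_csv(data_dir / f"{g}.csv", name=g)
            for g in STUDY_NODE_COUNTS]


@dataclass
class StudyReproduction:
    table: pd.DataFrame
    pca_scaled_pct: list[float]
    pca_unscaled_pct: list[float]
    cophenetic_correlation: float
    bifurcation_calls: pd.DataFrame


def reproduce(data_dir: str | Path, tau: float = 0.3) -> StudyReproduction:
    """Run the full battery + PCA + HCA + bifurcation calls on the study data."""
    nets = load_study_networks(data_dir)
    table = measure_table(nets)
    p_scaled = pca(table, scale=True)
    p_raw = pca(table, scale=False)
    tree = hca(table, k=4, scale=True)
    calls = classify_table(table, study_ordering(), tau=tau)
    return StudyReproduction(
        table=table,
        pca_scaled_pct=list(p_scaled.variance_explained),
        pca_unscaled_pct=list(p_raw.variance_explained),
        cophenetic_correlation=tree.cophenetic_correlation,
        bifurcation_calls=calls,
    )
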