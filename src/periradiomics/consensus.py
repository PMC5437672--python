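"""Subsampled hierarchical consensus clustering and cluster-label accuracy.

For each of ``n_iterations`` runs, 80% of patients are drawn without
replacement, hierarchically clustered (average linkage) under the Pearson
correlation distance between patient feature vectors, and cut at k
clusters; the consensus between two patients is the fraction of their
co-sampled runs in which they landed in the same cluster.  The final
assignment is obtained by hierarchically clustering 1 - consensus at k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .features import FeatureTable


@dataclass(frozen=True)
class ConsensusConfig:
    k: int = 2
    n_iterations: int = 1000
    subsample_fraction: float = 0.80
    linkage_method: str = "average"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class ConsensusMatrix:
    consensus: np.ndarray
    cosample_counts: np.ndarray
    final_assignment: np.ndarray
    patient_ids: list


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson correlation distances between rows.

    Rows with zero variance have undefined correlation; their pairwise
    distances are set to 1 with a warning.
    """
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} constant feature vectors; distance set to 1")
    Z = (X - X.mean(axis=1, keepdims=True)) / np.where(degenerate, 1.0, sd)[:, None]
    corr = (Z @ Z.T) / X.shape[1]
    dist = 1.0 - corr
    dist[degenerate, :] = 1.0
    dist[:, degenerate] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return squareform(dist, checks=False)


def consensus_cluster(table: FeatureTable, config: ConsensusConfig) -> ConsensusMatrix:
    """Consensus matrix and final assignment for a (restricted) feature table."""
    X = table.values
    n = X.shape[0]
    if n < config.k + 1:
        raise ValueError("need at least k + 1 patients")
    rng = np.random.default_rng(config.seed)
    n_sub = max(int(np.floor(config.subsample_fraction * n)), config.k)

    together = np.zeros((n, n))
    cosampled = np.zeros((n, n))
    for _ in range(config.n_iterations):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        d = _pearson_distance(X[idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy warns on non-Euclidean input
            Z = linkage(d, method=config.linkage_method)
        labels = fcluster(Z, t=config.k, criterion="maxclust")
        same = labels[:, None] == labels[None, :]
        cosampled[np.ix_(idx, idx)] += 1
        together[np.ix_(idx, idx)] += same

    with np.errstate(divide="ignore", invalid="ignore"):
        consensus = np.where(cosampled > 0, together / np.where(cosampled > 0, cosampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    final_d = squareform(1.0 - consensus, checks=False)
    Zf = linkage(final_d, method=config.linkage_method)
    final = fcluster(Zf, t=config.k, criterion="maxclust")
    return ConsensusMatrix(
        consensus=consensus,
        cosample_counts=cosampled,
        final_assignment=final,
        patient_ids=list(table.df.index),
    )


def cluster_label_accuracy(assignment: np.ndarray, labels: np.ndarray) -> dict:
    """Per-class clustering accuracy against ground-truth labels.

    Each true class is matched to the cluster holding most of its members;
    the accuracy of a class is the fraction of its members in that cluster.
    Invariant under permutation of cluster ids.
    """
    assignment = np.asarray(assignment)
    labels = np.asarray(labels)
    if assignment.shape != labels.shape:
        raise ValueError("assignment and labels must align")
    out = {}
    for cls in np.unique(labels):
        members = assignment[labels == cls]
        clusters, counts = np.unique(members, return_counts=True)
        out[str(cls)] = float(counts.max() / members.size)
    return out


def plot_consensus_heatmap(matrix: ConsensusMatrix, path) -> None:
    """Render the consensus matrix (patients ordered by final assignment)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(matrix.final_assignment, kind="stable")
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(matrix.consensus[np.ix_(order, order)], vmin=0, vmax=1, cmap="Blues")
    ax.set_xlabel("patients")
    ax.set_ylabel("patients")
    fig.colorbar(im, ax=ax, label="consensus")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
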