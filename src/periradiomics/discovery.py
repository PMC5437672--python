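"""Iterated cross-validated mRMR feature discovery.

Two-stage protocol: (1) greedy mRMR (mutual-information difference
criterion, MID) selects 10 features on each fold-training set across
repeated stratified 3-fold cross-validation; features are ranked by
selection frequency pooled over all fold-runs and the bottom 90% are
eliminated.  (2) the same cross-validated selection is repeated within the
retained set, features are re-ranked by frequency, features highly
correlated (|Pearson r| above a threshold) with a higher-ranked keeper are
greedily dropped, and the list is truncated to a cap of 10.  An optional
per-iteration downsampling of the majority class counteracts selection bias
in strongly imbalanced groups.

Mutual information is estimated on 10-bin quantile-discretized features
(rank-based, so monotone feature transforms do not change the selection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .features import FeatureTable


@dataclass(frozen=True)
class DiscoveryConfig:
    n_select_per_run: int = 10
    n_iterations: int = 200
    n_folds: int = 3
    retain_fraction: float = 0.10
    redundancy_r_threshold: float = 0.90
    cap: int = 10
    downsample_majority_to: int | None = None
    n_bins: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.retain_fraction < 1.0:
            raise ValueError("retain_fraction must be in (0, 1)")
        if self.cap > self.n_select_per_run:
            raise ValueError("cap must be <= n_select_per_run")


@dataclass
class DiscoveryResult:
    top_features: list[str]
    stage1_retained: list[str]
    stage1_frequency: dict[str, int]
    stage2_frequency: dict[str, int]
    n_fold_runs: int
    truncated_below_cap: bool = False


def _quantile_bins(X: np.ndarray, n_bins: int) -> np.ndarray:
    """Column-wise quantile discretization to integer bins 0..n_bins-1."""
    n = X.shape[0]
    ranks = rankdata(X, axis=0, method="average")
    bins = np.floor((ranks - 0.5) / n * n_bins).astype(np.int64)
    return np.clip(bins, 0, n_bins - 1)


def _mi_against_vector(binsX: np.ndarray, v: np.ndarray, n_bins: int, nv: int) -> np.ndarray:
    """MI (nats) of every column of ``binsX`` against integer vector ``v``."""
    n, F = binsX.shape
    joint_idx = (np.arange(F)[None, :] * (n_bins * nv) + binsX * nv + v[:, None]).ravel()
    counts = np.bincount(joint_idx, minlength=F * n_bins * nv).astype(float)
    pxy = counts.reshape(F, n_bins, nv) / n
    px = pxy.sum(axis=2, keepdims=True)
    py = pxy.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = pxy * (np.log(pxy) - np.log(px) - np.log(py))
    return np.where(pxy > 0, term, 0.0).sum(axis=(1, 2))


def mrmr_rank(
    X: np.ndarray | FeatureTable,
    labels: np.ndarray,
    k: int,
    n_bins: int = 10,
) -> tuple[list[int], np.ndarray]:
    """Greedy mRMR (MID) ranking of feature columns.

    The first feature maximizes mutual information with the labels; each
    subsequent pick maximizes relevance minus mean redundancy against the
    already-selected set.  Returns (selected column indices in order,
    per-selection mRMR scores).
    """
    if isinstance(X, FeatureTable):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("feature matrix must have at least one column")
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels must contain two classes")
    y_codes = np.searchsorted(classes, y)
    n, F = X.shape
    k = min(k, F)
    bins = _quantile_bins(X, n_bins)

    relevance = _mi_against_vector(bins, y_codes, n_bins, classes.size)
    red_sum = np.zeros(F)
    selected: list[int] = []
    scores: list[float] = []
    available = np.ones(F, dtype=bool)
    for step in range(k):
        if step == 0:
            crit = relevance.copy()
        else:
            red_sum += _mi_against_vector(bins, bins[:, selected[-1]], n_bins, n_bins)
            crit = relevance - red_sum / step
        crit[~available] = -np.inf
        j = int(np.argmax(crit))
        selected.append(j)
        scores.append(float(crit[j]))
        available[j] = False
    return selected, np.asarray(scores)


def prune_redundant(
    ranked: list[str], table: FeatureTable, r_threshold: float
) -> list[str]:
    """Greedy top-down retention dropping features with |Pearson r| >=
    threshold against any higher-ranked kept feature."""
    if not ranked:
        raise ValueError("ranked feature list is empty")
    X = table.df[ranked].to_numpy()
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    kept: list[int] = []
    for j in range(len(ranked)):
        redundant = False
        for i in kept:
            r = np.abs(np.mean(Z[:, i] * Z[:, j]))
            if r >= r_threshold:
                redundant = True
                break
        if not redundant:
            kept.append(j)
    return [ranked[j] for j in kept]


def _cv_selection_counts(
    X: np.ndarray,
    y: np.ndarray,
    config: DiscoveryConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled selection counts and score sums over iterations x folds."""
    n, F = X.shape
    counts = np.zeros(F, dtype=int)
    score_sums = np.zeros(F)
    n_runs = 0
    for _ in range(config.n_iterations):
        idx = np.arange(n)
        if config.downsample_majority_to is not None:
            vals, cnts = np.unique(y, return_counts=True)
            majority = vals[np.argmax(cnts)]
            maj_idx = idx[y == majority]
            min_idx = idx[y != majority]
            if maj_idx.size > config.downsample_majority_to:
                maj_idx = rng.choice(maj_idx, size=config.downsample_majority_to, replace=False)
            idx = np.concatenate([min_idx, maj_idx])
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        for train_pos, _ in skf.split(idx.reshape(-1, 1), y[idx]):
            tr = idx[train_pos]
            sel, sc = mrmr_rank(X[tr], y[tr], config.n_select_per_run, config.n_bins)
            sel = np.asarray(sel, dtype=int)
            counts[sel] += 1
            score_sums[sel] += sc
            n_runs += 1
    return counts, score_sums, n_runs


def _rank_by_frequency(
    names: list[str], counts: np.ndarray, score_sums: np.ndarray
) -> list[int]:
    """Indices sorted by (frequency desc, mean score desc, name asc)."""
    mean_scores = np.where(counts > 0, score_sums / np.maximum(counts, 1), -np.inf)
    order = sorted(
        range(len(names)), key=lambda j: (-counts[j], -mean_scores[j], names[j])
    )
    return order


def discovery_protocol(
    table: FeatureTable, labels: np.ndarray, config: DiscoveryConfig
) -> DiscoveryResult:
    """Two-stage cross-validated mRMR discovery yielding <= ``cap`` features."""
    names = table.columns
    X = table.values
    y = np.asarray(labels)
    F = len(names)

    rng = np.random.default_rng(config.seed)
    counts1, scores1, n_runs = _cv_selection_counts(X, y, config, rng)
    order1 = _rank_by_frequency(names, counts1, scores1)
    n_retain = int(np.ceil(config.retain_fraction * F))
    retained_idx = order1[:n_retain]
    retained = [names[j] for j in retained_idx]

    X2 = X[:, retained_idx]
    counts2, scores2, _ = _cv_selection_counts(X2, y, config, rng)
    order2 = _rank_by_frequency(retained, counts2, scores2)
    ranked2 = [retained[j] for j in order2]

    pruned = prune_redundant(ranked2, table, config.redundancy_r_threshold)
    top = pruned[: config.cap]
    return DiscoveryResult(
        top_features=top,
        stage1_retained=retained,
        stage1_frequency={names[j]: int(counts1[j]) for j in order1 if counts1[j] > 0},
        stage2_frequency={retained[j]: int(counts2[j]) for j in order2 if counts2[j] > 0},
        n_fold_runs=n_runs,
        truncated_below_cap=len(pruned) < config.cap,
    )
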