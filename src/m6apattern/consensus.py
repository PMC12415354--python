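"""Subsampling consensus clustering of expression profiles.

The procedure repeatedly subsamples the cohort, clusters each subsample
hierarchically (average linkage on 1 - Pearson correlation across the
chosen feature genes), and records how often each sample pair lands in
the same cluster among the iterations in which both were drawn.  The
resulting consensus matrix drives both the final cluster assignment and
the choice of k via the delta-area elbow of the consensus CDF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import accuracy_score, adjusted_rand_score
from sklearn.neighbors import NearestCentroid

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)


def _correlation_distance(X: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson correlation between rows of X."""
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((Xc ** 2).sum(axis=1))
    sd[sd == 0] = 1.0
    corr = (Xc @ Xc.T) / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    d = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def _hier_labels(D: np.ndarray, k: int, linkage_method: str = "average") -> np.ndarray:
    """Cut an agglomerative dendrogram of a distance matrix at k clusters."""
    if D.shape[0] <= k:
        return np.arange(D.shape[0])
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage_method)
    return hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1


def base_cluster(X: np.ndarray, k: int, metric: str = "correlation",
                 linkage_method: str = "average") -> np.ndarray:
    """Single agglomerative clustering of samples (rows of X)."""
    if metric == "correlation":
        D = _correlation_distance(X)
    elif metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt((diff ** 2).sum(-1))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return _hier_labels(D, k, linkage_method)


@dataclass
class ConsensusResult:
    """Consensus clustering output for one k (plus per-k selection curves)."""

    consensus_matrix: np.ndarray          # samples x samples in [0, 1]
    labels: np.ndarray                    # per-sample cluster id at chosen_k
    chosen_k: int
    k_range: list[int]
    cdf_areas: dict[int, float]           # area under consensus CDF per k
    delta_areas: dict[int, float]         # relative delta-area per k
    per_k_labels: dict[int, np.ndarray]
    per_k_matrices: dict[int, np.ndarray]
    n_iterations: int
    subsample_fraction: float
    sample_ids: list = field(default_factory=list)
    never_cosampled_pairs: int = 0


def _consensus_matrix_for_k(X, k, n_iter, frac, rng, metric, linkage_method):
    n = X.shape[0]
    m = max(2, int(np.ceil(frac * n)))
    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(n_iter):
        idx = np.sort(rng.choice(n, size=m, replace=False)) if m < n else np.arange(n)
        labels = base_cluster(X[idx], k, metric, linkage_method)
        same = labels[:, None] == labels[None, :]
        co_sample[np.ix_(idx, idx)] += 1.0
        co_cluster[np.ix_(idx, idx)] += same
    never = co_sample == 0
    n_never = int((never.sum() - never.trace()) // 2)
    if n_never:
        logger.warning("%d sample pair(s) were never co-sampled; consensus set to 0", n_never)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(never, 0.0, co_cluster / np.maximum(co_sample, 1))
    np.fill_diagonal(M, 1.0)
    M = (M + M.T) / 2.0
    return M, n_never


def consensus_cdf_area(M: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus entries.

    Left-Riemann sum over the sorted distinct entries: for values
    x_1 < ... < x_m, area = sum_i (x_i - x_{i-1}) * CDF(x_{i-1}).  A
    consensus matrix that is identically 1 off-diagonal has area 0.
    """
    n = M.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = np.sort(M[iu])
    xs, counts = np.unique(vals, return_counts=True)
    cdf = np.cumsum(counts) / counts.sum()
    if len(xs) < 2:
        return 0.0
    return float(np.sum(np.diff(xs) * cdf[:-1]))


def consensus_cluster(
    m: ExpressionMatrix,
    features,
    k_range=range(2, 7),
    n_iter: int = 2000,
    frac: float = 0.8,
    seed: int = 0,
    metric: str = "correlation",
    linkage_method: str = "average",
    delta_threshold: float = 0.05,
) -> ConsensusResult:
    """Consensus-cluster samples on the given feature genes over a k range.

    For each k, ``n_iter`` subsamples of ``ceil(frac * n)`` samples are
    clustered and aggregated into a consensus matrix; the final labels
    come from clustering 1 - M at the selected k.
    """
    features = [f for f in features if f in m.gene_ids]
    if not features:
        raise ValueError("none of the requested feature genes are in the matrix")
    sub = m.values.loc[features]
    keep = sub.std(axis=1) > 0
    dropped = [g for g, k_ in zip(sub.index, keep) if not k_]
    if dropped:
        logger.warning("dropping %d constant feature(s): %s", len(dropped), dropped[:5])
    sub = sub.loc[keep]
    if sub.shape[0] == 0:
        raise ValueError("all features are constant across samples")
    X = sub.to_numpy().T  # samples x features
    n = X.shape[0]
    k_range = [int(k) for k in k_range]
    if min(k_range) < 2 or max(k_range) > n / 3:
        raise ValueError(f"k range must satisfy 2 <= k <= n/3 (n={n})")
    rng = np.random.default_rng(seed)

    per_k_M: dict[int, np.ndarray] = {}
    per_k_labels: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    total_never = 0
    for k in k_range:
        M, n_never = _consensus_matrix_for_k(X, k, n_iter, frac, rng, metric, linkage_method)
        total_never += n_never
        per_k_M[k] = M
        per_k_labels[k] = _hier_labels(1.0 - M, k, linkage_method)
        areas[k] = consensus_cdf_area(M)
    chosen_k, deltas = select_k(areas, delta_threshold)
    return ConsensusResult(
        consensus_matrix=per_k_M[chosen_k],
        labels=per_k_labels[chosen_k],
        chosen_k=chosen_k,
        k_range=k_range,
        cdf_areas=areas,
        delta_areas=deltas,
        per_k_labels=per_k_labels,
        per_k_matrices=per_k_M,
        n_iterations=n_iter,
        subsample_fraction=frac,
        sample_ids=list(m.sample_ids),
        never_cosampled_pairs=total_never,
    )


def select_k(cdf_areas: dict[int, float], delta_threshold: float = 0.05):
    """Delta-area elbow: largest k whose relative area gain is >= threshold.

    The smallest candidate k always qualifies (its 'gain' is the whole
    area).  If the CDF areas are identical across k the smallest k is
    returned with a warning.
    """
    ks = sorted(cdf_areas)
    if len(ks) < 2:
        return ks[0], {ks[0]: float("inf")}
    deltas: dict[int, float] = {ks[0]: float("inf")}
    for prev, k in zip(ks, ks[1:]):
        a_prev, a_k = cdf_areas[prev], cdf_areas[k]
        deltas[k] = (a_k - a_prev) / a_prev if a_prev > 0 else (np.inf if a_k > 0 else 0.0)
    if all(np.isclose(cdf_areas[k], cdf_areas[ks[0]]) for k in ks):
        logger.warning("identical consensus CDFs across k; returning smallest k")
        return ks[0], deltas
    chosen = ks[0]
    for k in ks[1:]:
        if deltas[k] >= delta_threshold:
            chosen = k
    return chosen, deltas


def cluster_stability_check(m: ExpressionMatrix, features, labels, seed: int = 0):
    """Split-half nearest-centroid validation of a clustering.

    A nearest-centroid classifier is fitted on a random half of the
    samples using the consensus labels and predicts the other half; the
    report gives ARI and accuracy of prediction vs. consensus assignment.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("stability check needs at least 2 clusters")
    features = [f for f in features if f in m.gene_ids]
    X = m.values.loc[features].to_numpy().T
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    train, test = perm[:half], perm[half:]
    # ensure every cluster is represented in training
    for lab in np.unique(labels):
        if lab not in labels[train]:
            extra = np.nonzero(labels[test] == lab)[0][:1]
            train = np.concatenate([train, test[extra]])
            test = np.delete(test, extra)
    clf = NearestCentroid()
    clf.fit(X[train], labels[train])
    pred = clf.predict(X[test])
    return {
        "ari": float(adjusted_rand_score(labels[test], pred)),
        "accuracy": float(accuracy_score(labels[test], pred)),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
    }
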