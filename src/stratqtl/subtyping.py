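"""Phenotypic subtyping of cases by K-means on item-severity profiles.

Cases are partitioned with Lloyd's algorithm on the individuals x items
severity matrix using a missing-aware squared Euclidean distance

    d(x, c) = (P / |O|) * sum_{i in O} (x_i - c_i)^2,

where P is the number of items and O the items observed for that
individual — the scaling keeps sparsely scored individuals comparable to
fully scored ones without imputing.  Centroids are per-cluster means over
observed entries.  The number of clusters is chosen by a leave-one-item-out
figure-of-merit curve, and a PCA projection (column-mean imputation) is
provided to verify that the clusters separate.  Clusters are named by rank
of mean severity; with K = 4 the conventional labels are, from most to
least severe, "Language-impaired", "Intermediate", "Moderate", "Mild".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

#: severity-rank cluster names used when K = 4 (most to least severe)
K4_NAMES = ("Language-impaired", "Intermediate", "Moderate", "Mild")


@dataclass
class SubtypeAssignment:
    """Result of clustering: labels, centroids, objective, optional names."""

    k: int
    labels: pd.Series  # case id -> cluster index
    centroids: np.ndarray  # K x n_items
    inertia: float
    objective_history: list[float] = field(default_factory=list)
    names: dict[int, str] | None = None

    def named_labels(self) -> pd.Series:
        if self.names is None:
            raise ValueError("clusters have not been named; call name_clusters")
        return self.labels.map(self.names)

    def cluster_sizes(self) -> dict[int, int]:
        return self.labels.value_counts().sort_index().to_dict()


def _distances(x0: np.ndarray, obs: np.ndarray, n_obs: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Missing-aware scaled squared distances, shape (n_cases, K).

    ``x0`` is the data with missing entries zeroed, ``obs`` the observation
    mask, ``n_obs`` the per-row observed count.
    """
    n, p = x0.shape
    k = centroids.shape[0]
    d = np.empty((n, k))
    for j in range(k):
        diff = x0 - centroids[j]
        d[:, j] = np.einsum("ij,ij->i", diff * obs, diff)
    return d * (p / n_obs)[:, None]


def _update_centroids(
    x0: np.ndarray, obs: np.ndarray, labels: np.ndarray, k: int, previous: np.ndarray
) -> np.ndarray:
    """Per-cluster, per-item means over observed entries.

    An item with no observed value in a cluster keeps its previous centroid
    coordinate.
    """
    centroids = previous.copy()
    for j in range(k):
        members = labels == j
        if not members.any():
            continue
        counts = obs[members].sum(axis=0)
        sums = (x0[members] * obs[members]).sum(axis=0)
        seen = counts > 0
        centroids[j, seen] = sums[seen] / counts[seen]
    return centroids


def kmeans_cluster(
    matrix: pd.DataFrame,
    k: int = 4,
    n_restarts: int = 10,
    max_iter: int = 100,
    seed: int | None = None,
) -> SubtypeAssignment:
    """Lloyd K-means with missing-aware distance; best of ``n_restarts``.

    Each restart initialises centroids from ``k`` distinct data rows drawn
    uniformly, iterates assignment/update until the assignment is unchanged
    or ``max_iter`` is reached, and records the total within-cluster
    distance after each iteration (non-increasing).  If a cluster empties
    during iteration its centroid is re-seeded from the point farthest from
    its current centroid.

    Returns the restart with the lowest total within-cluster distance.
    """
    x = matrix.to_numpy(dtype=float)
    n, p = x.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k ({k}) exceeds number of cases ({n})")
    obs = ~np.isnan(x)
    n_obs = obs.sum(axis=1).astype(float)
    if (n_obs == 0).any():
        bad = matrix.index[n_obs == 0][0]
        raise ValueError(f"case {bad!r} has no observed items")
    x0 = np.where(obs, x, 0.0)

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(n_restarts):
        centroids = x0[rng.choice(n, size=k, replace=False)].copy()
        # seed centroids from rows: missing entries were zeroed, which is a
        # valid starting point; the first update replaces them with means
        labels = np.full(n, -1)
        history: list[float] = []
        for _ in range(max_iter):
            d = _distances(x0, obs, n_obs, centroids)
            new_labels = d.argmin(axis=1)
            for j in range(k):
                if not (new_labels == j).any():
                    farthest = d[np.arange(n), new_labels].argmax()
                    centroids[j] = x0[farthest]
                    d = _distances(x0, obs, n_obs, centroids)
                    new_labels = d.argmin(axis=1)
            history.append(float(d[np.arange(n), new_labels].sum()))
            if (new_labels == labels).all():
                break
            labels = new_labels
            centroids = _update_centroids(x0, obs, labels, k, centroids)
        d = _distances(x0, obs, n_obs, centroids)
        inertia = float(d[np.arange(n), labels].sum())
        if best is None or inertia < best[0]:
            best = (inertia, labels, centroids, history)

    inertia, labels, centroids, history = best
    return SubtypeAssignment(
        k=k,
        labels=pd.Series(labels, index=matrix.index),
        centroids=centroids,
        inertia=inertia,
        objective_history=history,
    )


def fom_curve(
    matrix: pd.DataFrame,
    k_range,
    seed: int | None = None,
    n_restarts: int = 3,
    max_iter: int = 50,
) -> list[tuple[int, float]]:
    """Leave-one-item-out figure of merit for each candidate K.

    For each left-out item e: cluster on the remaining items, then
    FOM(e) = sqrt(mean over cases of (x_e - mean of e in the case's
    cluster)^2), using observed entries of e.  FOM(K) = sum_e FOM(e),
    divided by the adjustment factor sqrt((n - K)/n) so that curves are
    comparable across K.  The elbow (minimum) estimates the number of
    distinct phenotypic profiles.
    """
    k_values = list(k_range)
    if not k_values:
        raise ValueError("k_range must be nonempty")
    n = len(matrix)
    if any(k >= n for k in k_values):
        raise ValueError("every K must be smaller than the number of cases")
    rng = np.random.default_rng(seed)
    curve = []
    for k in k_values:
        total = 0.0
        for e, item in enumerate(matrix.columns):
            rest = matrix.drop(columns=item)
            assignment = kmeans_cluster(
                rest,
                k=k,
                n_restarts=n_restarts,
                max_iter=max_iter,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            held = matrix[item].to_numpy(dtype=float)
            labels = assignment.labels.to_numpy()
            sq = 0.0
            n_seen = 0
            for j in range(k):
                vals = held[labels == j]
                vals = vals[~np.isnan(vals)]
                if len(vals) == 0:
                    continue
                sq += float(((vals - vals.mean()) ** 2).sum())
                n_seen += len(vals)
            if n_seen:
                total += np.sqrt(sq / n_seen)
        adjusted = total / np.sqrt((n - k) / n)
        curve.append((k, float(adjusted)))
    return curve


def select_k_elbow(curve: list[tuple[int, float]]) -> int:
    """Elbow of a FOM curve: the interior K with maximum discrete curvature.

    The figure of merit decreases monotonically in K on real data, so the
    optimal cluster count is where the improvement flattens — the K with
    the largest second difference of the curve.  Requires at least three
    points; with fewer, returns the K with the smallest FOM.
    """
    ks = [k for k, _ in curve]
    vs = np.array([v for _, v in curve])
    if len(ks) < 3:
        return ks[int(vs.argmin())]
    curvature = np.diff(np.diff(vs))
    return ks[1 + int(curvature.argmax())]


def pca_project(
    matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component coordinates of cases (column-mean imputation).

    Returns (coordinates DataFrame, explained-variance fractions), with
    components ordered by decreasing variance.
    """
    x = matrix.to_numpy(dtype=float)
    col_means = np.nanmean(x, axis=0)
    filled = np.where(np.isnan(x), col_means, x)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(filled)
    columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=matrix.index, columns=columns),
        pca.explained_variance_ratio_,
    )


def name_clusters(
    assignment: SubtypeAssignment, matrix: pd.DataFrame
) -> SubtypeAssignment:
    """Attach severity-rank names to clusters (most severe first).

    Clusters are ranked by mean severity over all observed entries of their
    member rows, descending, ties broken by cluster index.  With K = 4 the
    names are :data:`K4_NAMES`; otherwise "rank1".."rankK".
    """
    x = matrix.to_numpy(dtype=float)
    labels = assignment.labels.to_numpy()
    means = []
    for j in range(assignment.k):
        vals = x[labels == j]
        vals = vals[~np.isnan(vals)]
        means.append(vals.mean() if len(vals) else -np.inf)
    order = sorted(range(assignment.k), key=lambda j: (-means[j], j))
    name_list = (
        list(K4_NAMES)
        if assignment.k == 4
        else [f"rank{r + 1}" for r in range(assignment.k)]
    )
    names = {cluster: name_list[rank] for rank, cluster in enumerate(order)}
    return SubtypeAssignment(
        k=assignment.k,
        labels=assignment.labels,
        centroids=assignment.centroids,
        inertia=assignment.inertia,
        objective_history=assignment.objective_history,
        names=names,
    )
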