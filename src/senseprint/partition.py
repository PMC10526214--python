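"""Partitioning of a trained GSOM into clusters, and cluster validation.

The map's node weight vectors are clustered with K-means (k-means++
seeding, best of several restarts); participants inherit the cluster of
their best-matching unit.  Cluster quality is assessed with the
silhouette coefficient and Davies-Bouldin index computed at the
participant level, and cluster distinctiveness is confirmed with
pairwise Welch two-sample t-tests on the original instrument units.

Silhouette and Davies-Bouldin are implemented here rather than delegated
because the degenerate conventions matter for tiny maps: singleton
clusters and all-identical points contribute 0 to the silhouette
(0/0 := 0), and coincident centroids make the Davies-Bouldin ratio
undefined, which is reported as an explicit error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .gsom import GrowingSOM
from .preprocess import FeatureMatrix


class DegenerateClusteringError(ValueError):
    """A validation index is undefined for this clustering geometry."""


def _as_array(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    return np.asarray(getattr(features, "values", features), dtype=float)


def kmeans_nodes(
    som: GrowingSOM, k: int, seed: int = 0, restarts: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """K-means on the map's node weight vectors.

    Lloyd iterations with k-means++ seeding, best of ``restarts`` by
    within-cluster sum of squares; empty clusters are re-seeded to the
    farthest points.  Nodes are unweighted by hit count: the partition is
    of the map, not of the raw data.

    Returns ``(node_labels, centroids)``.
    """
    n_nodes = som.n_nodes_
    if not 2 <= k <= n_nodes:
        raise ValueError(f"k must lie in [2, {n_nodes}], got {k}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    node_labels = km.fit_predict(som.weights_)
    # exact member means (Lloyd's final relabel can leave centers one
    # half-step behind at tol-based early stops)
    centroids = np.array(
        [som.weights_[node_labels == c].mean(axis=0) for c in range(k)]
    )
    return node_labels, centroids


def assign_participants(
    som: GrowingSOM, node_labels: np.ndarray, features
) -> np.ndarray:
    """Give each participant the cluster label of its BMU."""
    node_labels = np.asarray(node_labels)
    if len(node_labels) != som.n_nodes_:
        raise ValueError(
            f"node_labels covers {len(node_labels)} nodes, map has {som.n_nodes_}"
        )
    bmus = som.predict(_as_array(features))
    return node_labels[bmus]


def silhouette_coefficient(features, labels) -> float:
    """Mean silhouette over points: (b - a) / max(a, b).

    ``a`` is the mean intra-cluster distance, ``b`` the smallest mean
    distance to another cluster.  Singleton points contribute 0, as does
    the 0/0 case of coincident points.
    """
    X = _as_array(features)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise DegenerateClusteringError("silhouette requires >= 2 clusters")
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    s = np.zeros(len(X))
    for i in range(len(X)):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton -> 0
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def davies_bouldin(features, labels) -> float:
    """Davies-Bouldin index: mean over clusters of max_j (s_i+s_j)/d_ij.

    ``s`` is the mean Euclidean distance of members to their centroid and
    ``d_ij`` the centroid separation.  Lower is better.  Raises
    :class:`DegenerateClusteringError` when two centroids coincide.
    """
    X = _as_array(features)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise DegenerateClusteringError("Davies-Bouldin requires >= 2 clusters")
    cents = np.array([X[labels == c].mean(axis=0) for c in uniq])
    scatter = np.array(
        [np.linalg.norm(X[labels == c] - cents[i], axis=1).mean() for i, c in enumerate(uniq)]
    )
    k = len(uniq)
    ratios = np.zeros(k)
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(cents[i] - cents[j])
            if d == 0:
                raise DegenerateClusteringError(
                    f"clusters {uniq[i]} and {uniq[j]} have coincident centroids"
                )
            worst = max(worst, (scatter[i] + scatter[j]) / d)
        ratios[i] = worst
    return float(ratios.mean())


def pairwise_t_tests(
    scores: pd.DataFrame, labels, equal_var: bool = False
) -> pd.DataFrame:
    """Welch two-sample t-tests for every cluster pair x feature.

    ``scores`` holds the analysed features in ORIGINAL instrument units
    (one column per feature).  Pairs where either cluster has fewer than
    two non-missing values are flagged ``testable=False`` rather than
    dropped.  No multiple-testing correction is applied; a Bonferroni
    column is provided for convenience.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    rows = []
    for ia, ca in enumerate(uniq):
        for cb in uniq[ia + 1 :]:
            for col in scores.columns:
                a = scores.loc[labels == ca, col].dropna().to_numpy(dtype=float)
                b = scores.loc[labels == cb, col].dropna().to_numpy(dtype=float)
                if len(a) < 2 or len(b) < 2:
                    rows.append(
                        dict(cluster_a=ca, cluster_b=cb, feature=col, testable=False,
                             t=np.nan, df=np.nan, p=np.nan)
                    )
                    continue
                res = stats.ttest_ind(a, b, equal_var=equal_var)
                rows.append(
                    dict(cluster_a=ca, cluster_b=cb, feature=col, testable=True,
                         t=float(res.statistic), df=float(res.df),
                         p=float(res.pvalue))
                )
    table = pd.DataFrame(rows)
    n_tests = int(table["testable"].sum())
    table["p_bonferroni"] = np.minimum(table["p"] * max(n_tests, 1), 1.0)
    return table


@dataclass
class ClusterSolution:
    """Everything the partition stage produces for one analysis."""

    k: int
    node_labels: np.ndarray
    participant_labels: pd.Series  # indexed by participant id
    centroids: np.ndarray  # node-weight-space centroids
    silhouette: float
    davies_bouldin: float
    ttest_table: pd.DataFrame | None = None


class GsomKMeans(ClusterMixin, BaseEstimator):
    """Two-stage clusterer: Growing SOM vector quantization, then K-means
    on the node codebook; samples inherit their BMU's cluster.

    Parameters mirror :class:`~senseprint.gsom.GrowingSOM` plus the
    cluster count ``n_clusters`` and K-means ``restarts``.

    Attributes
    ----------
    som_ : the fitted :class:`GrowingSOM`.
    node_labels_ : cluster id per map node.
    cluster_centers_ : K-means centroids in weight space.
    labels_ : cluster id per training sample.
    silhouette_, davies_bouldin_ : sample-level validation indices.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        spread_factor: float = 0.9,
        growing_epochs: int = 30,
        smoothing_epochs: int = 20,
        initial_learning_rate: float = 0.3,
        smoothing_learning_rate: float = 0.05,
        initial_radius: float = 3.0,
        error_distribution_factor: float = 0.5,
        restarts: int = 30,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.spread_factor = spread_factor
        self.growing_epochs = growing_epochs
        self.smoothing_epochs = smoothing_epochs
        self.initial_learning_rate = initial_learning_rate
        self.smoothing_learning_rate = smoothing_learning_rate
        self.initial_radius = initial_radius
        self.error_distribution_factor = error_distribution_factor
        self.restarts = restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        arr = _as_array(X)
        self.som_ = GrowingSOM(
            spread_factor=self.spread_factor,
            growing_epochs=self.growing_epochs,
            smoothing_epochs=self.smoothing_epochs,
            initial_learning_rate=self.initial_learning_rate,
            smoothing_learning_rate=self.smoothing_learning_rate,
            initial_radius=self.initial_radius,
            error_distribution_factor=self.error_distribution_factor,
            random_state=self.random_state,
        ).fit(arr)
        self.node_labels_, self.cluster_centers_ = kmeans_nodes(
            self.som_, self.n_clusters, seed=self.random_state, restarts=self.restarts
        )
        self.labels_ = assign_participants(self.som_, self.node_labels_, arr)
        try:
            self.silhouette_ = silhouette_coefficient(arr, self.labels_)
            self.davies_bouldin_ = davies_bouldin(arr, self.labels_)
        except DegenerateClusteringError:
            self.silhouette_ = np.nan
            self.davies_bouldin_ = np.nan
        return self

    def predict(self, X) -> np.ndarray:
        return self.node_labels_[self.som_.predict(_as_array(X))]

    def solution(self, features: FeatureMatrix, scores: pd.DataFrame | None = None) -> ClusterSolution:
        """Package the fitted clustering; optionally attach the Welch
        t-test table computed on instrument-unit ``scores``."""
        labels = pd.Series(self.labels_, index=features.participant_ids, name="cluster")
        ttable = None
        if scores is not None:
            ttable = pairwise_t_tests(scores.loc[features.participant_ids], self.labels_)
        return ClusterSolution(
            k=self.n_clusters,
            node_labels=self.node_labels_,
            participant_labels=labels,
            centroids=self.cluster_centers_,
            silhouette=self.silhouette_,
            davies_bouldin=self.davies_bouldin_,
            ttest_table=ttable,
        )


def select_k(
    som: GrowingSOM, features, k_range, seed: int = 0, restarts: int = 30
) -> tuple[int, pd.DataFrame]:
    """Pick the k in ``k_range`` maximizing participant-level silhouette.

    Ties go to the smaller k.  Returns the chosen k and the full
    silhouette-vs-k table for reporting.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    arr = _as_array(features)
    rows = []
    for k in ks:
        node_labels, _ = kmeans_nodes(som, k, seed=seed, restarts=restarts)
        labels = assign_participants(som, node_labels, arr)
        if len(np.unique(labels)) < 2:
            sc = -np.inf  # all participants collapsed into one cluster
        else:
            sc = silhouette_coefficient(arr, labels)
        rows.append(dict(k=k, silhouette=sc))
    table = pd.DataFrame(rows)
    best = int(table.loc[table["silhouette"].idxmax(), "k"])
    return best, table
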