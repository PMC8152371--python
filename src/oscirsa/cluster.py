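"""Correlation-distance k-means over the TF stack of RDM vectors.

The power and phase RDM vectors at every unmasked TF coordinate are pooled
into one set of points (each a dissimilarity vector of length n(n-1)/2)
and clustered with k-means under the correlation distance: points are
row-centered and unit-normalized, assignment uses ``1 - Pearson`` to the
centroids, and each centroid update takes the mean of the member rows
followed by re-centering and renormalization.  The best of several random
initializations (by residual sum of within-cluster distances) is kept.

Model selection uses an elbow criterion on the RSS-versus-k curve: the
chosen k is the point just before the first local maximum of the curve's
discrete second derivative — the k after which adding a cluster buys only
a marginal gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .rdm import RDMStack

__all__ = [
    "CorrelationKMeans",
    "ClusterResult",
    "CentroidDistanceMaps",
    "kmeans_rdm",
    "sweep_k",
    "choose_k_elbow",
    "distance_to_centroid_maps",
    "rank_clusters",
]

logger = logging.getLogger(__name__)


def _row_normalize(X: np.ndarray) -> np.ndarray:
    """Center and unit-normalize rows (the correlation-distance embedding)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("constant vector: correlation distance undefined")
    return Xc / norms


class CorrelationKMeans(BaseEstimator, ClusterMixin):
    """K-means with the correlation distance ``1 - Pearson``.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k.
    n_replicates : int
        Random initializations; the solution with the lowest residual sum
        of within-cluster distances is kept.
    max_iter : int
        Lloyd iteration cap per replicate.
    random_state : int or None
        Seed for the initializations; fitting is deterministic given it.

    Attributes
    ----------
    cluster_centers_ : (n_clusters, n_features) centered unit-norm centroids.
    labels_ : (n_samples,) cluster assignment of the training data.
    inertia_ : float, residual sum of within-cluster correlation distances.
    n_iter_ : iterations used by the winning replicate.
    """

    def __init__(self, n_clusters: int = 7, n_replicates: int = 5,
                 max_iter: int = 300, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_replicates = n_replicates
        self.max_iter = max_iter
        self.random_state = random_state

    def _lloyd(self, Xn: np.ndarray, rng: np.random.Generator):
        n, k = Xn.shape[0], self.n_clusters
        centers = Xn[rng.choice(n, size=k, replace=False)].copy()
        labels = np.full(n, -1)
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            dist = 1.0 - Xn @ centers.T
            new_labels = dist.argmin(axis=1)
            # re-seed empty clusters from the points farthest from their centroid
            empties = [c for c in range(k) if not np.any(new_labels == c)]
            if empties:
                own = np.take_along_axis(dist, new_labels[:, None], axis=1).ravel()
                worst = np.argsort(own)[::-1]
                for c, w in zip(empties, worst):
                    centers[c] = Xn[w]
                    new_labels[w] = c
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                members = Xn[labels == c]
                if members.shape[0] == 0:
                    continue
                m = members.mean(axis=0)
                m = m - m.mean()
                nrm = np.linalg.norm(m)
                if nrm > 0:
                    centers[c] = m / nrm
        dist = 1.0 - Xn @ centers.T
        labels = dist.argmin(axis=1)
        rss = float(np.take_along_axis(dist, labels[:, None], axis=1).sum())
        return labels, centers, rss, n_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        if not (1 <= self.n_clusters <= X.shape[0]):
            raise ValueError("need 1 <= n_clusters <= n_samples")
        Xn = _row_normalize(X)
        root = np.random.SeedSequence(self.random_state)
        best = None
        for rep_seed in root.spawn(self.n_replicates):
            rng = np.random.default_rng(rep_seed)
            labels, centers, rss, n_iter = self._lloyd(Xn, rng)
            if best is None or rss < best[2]:
                best = (labels, centers, rss, n_iter)
        self.labels_, self.cluster_centers_, self.inertia_, self.n_iter_ = best
        return self

    def predict(self, X):
        Xn = _row_normalize(np.asarray(X, dtype=float))
        return (1.0 - Xn @ self.cluster_centers_.T).argmin(axis=1)

    def transform(self, X):
        """Correlation distances of each sample to every centroid."""
        Xn = _row_normalize(np.asarray(X, dtype=float))
        return 1.0 - Xn @ self.cluster_centers_.T


@dataclass
class ClusterResult:
    """Clustering of a TF RDM stack with the k-selection bookkeeping."""

    assignments: dict           # (kind, freq_idx, time_idx) -> cluster id
    centroids: np.ndarray       # (k, n_pairs) centered unit-norm vectors
    rss_curve: dict             # k -> residual sum of distances
    chosen_k: int
    replicates: int = 5
    seed: int | None = None
    index: list = field(default_factory=list)  # row order used for clustering
    labels_: np.ndarray | None = None


def kmeans_rdm(vectors: np.ndarray, k: int, replicates: int = 5,
               seed: int | None = None) -> CorrelationKMeans:
    """Fit a :class:`CorrelationKMeans` on rows of RDM vectors."""
    return CorrelationKMeans(n_clusters=k, n_replicates=replicates,
                             random_state=seed).fit(vectors)


def sweep_k(stack: RDMStack, k_max: int = 20, replicates: int = 5,
            seed: int | None = None, choose: bool = True) -> ClusterResult:
    """Cluster the stack for k = 1..k_max and pick k by the elbow criterion.

    The stack's unmasked power and phase RDM vectors enter as equal rows.
    The returned result carries the winning model at the chosen k (or at
    ``k_max`` if ``choose=False``).
    """
    X, index = stack.flat_vectors()
    if k_max < 4:
        raise ValueError("k_max must be >= 4 for elbow selection")
    models = {}
    rss_curve = {}
    root = np.random.SeedSequence((seed, 733) if seed is not None else None)
    child = root.generate_state(1)[0] if seed is not None else None
    for k in range(1, k_max + 1):
        km = CorrelationKMeans(
            n_clusters=k, n_replicates=replicates,
            random_state=None if child is None else int((child + k) % (2**31)),
        ).fit(X)
        models[k] = km
        rss_curve[k] = km.inertia_
    chosen = choose_k_elbow(rss_curve) if choose else k_max
    km = models[chosen]
    assignments = {coord: int(c) for coord, c in zip(index, km.labels_)}
    return ClusterResult(assignments, km.cluster_centers_, rss_curve, chosen,
                         replicates, seed, index, km.labels_)


def choose_k_elbow(rss_curve: dict | np.ndarray, pre_maximum: bool = False) -> int:
    """Elbow selection on an RSS-versus-k curve.

    Computes the discrete second derivative ``d2(k) = RSS(k+1) - 2 RSS(k)
    + RSS(k-1)`` for interior k and returns the k at which the curvature
    peaks (ties resolved to the smallest k) — the point at which adding
    another cluster would only provide a marginal gain: the drop into k is
    still large while the drop beyond k is small.  ``pre_maximum=True``
    instead returns the point just before the curvature maximum
    (``k_m - 1``), an alternative reading of the elbow; it is one step
    conservative on curves with a sharp slope break.

    Raises
    ------
    ValueError
        If the curve has no curvature maximum (e.g., exactly linear, where
        the second derivative is constant).
    """
    if isinstance(rss_curve, dict):
        ks = sorted(rss_curve)
        rss = np.array([rss_curve[k] for k in ks], dtype=float)
    else:
        rss = np.asarray(rss_curve, dtype=float)
        ks = list(range(1, rss.size + 1))
    if rss.size < 4:
        raise ValueError("need RSS at k = 1..K_max with K_max >= 4")
    d2 = rss[2:] - 2 * rss[1:-1] + rss[:-2]  # indexed by ks[1:-1]
    if np.allclose(d2, d2[0]):
        raise ValueError("no elbow: RSS curve has constant curvature")
    i = int(d2.argmax())  # argmax takes the smallest index on ties
    k_m = ks[i + 1]
    return max(ks[0], k_m - 1) if pre_maximum else k_m


@dataclass
class CentroidDistanceMaps:
    """Per-cluster TF maps of correlation distance to the centroid."""

    maps: dict  # cluster id -> {kind: (n_freqs, n_times) array}
    kinds: list


def distance_to_centroid_maps(result: ClusterResult,
                              stack: RDMStack) -> CentroidDistanceMaps:
    """Correlation distance of every TF coordinate's RDM to each centroid.

    Visualizes how stereotypical each coordinate is for each cluster;
    masked coordinates stay NaN.
    """
    F, T = stack.freqs.size, stack.times.size
    X, index = stack.flat_vectors()
    Xc = X - X.mean(axis=1, keepdims=True)
    Xn = Xc / np.linalg.norm(Xc, axis=1, keepdims=True)
    dists = 1.0 - Xn @ result.centroids.T  # (n_points, k)
    maps = {}
    for c in range(result.centroids.shape[0]):
        per_kind = {k: np.full((F, T), np.nan) for k in stack.kinds}
        for row, (kind, fi, ti) in enumerate(index):
            per_kind[kind][fi, ti] = dists[row, c]
        maps[c] = per_kind
    return CentroidDistanceMaps(maps, list(stack.kinds))


def rank_clusters(result: ClusterResult, stack: RDMStack) -> list[int]:
    """Cluster ids ordered by ascending mean member-to-centroid distance.

    Tight clusters (stereotypical, low within-cluster distance) rank first;
    diffuse noise-like clusters rank last.
    """
    X, index = stack.flat_vectors()
    Xc = X - X.mean(axis=1, keepdims=True)
    Xn = Xc / np.linalg.norm(Xc, axis=1, keepdims=True)
    labels = np.array([result.assignments[coord] for coord in index])
    means = {}
    for c in range(result.centroids.shape[0]):
        members = Xn[labels == c]
        if members.size == 0:
            means[c] = np.inf
        else:
            means[c] = float((1.0 - members @ result.centroids[c]).mean())
    return sorted(means, key=lambda c: means[c])
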