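"""Correlation-distance k-means, elbow selection, centroid distance maps."""

import numpy as np
import pytest

from oscirsa import (CorrelationKMeans, choose_k_elbow, compute_rdm,
                     distance_to_centroid_maps, kmeans_rdm, rank_clusters,
                     sweep_k, vectorize_rdm)
from oscirsa.rdm import RDMStack


def family_vectors(n_families, per_family, seed, n_cond=14, noise=0.2):
    """Rows of noisy RDM vectors drawn around n_families planted geometries."""
    rng = np.random.default_rng(seed)
    rows, owners = [], []
    for fam in range(n_families):
        base = vectorize_rdm(
            compute_rdm(rng.standard_normal((n_cond, 30))).matrix)
        for _ in range(per_family):
            rows.append(base + noise * base.std() * rng.standard_normal(base.size))
            owners.append(fam)
    return np.asarray(rows), np.asarray(owners)


def stack_from_rows(rows, kinds=("power", "phase")):
    """Arrange rows of RDM vectors on a synthetic TF grid as an RDMStack."""
    n_k = len(kinds)
    n = rows.shape[0]
    per_kind = int(np.ceil(n / n_k))
    F = 1
    T = per_kind
    vectors = np.full((n_k, F, T, rows.shape[1]), np.nan)
    valid = np.zeros((F, T), dtype=bool)
    idx = 0
    for ti in range(T):
        for ki in range(n_k):
            if idx < n:
                vectors[ki, 0, ti] = rows[idx]
                idx += 1
        valid[0, ti] = True
    # drop any half-filled trailing column
    if n % n_k:
        valid[0, -1] = False
    n_cond = round_n(rows.shape[1])
    labels = [f"c{i}" for i in range(n_cond)]
    return RDMStack(vectors, list(kinds), np.array([10.0]),
                    np.arange(T, dtype=float), labels, valid)


def round_n(n_pairs):
    return int(round((1 + np.sqrt(1 + 8 * n_pairs)) / 2))


class TestCorrelationKMeans:
    def test_single_cluster_centroid_is_renormalized_grand_mean(self):
        rows, _ = family_vectors(2, 10, seed=1)
        km = kmeans_rdm(rows, k=1, seed=0)
        Xc = rows - rows.mean(axis=1, keepdims=True)
        Xn = Xc / np.linalg.norm(Xc, axis=1, keepdims=True)
        m = Xn.mean(axis=0)
        m = m - m.mean()
        m /= np.linalg.norm(m)
        assert np.allclose(km.cluster_centers_[0], m, atol=1e-10)
        assert km.inertia_ == pytest.approx(float((1 - Xn @ m).sum()))

    def test_two_separated_families_recovered_perfectly(self):
        rows, owners = family_vectors(2, 15, seed=2, noise=0.15)
        km = kmeans_rdm(rows, k=2, replicates=5, seed=3)
        # purity: each cluster maps to one family
        purity = 0
        for c in (0, 1):
            sel = km.labels_ == c
            purity += max((owners[sel] == f).sum() for f in (0, 1))
        assert purity / rows.shape[0] == 1.0

    def test_deterministic_given_seed(self):
        rows, _ = family_vectors(3, 8, seed=4)
        a = kmeans_rdm(rows, k=3, seed=9)
        b = kmeans_rdm(rows, k=3, seed=9)
        assert np.array_equal(a.labels_, b.labels_)
        assert a.inertia_ == b.inertia_

    def test_affine_rescaling_invariance(self):
        rows, _ = family_vectors(2, 10, seed=5)
        km1 = kmeans_rdm(rows, k=2, seed=1)
        scales = np.random.default_rng(6).uniform(0.5, 3.0, rows.shape[0])
        shifts = np.random.default_rng(7).normal(size=rows.shape[0])
        rows2 = rows * scales[:, None] + shifts[:, None]
        km2 = kmeans_rdm(rows2, k=2, seed=1)
        assert np.array_equal(km1.labels_, km2.labels_)

    def test_rss_non_increasing_in_k(self):
        rows, _ = family_vectors(4, 10, seed=8)
        rss = [kmeans_rdm(rows, k=k, replicates=5, seed=11).inertia_
               for k in range(1, 9)]
        assert np.all(np.diff(rss) <= 1e-9)

    def test_agrees_with_euclidean_kmeans_on_normalized_rows(self):
        """On normalized rows, correlation and Euclidean k-means agree for
        well-separated data (1 - r is a monotone map of squared distance)."""
        from sklearn.cluster import KMeans

        rows, owners = family_vectors(3, 12, seed=12, noise=0.15)
        Xc = rows - rows.mean(axis=1, keepdims=True)
        Xn = Xc / np.linalg.norm(Xc, axis=1, keepdims=True)
        sk = KMeans(n_clusters=3, n_init=10, random_state=0).fit(Xn)
        ours = kmeans_rdm(rows, k=3, replicates=5, seed=0)
        # compare partitions via pair-counting (labels are arbitrary)
        same_sk = sk.labels_[:, None] == sk.labels_[None, :]
        same_us = ours.labels_[:, None] == ours.labels_[None, :]
        assert np.array_equal(same_sk, same_us)


class TestElbow:
    def test_slope_break_detected_at_breakpoint(self):
        # piecewise-linear RSS: steep to k=7, flat after
        ks = np.arange(1, 13)
        rss = np.where(ks <= 7, 100 - 10 * (ks - 1), 40 - 0.5 * (ks - 7))
        assert choose_k_elbow(dict(zip(ks, rss))) == 7
        assert choose_k_elbow(dict(zip(ks, rss)), pre_maximum=True) == 6

    def test_linear_curve_has_no_elbow(self):
        rss = {k: 100 - 5 * k for k in range(1, 10)}
        with pytest.raises(ValueError, match="no elbow"):
            choose_k_elbow(rss)

    def test_seven_family_structure_recovered_modally(self):
        picks = []
        for seed in range(1, 21):
            rows, _ = family_vectors(7, 30, seed=seed, n_cond=20, noise=0.35)
            rss = {k: kmeans_rdm(rows, k=k, replicates=5,
                                 seed=seed * 100 + k).inertia_
                   for k in range(1, 13)}
            picks.append(choose_k_elbow(rss))
        counts = np.bincount(picks)
        assert counts.argmax() == 7


class TestMapsAndRanking:
    def _fitted(self, seed=3):
        rows, owners = family_vectors(2, 12, seed=seed, noise=0.15)
        stack = stack_from_rows(rows)
        result = sweep_k(stack, k_max=4, replicates=3, seed=5, choose=False)
        return rows, owners, stack, result

    def test_member_at_centroid_has_zero_distance(self):
        rows, _ = family_vectors(2, 6, seed=6)
        stack = stack_from_rows(rows)
        result = sweep_k(stack, k_max=4, replicates=3, seed=7, choose=False)
        # plant a coordinate equal to a centroid
        X, index = stack.flat_vectors()
        dmaps = distance_to_centroid_maps(result, stack)
        for c in range(result.centroids.shape[0]):
            for kind in stack.kinds:
                m = dmaps.maps[c][kind]
                vals = m[np.isfinite(m)]
                assert vals.min() >= -1e-9 and vals.max() <= 2 + 1e-9

    def test_within_cluster_distance_below_between(self):
        rows, owners, stack, _ = self._fitted()
        km = kmeans_rdm(rows, k=2, replicates=5, seed=1)
        dist = km.transform(rows)
        within = np.take_along_axis(dist, km.labels_[:, None], axis=1).mean()
        between = np.take_along_axis(dist, 1 - km.labels_[:, None], axis=1).mean()
        assert within < between

    def test_tight_cluster_ranks_before_diffuse(self):
        rng = np.random.default_rng(9)
        base1 = vectorize_rdm(compute_rdm(rng.standard_normal((14, 30))).matrix)
        base2 = vectorize_rdm(compute_rdm(rng.standard_normal((14, 30))).matrix)
        rows = np.vstack(
            [base1 + 0.02 * rng.standard_normal(base1.size) for _ in range(10)]
            + [base2 + 0.9 * base2.std() * rng.standard_normal(base2.size)
               for _ in range(10)])
        stack = stack_from_rows(rows)
        result = sweep_k(stack, k_max=4, replicates=5, seed=2, choose=False)
        # refit at k=2 for a clean two-cluster ranking
        km = kmeans_rdm(rows, k=2, replicates=5, seed=2)
        result.centroids = km.cluster_centers_
        X, index = stack.flat_vectors()
        result.assignments = {coord: int(c) for coord, c in zip(index, km.labels_)}
        ranking = rank_clusters(result, stack)
        tight_cluster = km.labels_[0]
        assert ranking[0] == tight_cluster

    def test_ranking_invariant_to_relabeling(self):
        rows, owners, stack, result = self._fitted(seed=10)
        ranking = rank_clusters(result, stack)
        # permute cluster ids consistently
        k = result.centroids.shape[0]
        perm = np.roll(np.arange(k), 1)
        permuted_assign = {c: int(perm[v]) for c, v in result.assignments.items()}
        from oscirsa.cluster import ClusterResult
        permuted = ClusterResult(permuted_assign,
                                 result.centroids[np.argsort(perm)],
                                 result.rss_curve, result.chosen_k,
                                 result.replicates, result.seed, result.index)
        ranking2 = rank_clusters(permuted, stack)
        assert [perm[c] for c in ranking] == ranking2
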