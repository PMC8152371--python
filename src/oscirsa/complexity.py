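"""Cortical-level and feature-hierarchy complexity scores for cluster centroids.

Two complementary scores locate each cluster's representational geometry
along the visual hierarchy:

* the *level score* ``L = sigmoid((R_IT - R_V1) / (R_IT + R_V1))`` combines
  the centroid's partial correlations with the low-level (V1-like) and
  high-level (IT-like) reference RDMs into one scale — 0.5 when the two
  match equally, below for V1-like content, above for IT-like content.
  Note the sigmoid of the ratio spans only about [0.269, 0.731] for
  non-negative correlations; the formula is applied literally and a
  non-positive denominator is treated as undefined.
* the *hierarchy complexity* maps the centroid onto layered feature sets:
  per hierarchy, the layer whose (centered) RDM best matches the centroid
  under Spearman correlation, normalized to [0, 1] across the hierarchy's
  depth, then averaged across hierarchies.

Significance of a centroid-to-reference partial correlation is assessed
with a surrogate test that shuffles the centroid's dissimilarity entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

from .rdm import compute_rdm, vectorize_rdm
from .rsa import partial_correlation
from .simulate import LayeredFeatureSet

__all__ = [
    "LevelScore",
    "ComplexityScore",
    "level_score",
    "surrogate_test",
    "center_features",
    "centroid_origin_distance",
    "hierarchy_complexity",
]

logger = logging.getLogger(__name__)


@dataclass
class LevelScore:
    """Level score with the partial correlations and surrogate p values."""

    r_v1: float
    r_it: float
    level: float
    p_low: float | None = None
    p_high: float | None = None


def level_score(r_v1: float, r_it: float) -> float:
    """``L = sigmoid((R_IT - R_V1) / (R_IT + R_V1))``.

    Raises
    ------
    ValueError
        If ``R_IT + R_V1 <= 0`` (the scale is undefined when neither
        reference shows a positive net match).
    """
    s = r_it + r_v1
    if s <= 0:
        raise ValueError(
            f"level undefined: R_IT + R_V1 = {s:.4g} is not positive"
        )
    return float(expit((r_it - r_v1) / s))


def surrogate_test(centroid_vec: np.ndarray, target_rdm_vec: np.ndarray,
                   control_rdm_vec: np.ndarray, n_iter: int = 100_000,
                   seed: int | None = None, scheme: str = "entries",
                   chunk: int = 2000) -> float:
    """One-sided surrogate p for a centroid-to-reference partial correlation.

    Each iteration shuffles the centroid vector and recomputes the partial
    correlation with ``target`` controlling ``control``; the p value is the
    add-one-corrected proportion of surrogates at or above the observed
    value: ``p = (#{r_surr >= r_obs} + 1) / (n_iter + 1)``.

    ``scheme='entries'`` permutes the dissimilarity entries directly;
    ``scheme='conditions'`` permutes condition rows/columns jointly, which
    preserves the RDM structure of the surrogate (stricter null).
    """
    x = np.asarray(centroid_vec, dtype=float)
    y = np.asarray(target_rdm_vec, dtype=float)
    z = np.asarray(control_rdm_vec, dtype=float)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    observed = partial_correlation(x, y, z)

    def _std(v):
        c = v - v.mean()
        return c / np.linalg.norm(c)

    ys, zs = _std(y), _std(z)
    r_yz = float(ys @ zs)
    denom = np.sqrt(1.0 - r_yz**2)
    rng = np.random.default_rng(seed)
    n = x.size
    count = 0

    if scheme == "entries":
        xs = _std(x)  # permutation-invariant standardization
        done = 0
        while done < n_iter:
            m = min(chunk, n_iter - done)
            perms = np.argsort(rng.random((m, n)), axis=1)
            Xp = xs[perms]
            r_xy = Xp @ ys
            r_xz = Xp @ zs
            with np.errstate(invalid="ignore", divide="ignore"):
                r_part = (r_xy - r_xz * r_yz) / (np.sqrt(1 - r_xz**2) * denom)
            count += int(np.sum(r_part >= observed))
            done += m
    elif scheme == "conditions":
        rdm = compute_rdm_safe(x)
        n_cond = rdm.shape[0]
        for _ in range(n_iter):
            p = rng.permutation(n_cond)
            surr = vectorize_rdm(rdm[np.ix_(p, p)])
            xs = _std(surr)
            r_xy, r_xz = float(xs @ ys), float(xs @ zs)
            r_part = (r_xy - r_xz * r_yz) / (np.sqrt(1 - r_xz**2) * denom)
            if r_part >= observed:
                count += 1
    else:
        raise ValueError(f"unknown surrogate scheme {scheme!r}")
    return (count + 1) / (n_iter + 1)


def compute_rdm_safe(vec: np.ndarray) -> np.ndarray:
    """Square form of an RDM vector without entry-range validation.

    Centroid vectors are centered/normalized RDM vectors whose entries are
    not confined to [0, 2]; the condition-permutation surrogate only needs
    the square arrangement.
    """
    vec = np.asarray(vec, dtype=float)
    n = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
    if n * (n - 1) // 2 != vec.size:
        raise ValueError("vector length is not a triangular number")
    m = np.zeros((n, n))
    i, j = np.tril_indices(n, k=-1)
    m[i, j] = vec
    m[j, i] = vec
    return m


def center_features(features: LayeredFeatureSet) -> LayeredFeatureSet:
    """Subtract each layer's centering-set mean activation from the analysis set.

    Removes the common offset that pushes all analysis images into a remote
    corner of feature space; computed from the independent centering images
    only, so no information leaks from the analysis set.
    """
    layers = []
    for li, (a, c) in enumerate(zip(features.layers, features.centering)):
        if a.shape[1] != c.shape[1]:
            raise ValueError(f"layer {li}: feature count mismatch with centering set")
        layers.append(a - c.mean(axis=0, keepdims=True))
    return LayeredFeatureSet(layers, [c.copy() for c in features.centering],
                             name=features.name)


def centroid_origin_distance(features: LayeredFeatureSet) -> np.ndarray:
    """Normalized distance of each layer's image centroid from the origin.

    Per layer: the Euclidean norm of the mean feature vector across images,
    divided by the root-mean per-feature SD across images.  Large values
    diagnose the remote-corner geometry that feature centering removes.
    """
    out = []
    for li, a in enumerate(features.layers):
        if a.shape[0] < 2:
            raise ValueError(f"layer {li}: need >= 2 images")
        var = a.var(axis=0)
        if np.all(var == 0):
            raise ValueError(f"layer {li}: zero variance across images")
        out.append(np.linalg.norm(a.mean(axis=0)) / np.sqrt(var.mean()))
    return np.asarray(out)


@dataclass
class ComplexityScore:
    """Per-hierarchy argmax layer and the mean normalized position."""

    per_hierarchy: list = field(default_factory=list)
    # each: dict(name, argmax_layer (1-based), n_layers, position, peak_r)
    mean_position: float = float("nan")


def _spearman_vs(centroid_rank: np.ndarray, vec: np.ndarray) -> float:
    r = rankdata(vec)
    return float(np.corrcoef(centroid_rank, r)[0, 1])


def hierarchy_complexity(centroid_vec: np.ndarray,
                         feature_sets: list[LayeredFeatureSet],
                         center: bool = True) -> ComplexityScore:
    """Map a centroid RDM onto layered feature hierarchies.

    Per hierarchy: Spearman-correlate the centroid vector with every
    (centered) layer's RDM vector; take the argmax layer (ties go to the
    smallest index, logged) and its normalized position
    ``(argmax - 1) / (n_layers - 1)``; average positions across
    hierarchies.
    """
    x = np.asarray(centroid_vec, dtype=float)
    if not feature_sets:
        raise ValueError("need at least one feature hierarchy")
    xr = rankdata(x)
    per = []
    for fs in feature_sets:
        if fs.n_layers < 2:
            raise ValueError(f"{fs.name}: need >= 2 layers")
        cfs = center_features(fs) if center else fs
        rs = []
        for a in cfs.layers:
            v = vectorize_rdm(compute_rdm(a).matrix)
            if v.size != x.size:
                raise ValueError(
                    f"{fs.name}: layer RDM size {v.size} != centroid size {x.size}"
                )
            rs.append(_spearman_vs(xr, v))
        rs = np.asarray(rs)
        best = int(rs.argmax())  # argmax takes the first (smallest) index on ties
        if np.sum(rs == rs[best]) > 1:
            logger.info("%s: tie at argmax layer, keeping smallest index", fs.name)
        per.append({
            "name": fs.name,
            "argmax_layer": best + 1,
            "n_layers": fs.n_layers,
            "position": best / (fs.n_layers - 1),
            "peak_r": float(rs[best]),
            "layer_r": rs.tolist(),
        })
    mean_pos = float(np.mean([p["position"] for p in per]))
    return ComplexityScore(per, mean_pos)
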