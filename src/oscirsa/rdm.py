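"""Representational dissimilarity matrices (RDMs) and their comparison.

An RDM summarises the geometry of a set of condition-wise activation
patterns: entry (i, j) is ``1 - Pearson(pattern_i, pattern_j)``, so values
live in [0, 2] with a zero diagonal.  All modules share a single, fixed
vectorization order (strictly-lower triangle, row-major) so that RDM
vectors are comparable and serializable across stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RDM",
    "RDMStack",
    "compute_rdm",
    "vectorize_rdm",
    "devectorize_rdm",
    "rdm_correlation",
    "build_rdm_stack",
]

_SYM_TOL = 1e-12


@dataclass
class RDM:
    """A square symmetric dissimilarity matrix with condition labels."""

    matrix: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"RDM matrix must be square, got shape {m.shape}")
        if not self.labels:
            self.labels = list(range(m.shape[0]))
        if len(self.labels) != m.shape[0]:
            raise ValueError("label count does not match matrix size")
        if np.abs(m - m.T).max() > 1e-9:
            raise ValueError("RDM matrix is not symmetric")
        # tidy numerically: exact symmetry, exact zero diagonal
        self.matrix = (m + m.T) / 2.0
        np.fill_diagonal(self.matrix, 0.0)
        if self.matrix.min() < -1e-9 or self.matrix.max() > 2 + 1e-9:
            raise ValueError("RDM entries must lie in [0, 2]")
        np.clip(self.matrix, 0.0, 2.0, out=self.matrix)

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[0]

    def vector(self) -> np.ndarray:
        return vectorize_rdm(self)


def compute_rdm(patterns: np.ndarray, labels: Sequence | None = None) -> RDM:
    """1 - Pearson RDM of a (conditions x features) pattern matrix.

    Pearson is computed with matched normalization in numerator and
    denominator, so the result is independent of n-vs-(n-1) conventions
    and of any per-condition positive affine map of the rows.

    Raises
    ------
    ValueError
        If fewer than 3 conditions, or if any condition's pattern vector
        has zero variance (correlation undefined); the offending condition
        is named in the message.
    """
    x = np.asarray(patterns, dtype=float)
    if x.ndim != 2:
        raise ValueError("patterns must be 2-D (conditions x features)")
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 conditions, got {n}")
    labels = list(labels) if labels is not None else list(range(n))
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance pattern for condition {labels[bad[0]]!r}; "
            "correlation distance undefined"
        )
    r = np.corrcoef(x)
    return RDM(1.0 - r, labels)


def vectorize_rdm(rdm: RDM | np.ndarray) -> np.ndarray:
    """Strictly-lower-triangle entries in row-major order, length n(n-1)/2."""
    m = rdm.matrix if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def devectorize_rdm(vec: np.ndarray, labels: Sequence | None = None) -> RDM:
    """Inverse of :func:`vectorize_rdm` (bijection on the half-matrix)."""
    vec = np.asarray(vec, dtype=float)
    # n(n-1)/2 = len  ->  n = (1 + sqrt(1 + 8 len)) / 2
    n = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
    if n * (n - 1) // 2 != vec.size:
        raise ValueError(f"vector length {vec.size} is not a triangular number")
    m = np.zeros((n, n))
    i, j = np.tril_indices(n, k=-1)
    m[i, j] = vec
    m[j, i] = vec
    return RDM(m, list(labels) if labels is not None else None)


def rdm_correlation(a: RDM, b: RDM, method: str = "pearson") -> float:
    """Correlation between two RDMs' vectorized forms.

    ``method='spearman'`` uses average ranks for ties, the convention for
    comparing a measured RDM against reference or model-layer geometries.
    """
    if isinstance(a, RDM) and isinstance(b, RDM) and a.labels != b.labels:
        raise ValueError("RDMs have different condition labels")
    va, vb = vectorize_rdm(a), vectorize_rdm(b)
    if va.size != vb.size:
        raise ValueError("RDM sizes differ")
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("constant RDM vector: correlation undefined")
    if method == "pearson":
        return float(np.corrcoef(va, vb)[0, 1])
    if method == "spearman":
        return float(stats.spearmanr(va, vb).statistic)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class RDMStack:
    """Vectorized RDMs indexed by (signal kind, frequency, time).

    ``vectors`` has shape (n_kinds, n_freqs, n_times, n_pairs); ``valid``
    marks time-frequency coordinates whose analysis window fit inside the
    epoch (shared across kinds).
    """

    vectors: np.ndarray
    kinds: list
    freqs: np.ndarray
    times: np.ndarray
    labels: list
    valid: np.ndarray  # (n_freqs, n_times) bool

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        k, f, t, p = self.vectors.shape
        if (k, f, t) != (len(self.kinds), self.freqs.size, self.times.size):
            raise ValueError("vector array shape inconsistent with index")
        n = len(self.labels)
        if n * (n - 1) // 2 != p:
            raise ValueError("pair dimension inconsistent with labels")

    @property
    def n_pairs(self) -> int:
        return self.vectors.shape[-1]

    def get_rdm(self, kind, freq_index: int, time_index: int) -> RDM:
        ki = self.kinds.index(kind)
        if not self.valid[freq_index, time_index]:
            raise ValueError("coordinate is masked (window outside epoch)")
        return devectorize_rdm(self.vectors[ki, freq_index, time_index], self.labels)

    def flat_vectors(self) -> tuple[np.ndarray, list]:
        """All unmasked RDM vectors as rows, plus their (kind, fi, ti) index.

        Row order: kinds outer, then frequency, then time — the order used
        for clustering and for mapping assignments back to TF coordinates.
        """
        rows, index = [], []
        for ki, kind in enumerate(self.kinds):
            for fi in range(self.freqs.size):
                for ti in range(self.times.size):
                    if self.valid[fi, ti]:
                        rows.append(self.vectors[ki, fi, ti])
                        index.append((kind, fi, ti))
        return np.asarray(rows), index


def build_rdm_stack(pattern_sets) -> RDMStack:
    """RDM stack from one or more pattern sets (typically power and phase).

    Each unmasked (freq, time) coordinate of every pattern set yields one
    vectorized 1 - Pearson RDM.  All pattern sets must share the TF grid,
    condition labels, and validity mask; a coordinate is dropped (masked)
    when any pattern there is degenerate.
    """
    if not pattern_sets:
        raise ValueError("need at least one pattern set")
    grid = pattern_sets[0].grid
    labels = list(pattern_sets[0].labels)
    kinds = [ps.kind for ps in pattern_sets]
    if len(set(kinds)) != len(kinds):
        raise ValueError("duplicate pattern-set kinds")
    F, T = grid.n_freqs, grid.n_times
    valid = np.ones((F, T), dtype=bool)
    for ps in pattern_sets:
        if ps.grid.n_freqs != F or ps.grid.n_times != T:
            raise ValueError("pattern sets must share the TF grid")
        if list(ps.labels) != labels:
            raise ValueError("pattern sets must share condition labels")
        valid &= ps.valid
    n = len(labels)
    n_pairs = n * (n - 1) // 2
    vectors = np.full((len(kinds), F, T, n_pairs), np.nan)
    for ki, ps in enumerate(pattern_sets):
        for fi in range(F):
            for ti in range(T):
                if not valid[fi, ti]:
                    continue
                pats = ps.values[fi, ti]
                if not np.all(np.isfinite(pats)) or np.any(pats.std(axis=1) == 0):
                    valid[fi, ti] = False
                    continue
                vectors[ki, fi, ti] = vectorize_rdm(compute_rdm(pats, labels).matrix)
    return RDMStack(vectors, kinds, grid.freqs, grid.times, labels, valid)
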