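"""Partial-correlation RSA between a TF RDM stack and two reference RDMs.

Because the two reference geometries (a low-level, V1-like RDM and a
high-level, IT-like RDM) are themselves positively correlated, each one's
match to an oscillatory RDM is assessed with the *partial* Pearson
correlation, controlling for the other reference.  This isolates the
unique contribution of each region and yields, per subject, one RSA map
over (frequency, time) for every combination of signal kind (power,
phase) and reference (low, high).

Group-level significance is a per-coordinate one-sample t test of the
partial correlations against zero (no Fisher transform, two-sided),
followed by Benjamini-Hochberg FDR across the unmasked coordinates of
each map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rdm import RDMStack, vectorize_rdm
from .simulate import ReferenceRDMPair
from .tf import TFGrid

__all__ = [
    "RSAMap",
    "GroupResult",
    "partial_correlation",
    "rsa_map",
    "group_significance",
    "latency_correct",
    "band_profile",
    "BANDS",
]

logger = logging.getLogger(__name__)

#: Canonical frequency bands (Hz) for time-course profiles.
BANDS = {"alpha": (8.0, 13.0), "low_beta": (13.0, 20.0), "high_beta": (20.0, 32.0)}


def partial_correlation(x, y, z) -> float:
    """Partial Pearson correlation of ``x`` and ``y`` controlling for ``z``.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y, z must be 1-D vectors of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if v.std() == 0:
            raise ValueError(f"{name} is constant: correlation undefined")
    r = np.corrcoef(np.vstack([x, y, z]))
    rxy, rxz, ryz = r[0, 1], r[0, 2], r[1, 2]
    denom_sq = (1 - rxz**2) * (1 - ryz**2)
    if denom_sq <= 0 or abs(ryz) >= 1 - 1e-12:
        raise ValueError("y and z are collinear: partial correlation undefined")
    return float((rxy - rxz * ryz) / np.sqrt(denom_sq))


@dataclass
class RSAMap:
    """Partial-correlation values over (signal kind, freq, time) for one target."""

    values: np.ndarray  # (n_kinds, n_freqs, n_times); NaN where masked
    kinds: list
    grid: TFGrid
    target: str  # 'low' or 'high'

    def kind_map(self, kind) -> np.ndarray:
        return self.values[self.kinds.index(kind)]


def rsa_map(stack: RDMStack, ref_pair: ReferenceRDMPair) -> tuple[RSAMap, RSAMap]:
    """Partial-correlation RSA maps of one subject's RDM stack.

    At each unmasked TF coordinate and for both signal kinds, correlates
    the MEG RDM vector with each reference RDM while partialling out the
    other, producing the (low, high) map pair — with power and phase rows,
    the 2 x 2 design's four maps per subject.
    """
    if ref_pair.rdm_low.labels != stack.labels or ref_pair.rdm_high.labels != stack.labels:
        raise ValueError("reference RDMs and stack must share condition labels")
    vlow = vectorize_rdm(ref_pair.rdm_low)
    vhigh = vectorize_rdm(ref_pair.rdm_high)
    r_lh = float(np.corrcoef(vlow, vhigh)[0, 1])
    if abs(r_lh) >= 1 - 1e-12:
        raise ValueError("reference RDMs are collinear: partial correlation undefined")

    def _norm(v):
        c = v - v.mean()
        return c / np.linalg.norm(c)

    nlow, nhigh = _norm(vlow), _norm(vhigh)
    K, F, T, P = stack.vectors.shape
    out_low = np.full((K, F, T), np.nan)
    out_high = np.full((K, F, T), np.nan)
    denom = np.sqrt(1 - r_lh**2)
    n_degenerate = 0
    for ki in range(K):
        X = stack.vectors[ki].reshape(F * T, P)
        Xc = X - X.mean(axis=1, keepdims=True)  # masked rows stay NaN
        norms = np.linalg.norm(Xc, axis=1)
        ok = stack.valid.ravel() & np.isfinite(norms) & (norms > 0)
        Xn = Xc[ok] / norms[ok, None]
        r_xl = Xn @ nlow
        r_xh = Xn @ nhigh
        with np.errstate(invalid="ignore", divide="ignore"):
            p_low = (r_xl - r_xh * r_lh) / (np.sqrt(1 - r_xh**2) * denom)
            p_high = (r_xh - r_xl * r_lh) / (np.sqrt(1 - r_xl**2) * denom)
        bad = ~np.isfinite(p_low) | ~np.isfinite(p_high)
        n_degenerate += int(bad.sum())
        p_low[bad] = np.nan
        p_high[bad] = np.nan
        lo = np.full(F * T, np.nan)
        hi = np.full(F * T, np.nan)
        lo[ok] = p_low
        hi[ok] = p_high
        out_low[ki] = lo.reshape(F, T)
        out_high[ki] = hi.reshape(F, T)
    if n_degenerate:
        logger.warning("rsa_map: %d degenerate coordinates masked", n_degenerate)
    grid = TFGrid(stack.freqs, stack.times)
    return (RSAMap(out_low, list(stack.kinds), grid, "low"),
            RSAMap(out_high, list(stack.kinds), grid, "high"))


@dataclass
class GroupResult:
    """Group t/p maps and the BH-FDR rejection mask for one RSA map family."""

    t_map: np.ndarray
    p_map: np.ndarray
    fdr_mask: np.ndarray
    alpha: float = 0.05


def group_significance(subject_maps: list[np.ndarray] | np.ndarray,
                       alpha: float = 0.05) -> GroupResult:
    """One-sample t test of per-subject partial correlations against zero.

    ``subject_maps`` stacks one map per subject (matching shapes); raw r
    values are tested (no Fisher transform), two-sided, and the p values of
    all defined coordinates are corrected with Benjamini-Hochberg FDR at
    ``alpha``.  Coordinates that are masked in any subject, or with zero
    between-subject variance, have undefined p and are excluded from the
    mask.
    """
    arr = np.asarray(subject_maps, dtype=float)
    if arr.ndim < 2 or arr.shape[0] < 2:
        raise ValueError("need maps from at least 2 subjects")
    finite = np.all(np.isfinite(arr), axis=0)
    sd = arr.std(axis=0)
    testable = finite & (sd > 0)
    t_map = np.full(arr.shape[1:], np.nan)
    p_map = np.full(arr.shape[1:], np.nan)
    if np.any(testable):
        t, p = stats.ttest_1samp(arr[:, testable], 0.0, axis=0)
        t_map[testable] = t
        p_map[testable] = p
    fdr_mask = np.zeros(arr.shape[1:], dtype=bool)
    pvals = p_map[testable]
    if pvals.size:
        reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        fdr_mask[testable] = reject
    return GroupResult(t_map, p_map, fdr_mask, alpha)


def latency_correct(grid: TFGrid) -> np.ndarray:
    """Latency-corrected time axis per frequency: ``t + (window_cycles/f)/2``.

    The TF window smears responses backwards in time by up to half the
    window duration; adding half the window length per frequency avoids
    underestimating onset latencies.  Returns an (n_freqs, n_times) array.
    """
    shift = (grid.window_cycles / grid.freqs)[:, None] / 2.0
    return grid.times[None, :] + shift


def band_profile(values: np.ndarray, grid: TFGrid,
                 band: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Time course of a (freq x time) map averaged over a frequency band.

    Frequencies inside the closed interval ``band`` are averaged without
    weighting, per time point.  Returns ``(times_corrected, profile)``
    where ``times_corrected`` is the latency-corrected axis averaged over
    the band's frequencies (the per-frequency correction differs within
    the band; its mean locates the profile in corrected time).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_freqs, grid.n_times):
        raise ValueError("values must be (n_freqs x n_times) for the grid")
    lo, hi = band
    sel = (grid.freqs >= lo) & (grid.freqs <= hi)
    if not np.any(sel):
        raise ValueError(f"band {band} contains no grid frequencies")
    profile = values[sel].mean(axis=0)
    corrected = latency_correct(grid)[sel].mean(axis=0)
    return corrected, profile
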