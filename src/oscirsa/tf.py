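"""Multitaper time-frequency decomposition and condition pattern extraction.

Each (frequency, time) coordinate uses a sliding window of a fixed number
of oscillation cycles (default 2), with spectral smoothing proportional to
frequency (half-bandwidth ``0.4 * f``).  The time-half-bandwidth product is
therefore constant, ``NW = window_cycles * smoothing_factor = 0.8``, which
puts the taper count ``K = max(1, floor(2*NW - 1))`` at a single discrete
prolate spheroidal (Slepian) taper throughout.

From the complex coefficients, two condition pattern sets are derived per
coordinate:

* power — per-trial ``|coef|^2`` in dB, averaged across trials, giving an
  S-dimensional sensor pattern per condition;
* phase — per-trial unit-normalized coefficients averaged into a resultant,
  renormalized, and split into cosine (real) and sine (imaginary) parts,
  giving a 2S-dimensional pattern per condition.

Coordinates whose analysis window would overrun the epoch are masked, not
zero-padded: padding invents data and biases onset latencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import dpss
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import EpochSet

__all__ = [
    "TFGrid",
    "ComplexTFR",
    "PatternSet",
    "build_tf_grid",
    "MultitaperDecomposer",
    "multitaper_tfr",
    "condition_power_patterns",
    "condition_phase_patterns",
]

DB_FLOOR = 1e-20  # squared-amplitude units; avoids -inf on silent channels


@dataclass
class TFGrid:
    """Time-frequency analysis grid with the window/smoothing rule."""

    freqs: np.ndarray
    times: np.ndarray
    window_cycles: float = 2.0
    smoothing_factor: float = 0.4

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.freqs.ndim != 1 or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.freqs <= 0):
            raise ValueError("freqs must be positive")
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_freqs(self) -> int:
        return self.freqs.size

    @property
    def n_times(self) -> int:
        return self.times.size

    def window_duration(self, freq: float) -> float:
        """Sliding-window length in seconds at ``freq``."""
        return self.window_cycles / freq

    def half_bandwidth(self, freq: float) -> float:
        return self.smoothing_factor * freq

    def n_tapers(self, freq: float) -> int:
        nw = self.window_duration(freq) * self.half_bandwidth(freq)
        return max(1, int(np.floor(2 * nw - 1)))


def build_tf_grid(fmin: float = 3.0, fmax: float = 100.0, n_freqs: int = 50,
                  tmin: float = -0.6, tmax: float = 0.7, tstep: float = 0.02,
                  window_cycles: float = 2.0,
                  smoothing_factor: float = 0.4) -> TFGrid:
    """Log-spaced frequencies (endpoints inclusive) and an arithmetic time grid.

    The time grid starts at ``tmin`` and steps by ``tstep``; its last point
    is the largest grid value ``<= tmax`` (``tmax`` itself is included when
    the span is a multiple of ``tstep``).  Defaults give 50 frequencies from
    3 to 100 Hz and 66 time points from -0.6 to 0.7 s in 20 ms steps.
    """
    if fmin <= 0 or fmax <= fmin:
        raise ValueError("need 0 < fmin < fmax")
    if n_freqs < 1:
        raise ValueError("n_freqs must be >= 1")
    if tmin >= tmax or tstep <= 0:
        raise ValueError("need tmin < tmax and tstep > 0")
    freqs = np.geomspace(fmin, fmax, n_freqs) if n_freqs > 1 else np.array([fmin])
    n_steps = int(np.floor((tmax - tmin) / tstep + 1e-9)) + 1
    times = tmin + tstep * np.arange(n_steps)
    return TFGrid(freqs, times, window_cycles, smoothing_factor)


@dataclass
class ComplexTFR:
    """Complex TF coefficients over (condition, trial, sensor, freq, time).

    ``valid`` marks (freq, time) coordinates whose window fit inside the
    epoch; coefficients at masked coordinates are NaN.
    """

    coefficients: np.ndarray
    grid: TFGrid
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.coefficients.ndim != 5:
            raise ValueError("coefficients must be 5-D")
        if self.coefficients.shape[3:] != (self.grid.n_freqs, self.grid.n_times):
            raise ValueError("coefficient shape inconsistent with grid")


@dataclass
class PatternSet:
    """Per-TF-coordinate condition pattern matrices.

    ``values`` has shape (n_freqs, n_times, n_conditions, n_features) with
    ``n_features = S`` for power (dB sensor patterns) and ``2S`` for phase
    (cosine parts for all sensors, then sine parts).
    """

    kind: str
    values: np.ndarray
    grid: TFGrid
    valid: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("power", "phase"):
            raise ValueError("kind must be 'power' or 'phase'")
        if self.values.shape[:2] != (self.grid.n_freqs, self.grid.n_times):
            raise ValueError("values shape inconsistent with grid")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[2]

    @property
    def n_features(self) -> int:
        return self.values.shape[3]


class MultitaperDecomposer(BaseEstimator, TransformerMixin):
    """Sliding-window multitaper transform of epochs onto a TF grid.

    At each (f, t): the window spans ``window_cycles / f`` seconds centered
    at ``t``; ``K`` Slepian tapers with time-half-bandwidth ``NW = T * W``
    (``W = smoothing_factor * f``) multiply the signal, which is then
    demodulated at ``f`` with phase referenced to the window center, so the
    coefficient's argument estimates the oscillation phase at time ``t``.
    Per-coordinate coefficients are the taper average.
    """

    def __init__(self, grid: TFGrid | None = None):
        self.grid = grid

    def fit(self, X: EpochSet, y=None):
        grid = self.grid if self.grid is not None else build_tf_grid()
        if np.any(grid.freqs >= X.sfreq / 2):
            raise ValueError(
                f"grid frequencies reach the Nyquist frequency {X.sfreq / 2} Hz"
            )
        self.grid_ = grid
        return self

    def transform(self, X: EpochSet) -> ComplexTFR:
        if not hasattr(self, "grid_"):
            self.fit(X)
        grid = self.grid_
        C, T, S, N = X.data.shape
        F, Ti = grid.n_freqs, grid.n_times
        coefs = np.full((C, T, S, F, Ti), np.nan, dtype=complex)
        valid = np.zeros((F, Ti), dtype=bool)
        sf = X.sfreq
        for fi, f in enumerate(grid.freqs):
            n_win = int(round(grid.window_duration(f) * sf))
            if n_win < 2 or n_win > N:
                continue
            nw = grid.window_duration(f) * grid.half_bandwidth(f)
            k = grid.n_tapers(f)
            tapers = np.atleast_2d(dpss(n_win, nw, Kmax=k))
            # demodulator, phase-referenced to the window center
            rel = (np.arange(n_win) - (n_win - 1) / 2.0) / sf
            demod = np.exp(-2j * np.pi * f * rel)
            kernel = (tapers * demod[None, :]).mean(axis=0)
            for ti, t in enumerate(grid.times):
                ic = int(round((t - X.tmin) * sf))
                start = ic - n_win // 2
                stop = start + n_win
                if start < 0 or stop > N:
                    continue
                seg = X.data[..., start:stop]
                # re-reference the phase to the requested grid time t (the
                # discrete window center sits up to half a sample away)
                tc = X.tmin + (start + (n_win - 1) / 2.0) / sf
                shift = np.exp(-2j * np.pi * f * (tc - t))
                coefs[..., fi, ti] = (seg @ kernel) * shift
                valid[fi, ti] = True
        return ComplexTFR(coefs, grid, valid)


def multitaper_tfr(epochs: EpochSet, grid: TFGrid) -> ComplexTFR:
    """Functional wrapper over :class:`MultitaperDecomposer`."""
    return MultitaperDecomposer(grid).fit(epochs).transform(epochs)


class PowerPatternExtractor(BaseEstimator, TransformerMixin):
    """dB power condition patterns: ``10*log10(|coef|^2 + eps)``, trial-averaged.

    The dB conversion precedes trial averaging (a geometric, not arithmetic,
    mean of power), and ``eps`` floors silent channels at a finite value.
    """

    def __init__(self, db_floor: float = DB_FLOOR):
        self.db_floor = db_floor

    def fit(self, X: ComplexTFR, y=None):
        return self

    def transform(self, X: ComplexTFR) -> PatternSet:
        power = np.abs(X.coefficients) ** 2
        db = 10.0 * np.log10(power + self.db_floor)
        vals = db.mean(axis=1)                     # (C, S, F, Ti); masked -> NaN
        vals = np.moveaxis(vals, (2, 3), (0, 1))   # (F, Ti, C, S)
        vals = np.where(X.valid[:, :, None, None], vals, np.nan)
        C = X.coefficients.shape[0]
        labels = [f"cond{i:03d}" for i in range(C)]
        return PatternSet("power", vals, X.grid, X.valid.copy(), labels)


class PhasePatternExtractor(BaseEstimator, TransformerMixin):
    """Phase condition patterns from trial-averaged unit resultants.

    Per sensor and condition the trial coefficients are unit-normalized
    (exact-zero coefficients are excluded rather than propagating NaN),
    averaged, and the resultant renormalized; features are the cosine
    parts for all sensors followed by the sine parts (2S total).  A zero
    resultant leaves that entry NaN (degenerate coordinate).
    """

    def fit(self, X: ComplexTFR, y=None):
        return self

    def transform(self, X: ComplexTFR) -> PatternSet:
        coefs = X.coefficients
        mag = np.abs(coefs)
        with np.errstate(invalid="ignore", divide="ignore"):
            nonzero = mag > 0
            unit = np.where(nonzero, coefs / np.where(nonzero, mag, 1.0), 0.0)
        counts = nonzero.sum(axis=1)               # (C, S, F, Ti)
        resultant = unit.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            resultant = np.where(counts > 0, resultant / np.maximum(counts, 1), np.nan)
            rmag = np.abs(resultant)
            u = np.where(rmag > 0, resultant / np.where(rmag > 0, rmag, 1.0), np.nan)
        u = np.moveaxis(u, (2, 3), (0, 1))         # (F, Ti, C, S)
        vals = np.concatenate([u.real, u.imag], axis=3)
        vals = np.where(X.valid[:, :, None, None], vals, np.nan)
        C = coefs.shape[0]
        labels = [f"cond{i:03d}" for i in range(C)]
        return PatternSet("phase", vals, X.grid, X.valid.copy(), labels)


def condition_power_patterns(tfr: ComplexTFR, db_floor: float = DB_FLOOR) -> PatternSet:
    """Functional wrapper over :class:`PowerPatternExtractor`."""
    return PowerPatternExtractor(db_floor=db_floor).transform(tfr)


def condition_phase_patterns(tfr: ComplexTFR) -> PatternSet:
    """Functional wrapper over :class:`PhasePatternExtractor`."""
    return PhasePatternExtractor().transform(tfr)
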