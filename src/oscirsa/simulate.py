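"""Synthetic epoched MEG-like recordings with planted representational structure.

Every downstream stage of the pipeline (time-frequency features, RDMs,
partial-correlation RSA, clustering, level/complexity scores) is validated
against data generated here, because the planted structure — which
condition geometry is carried by which oscillation, in power or in phase —
is known exactly.

The generative model per trial is a sum of oscillatory components plus 1/f
background noise:

* a *power-coded* component is a sinusoid whose amplitude (in dB) is a
  condition-specific sensor pattern; its phase is drawn uniformly at random
  per condition and trial (shared across sensors), so phase patterns carry
  no geometry — the trial-averaged phase direction is random per condition;
* a *phase-coded* component is a sinusoid of fixed amplitude whose phase
  offset is a condition-specific sensor pattern, so power patterns carry no
  condition information.

Condition geometries are supplied as (conditions x d) latent matrices and
embedded into sensor space through an orthonormal, zero-sum basis, which
preserves the latent rows' Pearson geometry exactly (see
:func:`_sensor_embedding`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .rdm import RDM, compute_rdm, vectorize_rdm

__all__ = [
    "PlantedComponent",
    "GeneratorSpec",
    "EpochSet",
    "ReferenceRDMPair",
    "LayeredFeatureSet",
    "simulate_meg_epochs",
    "simulate_subjects",
    "component_patterns",
    "simulate_reference_rdms",
    "simulate_layered_features",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PlantedComponent:
    """One condition-coded oscillation planted into the simulated epochs.

    Parameters
    ----------
    freq : float
        Oscillation frequency in Hz.
    time_window : (float, float)
        Onset and offset in seconds, within the epoch window.
    coding : {'power', 'phase', 'none'}
        Which signal aspect carries the condition geometry.
    geometry : (n_conditions, d) array or None
        Latent matrix whose row-wise Pearson structure is the planted RDM.
        Required unless ``coding='none'``.
    topography : (n_sensors,) array or None
        Per-sensor gain; ``None`` means uniform (all ones).
    amplitude_base : float
        Baseline oscillation amplitude (arbitrary units).
    amplitude_gain : float
        Power coding: dB range of the condition modulation.
    phase_gain : float
        Phase coding: radians spanned by the condition phase offsets;
        the embedded geometry is rescaled to unit max-abs so offsets stay
        within (-pi, pi] whenever ``phase_gain <= pi``.
    """

    freq: float
    time_window: tuple[float, float]
    coding: str = "power"
    geometry: np.ndarray | None = None
    topography: np.ndarray | None = None
    amplitude_base: float = 1.0
    amplitude_gain: float = 6.0
    phase_gain: float = 2.0

    def __post_init__(self) -> None:
        if self.coding not in ("power", "phase", "none"):
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.coding != "none" and self.geometry is None:
            raise ValueError("condition-coded component needs a geometry matrix")
        if self.geometry is not None:
            self.geometry = np.asarray(self.geometry, dtype=float)
        if self.time_window[0] >= self.time_window[1]:
            raise ValueError("component time_window must have on < off")
        if self.coding == "phase" and not 0 < self.phase_gain <= np.pi:
            raise ValueError("phase_gain must lie in (0, pi] to keep offsets in (-pi, pi]")


@dataclass
class GeneratorSpec:
    """Full description of one simulated dataset (one subject)."""

    n_conditions: int = 92
    n_sensors: int = 306
    n_trials: int = 20
    sfreq: float = 500.0
    epoch_window: tuple[float, float] = (-0.6, 1.2)
    components: list = field(default_factory=list)
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions < 3:
            raise ValueError("n_conditions must be >= 3")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("epoch_window must have t0 < t1")
        for comp in self.components:
            if comp.freq >= self.sfreq / 2:
                raise ValueError(
                    f"component frequency {comp.freq} Hz is at or above the "
                    f"Nyquist frequency {self.sfreq / 2} Hz"
                )
            if (comp.time_window[0] < self.epoch_window[0]
                    or comp.time_window[1] > self.epoch_window[1]):
                raise ValueError("component time_window must lie inside epoch_window")
            if comp.geometry is not None and comp.geometry.shape[0] != self.n_conditions:
                raise ValueError("component geometry rows must equal n_conditions")
            if (comp.topography is not None
                    and np.asarray(comp.topography).shape != (self.n_sensors,)):
                raise ValueError("topography must have one weight per sensor")
            if comp.topography is not None and not np.any(comp.topography):
                raise ValueError("topography must not be all zero")

    @property
    def n_samples(self) -> int:
        t0, t1 = self.epoch_window
        return int(round((t1 - t0) * self.sfreq))

    def times(self) -> np.ndarray:
        return self.epoch_window[0] + np.arange(self.n_samples) / self.sfreq


@dataclass
class EpochSet:
    """Condition-labelled epoched trials: (conditions, trials, sensors, samples)."""

    data: np.ndarray
    sfreq: float
    tmin: float
    condition_labels: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (conditions, trials, sensors, samples)")
        if len(self.condition_labels) != self.data.shape[0]:
            raise ValueError("condition label count mismatch")

    @property
    def n_conditions(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[2]

    @property
    def n_samples(self) -> int:
        return self.data.shape[3]

    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.sfreq


@dataclass
class ReferenceRDMPair:
    """Two reference geometries ('low'/V1-like and 'high'/IT-like).

    ``latent_low`` / ``latent_high`` are the pattern matrices the RDMs were
    built from; planting one of them as a component geometry makes that
    component's RDM match the corresponding reference exactly (noise-free).
    """

    rdm_low: RDM
    rdm_high: RDM
    achieved_correlation: float
    latent_low: np.ndarray | None = None
    latent_high: np.ndarray | None = None


@dataclass
class LayeredFeatureSet:
    """Ordered per-layer (images x features) matrices plus a centering set.

    The centering set is drawn over a disjoint image sample from the same
    per-layer distribution (same additive mean offset), emulating feature
    activations of an independent stimulus set.
    """

    layers: list
    centering: list
    name: str = "hierarchy"

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValueError("need at least 2 layers")
        if len(self.centering) != len(self.layers):
            raise ValueError("centering set must have one matrix per layer")
        n_img = {l.shape[0] for l in self.layers}
        if len(n_img) != 1:
            raise ValueError("all layers must share the image count")
        for li, (a, c) in enumerate(zip(self.layers, self.centering)):
            if a.shape[1] != c.shape[1]:
                raise ValueError(f"layer {li}: centering feature count mismatch")
            if c.shape[0] < 1:
                raise ValueError(f"layer {li}: empty centering set")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_images(self) -> int:
        return self.layers[0].shape[0]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _sensor_embedding(d: int, n_sensors: int, rng: np.random.Generator) -> np.ndarray:
    """A (d, n_sensors) basis with orthonormal rows, each summing to zero.

    Embedding row-centered latent rows through this basis preserves their
    pairwise Pearson correlations exactly: row sums of the basis are zero,
    so embedded patterns have zero sensor-mean, and orthonormality keeps
    inner products.  Requires d <= n_sensors - 1 (the all-ones direction is
    excluded).
    """
    if d > n_sensors - 1:
        raise ValueError(
            f"latent dimension {d} too large for {n_sensors} sensors "
            "(need d <= n_sensors - 1)"
        )
    m = rng.standard_normal((d, n_sensors))
    m -= m.mean(axis=1, keepdims=True)  # every row orthogonal to the ones vector
    q, _ = np.linalg.qr(m.T)            # columns orthonormal, span perp to ones
    return q[:, :d].T


def _embedded_geometry(comp: PlantedComponent, n_sensors: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Row-centered latent geometry mapped to sensor space (conditions x sensors)."""
    g = comp.geometry - comp.geometry.mean(axis=1, keepdims=True)
    basis = _sensor_embedding(g.shape[1], n_sensors, rng)
    return g @ basis


def _one_over_f_noise(shape: tuple, exponent: float, sfreq: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with a 1/f^exponent power spectrum along the last axis."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal(shape[:-1] + (freqs.size,))
            + 1j * rng.standard_normal(shape[:-1] + (freqs.size,))) * amp
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _component_patterns(comp: PlantedComponent, n_sensors: int,
                        seed: np.random.SeedSequence) -> dict:
    """Deterministic planted patterns for one component.

    Returns the condition x sensor dB-power pattern (power coding) or phase
    offsets plus the [cos, sin] feature pattern (phase coding), exactly as
    they should appear in downstream pattern sets.
    """
    rng = np.random.default_rng(seed)
    topo = (np.ones(n_sensors) if comp.topography is None
            else np.asarray(comp.topography, dtype=float))
    out: dict = {"topography": topo}
    if comp.coding == "none":
        out["amplitude"] = comp.amplitude_base * topo
        return out
    emb = _embedded_geometry(comp, n_sensors, rng)
    if comp.coding == "power":
        # dB pattern: baseline (incl. topography) + gain * embedded geometry.
        db = 20.0 * np.log10(comp.amplitude_base * np.abs(topo)[None, :]) \
            + comp.amplitude_gain * emb
        out["db_pattern"] = db
        out["amplitude"] = np.abs(topo)[None, :] * comp.amplitude_base \
            * 10.0 ** (comp.amplitude_gain * emb / 20.0)
        out["planted_rdm"] = compute_rdm(db)
    else:  # phase
        scale = np.abs(emb).max()
        phases = comp.phase_gain * (emb / scale if scale > 0 else emb)
        out["phase_offsets"] = phases
        feat = np.concatenate([np.cos(phases), np.sin(phases)], axis=1)
        out["phase_pattern"] = feat
        out["amplitude"] = comp.amplitude_base * np.abs(topo)
        out["planted_rdm"] = compute_rdm(feat)
    return out


def component_patterns(spec: GeneratorSpec) -> list[dict]:
    """Planted per-component patterns for ``spec`` (ground truth for tests).

    Reproduces, independently of :func:`simulate_meg_epochs`, the exact
    condition patterns each component injects — the oracle for planted-
    geometry recovery.
    """
    root = np.random.SeedSequence(spec.seed)
    comp_seeds = root.spawn(len(spec.components) + 1)
    return [_component_patterns(c, spec.n_sensors, s.spawn(2)[0])
            for c, s in zip(spec.components, comp_seeds)]


# ---------------------------------------------------------------------------
# epoch simulation
# ---------------------------------------------------------------------------

def simulate_meg_epochs(spec: GeneratorSpec) -> EpochSet:
    """Simulate condition-labelled epochs from a :class:`GeneratorSpec`.

    Deterministic given ``spec.seed``.  Each trial is the sum of the planted
    components (see module docstring for the power/phase coding model) plus
    1/f background noise.  An empty component list yields pure noise.
    """
    root = np.random.SeedSequence(spec.seed)
    comp_seeds = root.spawn(len(spec.components) + 1)
    noise_rng = np.random.default_rng(comp_seeds[-1])

    C, T, S, N = spec.n_conditions, spec.n_trials, spec.n_sensors, spec.n_samples
    t = spec.times()
    data = np.zeros((C, T, S, N))

    for comp, cseed in zip(spec.components, comp_seeds[:-1]):
        pat_seed, trial_seed = cseed.spawn(2)
        pats = _component_patterns(comp, S, pat_seed)
        crng = np.random.default_rng(trial_seed)
        on, off = comp.time_window
        sel = (t >= on) & (t < off)
        ts = t[sel]
        if comp.coding == "power":
            amp = pats["amplitude"]                       # (C, S)
            # phase random per condition and trial, shared across sensors:
            # phase patterns then carry no geometry (directions are random),
            # while the dB pattern picks up only a per-condition constant,
            # which Pearson RDMs ignore
            trial_phase = crng.uniform(-np.pi, np.pi, size=(C, T))
            osc = np.cos(2 * np.pi * comp.freq * ts[None, None, :]
                         + trial_phase[:, :, None])       # (C, T, n_sel)
            data[:, :, :, sel] += amp[:, None, :, None] * osc[:, :, None, :]
        elif comp.coding == "phase":
            amp = pats["amplitude"]                       # (S,)
            ph = pats["phase_offsets"]                    # (C, S)
            osc = np.cos(2 * np.pi * comp.freq * ts[None, None, :]
                         + ph[:, :, None])                # (C, S, n_sel)
            data[:, :, :, sel] += amp[None, None, :, None] * osc[:, None, :, :]
        else:  # 'none': condition-blind oscillation, random phase per trial
            amp = pats["amplitude"]                       # (S,)
            trial_phase = crng.uniform(-np.pi, np.pi, size=T)
            osc = np.cos(2 * np.pi * comp.freq * ts[None, :]
                         + trial_phase[:, None])          # (T, n_sel)
            data[:, :, :, sel] += amp[None, None, :, None] * osc[None, :, None, :]

    if spec.noise_scale > 0:
        data += spec.noise_scale * _one_over_f_noise(
            (C, T, S, N), spec.noise_exponent, spec.sfreq, noise_rng)

    labels = [f"cond{i:03d}" for i in range(C)]
    meta = {
        "seed": spec.seed,
        "sfreq": spec.sfreq,
        "epoch_window": list(spec.epoch_window),
        "n_trials": T,
        "noise_exponent": spec.noise_exponent,
        "noise_scale": spec.noise_scale,
        "n_components": len(spec.components),
    }
    return EpochSet(data, spec.sfreq, spec.epoch_window[0], labels, meta)


def simulate_subjects(spec: GeneratorSpec, n_subjects: int,
                      geometry_jitter_sd: float = 0.2) -> list[EpochSet]:
    """Simulate a group: shared component geometry plus per-subject jitter.

    Each subject gets an independent seed derived from ``spec.seed`` and a
    jittered copy of every component geometry (additive Gaussian with SD
    ``geometry_jitter_sd`` times the geometry SD), providing the between-
    subject variability that group-level paired tests require.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    root = np.random.SeedSequence((spec.seed, 9173))
    out = []
    for si, sseed in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(sseed)
        comps = []
        for comp in spec.components:
            if comp.geometry is not None and geometry_jitter_sd > 0:
                g = comp.geometry
                jit = geometry_jitter_sd * g.std() * rng.standard_normal(g.shape)
                comps.append(replace(comp, geometry=g + jit))
            else:
                comps.append(comp)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        out.append(simulate_meg_epochs(replace(spec, components=comps, seed=sub_seed)))
    return out


# ---------------------------------------------------------------------------
# reference RDM pairs
# ---------------------------------------------------------------------------

def simulate_reference_rdms(n_conditions: int, target_correlation: float = 0.3,
                            seed: int = 0, latent_dim: int = 100) -> ReferenceRDMPair:
    """Two reference RDMs with a controlled inter-RDM Pearson correlation.

    Both RDMs are 1 - Pearson matrices of Gaussian latent pattern matrices
    that share a common component:  ``L_k = a*Common + b*Unique_k`` with
    ``a^2 + b^2 = 1``.  For such latents the correlation between the two
    vectorized RDMs is ``a^4`` (the off-diagonal entries are, to leading
    order in 1/d, bilinear in the latent rows, and only the shared-by-shared
    term covaries), so the mixing weight is solved as ``a = target^(1/4)``.

    The achieved correlation per draw fluctuates with ``O(1/sqrt(n_pairs))``
    sampling noise; the documented calibration is on the mean over seeds.
    """
    if n_conditions < 3:
        raise ValueError("n_conditions must be >= 3")
    if not 0 <= target_correlation <= 1:
        raise ValueError(
            "target_correlation must lie in [0, 1]: the shared-component "
            "construction cannot plant negative RDM correlations"
        )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 551)))
    a = target_correlation ** 0.25
    b = np.sqrt(1.0 - a * a)
    common = rng.standard_normal((n_conditions, latent_dim))
    lat_low = a * common + b * rng.standard_normal((n_conditions, latent_dim))
    lat_high = a * common + b * rng.standard_normal((n_conditions, latent_dim))
    labels = [f"cond{i:03d}" for i in range(n_conditions)]
    rdm_low = compute_rdm(lat_low, labels)
    rdm_high = compute_rdm(lat_high, labels)
    achieved = float(np.corrcoef(vectorize_rdm(rdm_low), vectorize_rdm(rdm_high))[0, 1])
    if n_conditions < 6 and abs(achieved - target_correlation) > 0.2:
        warnings.warn(
            f"target correlation {target_correlation} not reached with only "
            f"{n_conditions} conditions (achieved {achieved:.3f})",
            stacklevel=2,
        )
    return ReferenceRDMPair(rdm_low, rdm_high, achieved, lat_low, lat_high)


# ---------------------------------------------------------------------------
# layered feature hierarchies
# ---------------------------------------------------------------------------

def simulate_layered_features(n_images: int, n_layers: int,
                              low_geometry: np.ndarray,
                              high_geometry: np.ndarray,
                              mean_offset_scale: float = 4.0,
                              seed: int = 0,
                              n_centering: int | None = None,
                              layer_noise_sd: float = 0.05,
                              name: str = "hierarchy") -> LayeredFeatureSet:
    """Layered features morphing from a low- to a high-level geometry.

    Layer ``l`` (1-based) mixes the two latent geometries with weight
    ``w = (l-1)/(n_layers-1)``: ``G_l = (1-w)*low + w*high`` plus a small
    independent perturbation, so the centered per-layer RDMs interpolate
    monotonically (in RDM correlation) between the two references.  Every
    layer additionally carries a fixed non-zero mean feature vector of
    magnitude ``mean_offset_scale`` times the layer's feature SD — the
    common offset that pushes all images into a remote corner of feature
    space and distorts correlation distances until it is centered out.

    The centering set is drawn over fresh (disjoint) images from the same
    per-layer distribution; its default size is ``4 * n_images``.
    """
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    low = np.asarray(low_geometry, dtype=float)
    high = np.asarray(high_geometry, dtype=float)
    if low.shape != high.shape or low.shape[0] != n_images:
        raise ValueError("low/high geometry must be (n_images x d) with matching shapes")
    if n_centering is None:
        n_centering = 4 * n_images
    if n_centering < 1:
        raise ValueError("n_centering must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 907)))
    d = low.shape[1]
    layers, centering = [], []
    for li in range(n_layers):
        w = li / (n_layers - 1)
        g = (1 - w) * low + w * high
        if layer_noise_sd > 0:
            g = g + layer_noise_sd * g.std() * rng.standard_normal(g.shape)
        sd = g.std()
        offset = rng.standard_normal(d)
        offset *= mean_offset_scale * sd / np.linalg.norm(offset) * np.sqrt(d)
        layers.append(g + offset[None, :])
        cent = sd * rng.standard_normal((n_centering, d)) + offset[None, :]
        centering.append(cent)
    return LayeredFeatureSet(layers, centering, name=name)
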