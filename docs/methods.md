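# Methods

## The model and what each stage assumes

The pipeline treats an epoched recording as a set of condition-labelled
trials `x[c, t, s, n]` (condition, trial, sensor, sample). At each
time–frequency coordinate it extracts two condition pattern sets and
summarises each as a representational dissimilarity matrix (RDM), i.e. the
geometry of the condition set as seen by that signal aspect at that
coordinate. Everything downstream — partial-correlation RSA against two
reference geometries, clustering of the RDM stack, level and complexity
scores — operates on these RDM vectors. The core assumption throughout is
that Pearson correlation over pattern entries is the right pattern
dissimilarity, and that RDM vectors (lower triangle, row-major — the fixed
order every module shares) are comparable across coordinates, subjects and
modalities.

## Time–frequency decomposition

Sliding-window multitaper demodulation. At frequency `f` the window spans
`window_cycles / f` seconds (default 2 cycles) and the spectral
half-bandwidth is `smoothing_factor · f` (default 0.4·f). The
time-half-bandwidth product is therefore constant, `NW = 0.8`, and the
taper count rule `K = max(1, floor(2NW − 1))` yields a single Slepian
taper at every frequency: the smoothing parameters sit below the
two-taper threshold, and we fall back to one prolate taper rather than
refusing to compute. The `0.4·f` smoothing is interpreted as a
*half*-bandwidth; the alternative (full bandwidth) would halve `NW` and
changes nothing about the K=1 fallback.

The demodulator is phase-referenced to the requested grid time (not the
discrete window center, which can sit half a sample away), so the
coefficient's argument estimates the oscillation phase at that time.
Windows that would overrun the epoch are masked, never zero-padded:
padding invents data and biases onset latencies. The default analysis grid
is 50 log-spaced frequencies from 3 to 100 Hz and 20 ms time steps from
−0.6 to 0.7 s (66 points).

Power patterns: per-trial `10·log10(|coef|² + ε)` with `ε = 1e−20` in
squared-amplitude units (a floor for numerically silent channels,
configurable), then averaged across trials — dB first, then average, a
geometric rather than arithmetic mean of power. Phase patterns: per-trial
coefficients are unit-normalized (exact zeros are excluded from the
average rather than propagating NaN — they arise only on synthetic
silence), averaged into a resultant, renormalized, and split into cosine
and sine blocks (2S features). A zero resultant marks the coordinate
degenerate.

## Reference fusion

`partial r = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²))` of an RDM vector
with each reference, controlling the other. The group test is a two-sided
one-sample t test of the raw partial correlations against zero (no Fisher
transform, matching the analysis the pipeline replicates; a Fisher-z
variant would be a one-line change) with Benjamini–Hochberg FDR at
α = 0.05 applied per map (per signal kind × reference), not pooled across
the 2×2 family — the per-panel reading of "significant against zero";
users wanting a pooled correction can concatenate maps before testing.

A caveat the synthetic tests make explicit: partial correlation removes
only the *linear* contribution of the controlled reference. An RDM that is
a noisy nonlinear image of one reference geometry retains a small but
consistent residual correlation with the other (correlated) reference, so
reference-level exclusivity should not be over-read from these maps; the
power/phase *signal-kind* dissociation, by contrast, is clean.

## Clustering and model selection

Correlation-distance k-means: rows are centered and unit-normalized,
assignment minimises `1 − Pearson` to the centroids, and each centroid
update is the member mean re-centered and renormalized — the standard
semantics of correlation-metric k-means. Five random initializations per
k; the solution with the lowest residual sum of within-cluster distances
(RSS) wins; an emptied cluster is re-seeded from the point farthest from
its centroid. Power and phase coordinates enter as equal rows with no
reweighting.

The elbow rule computes the discrete second derivative
`d2(k) = RSS(k+1) − 2·RSS(k) + RSS(k−1)` and returns the k at its global
maximum — the point where the drop into k is still large and the drop
beyond k is marginal. The *first local* maximum of d2 is deliberately not
used: an ordinary convex RSS decline puts a spurious local maximum at
k = 2, and on stacks with a planted 7-family structure that reading
selects 1–2 clusters while the curvature maximum recovers 7. The
one-step-earlier variant (`k_m − 1`) is available behind the
`pre_maximum` flag.

## Level and complexity scores

`L = σ((R_IT − R_V1)/(R_IT + R_V1))` with σ the logistic sigmoid. Note
that for non-negative partial correlations the ratio lies in [−1, 1], so
L is confined to ≈ [0.269, 0.731] rather than the full (0, 1); the
formula is implemented literally, and a non-positive denominator
(`R_IT + R_V1 ≤ 0`, typical of noise clusters) raises a "level undefined"
error rather than being clamped — a score midway between two non-matches
is not meaningful.

Surrogate significance permutes the centroid's dissimilarity entries
uniformly (default 10⁵ iterations) and recomputes the partial correlation;
`p = (#{r_surr ≥ r_obs} + 1)/(n_iter + 1)`, one-sided with add-one
correction. Entry permutation is the literal shuffling scheme; a stricter
variant that permutes condition rows/columns jointly (preserving RDM
structure) is available via `scheme='conditions'`.

Hierarchy complexity centers each layer's features by subtracting the mean
activation of an independent centering image set (default four images per
condition, 368 for 92 conditions), computes per-layer RDMs, Spearman-
correlates them with the centroid, and reports the argmax layer normalized
as `(argmax − 1)/(n_layers − 1)` so the endpoints hit exactly 0 and 1;
ties go to the smallest layer. `centroid_origin_distance` diagnoses the
offset problem centering solves: the norm of the image-mean feature vector
over the RMS per-feature SD, per layer.

## The synthetic generator

What it emulates: condition-coded oscillatory components in power and in
phase, 1/f background noise, coupled reference geometries, and layered
feature sets with a common mean offset. Defaults mirror the full-scale
recording setting (92 conditions, 306 sensors, 20 trials/condition,
500 Hz, epochs −0.6..1.2 s); desk-scale analyses reduce these explicitly.

* **Power coding**: trial = sinusoid whose amplitude is
  `topography · base · 10^(gain·E/20)`, with `E` the condition geometry
  embedded into sensor space through an orthonormal zero-sum basis (which
  preserves the latent rows' Pearson geometry exactly). The oscillation
  phase is uniform per (condition, trial) and shared across sensors. Two
  consequences: the trial-averaged phase direction is a geometry-free
  random angle (no leak of power-coded structure into phase patterns, a
  property an earlier shared-across-conditions variant violated through
  amplitude-dependent phase SNR), and in the noise-free case the
  demodulation's negative-frequency leakage is a per-condition constant in
  dB, so the recovered power RDM equals the planted one to machine
  precision.
* **Phase coding**: fixed amplitude, condition×sensor phase offsets
  `phase_gain · E / max|E|` (kept within (−π, π]). The recovered phase RDM
  matches a closed-form demodulation oracle to 1e−6; against the planted
  pattern RDM itself the match is limited by the real-signal leakage term
  to ~1e−2 — an inherent property of demodulating real sinusoids, not an
  implementation artifact.
* **Noise**: spectrally shaped Gaussian noise (`1/f^exponent` amplitude,
  random phases) per condition/trial/sensor, normalized to unit variance
  and scaled by `noise_scale`.
* **Reference pairs**: two latent matrices sharing a common component,
  `L_k = a·C + b·U_k`, `a = target^(1/4)` — for such latents the
  correlation between the two 1−Pearson RDM vectors is `a⁴` to leading
  order. Calibration is on the mean over draws: at 92 conditions the
  per-draw SD is ≈ 0.015, at 24 conditions ≈ 0.05–0.07. Negative targets
  are rejected (unreachable with a shared component); `target = 1` returns
  identical latents.
* **Hierarchies**: layer ℓ mixes the low and high latent geometries with
  weight `(ℓ−1)/(n_layers−1)` plus a small perturbation (`layer_noise_sd`,
  default 0.05), and every layer adds a fixed mean offset of magnitude
  `mean_offset_scale` (default 4) × feature SD; the centering set is drawn
  over fresh images from the same distribution.
* **Groups**: subjects share component geometries up to additive Gaussian
  jitter (`geometry_jitter_sd`, default 0.2 × geometry SD) and have
  independent seeds, giving the between-subject variability that paired
  tests need. Session effects (the empirical 20–30 trials pool two
  sessions) are not modelled.

What it does *not* emulate: head geometry and forward models, sensor noise
covariance, trial-count imbalance, artifacts, or any non-sinusoidal signal
structure. Passing recovery tests therefore demonstrates the pipeline's
correctness and sensitivity under its own assumptions, not performance on
empirical recordings.

## Problem sizes and determinism

The default `PipelineConfig` runs 24 conditions × 32 sensors × 20 trials ×
5 subjects on a 12×20 TF grid (~1 minute on one CPU); the test suite uses
the same or smaller scales, with 10 subjects for the dissociation check,
20 seeds for the recovery majorities, and 50 seeds for the null and
calibration checks. These sizes are the package's chosen desk scale; every
quantity scales to the full setting by configuration only. All randomness
flows from explicit seeds through `numpy.random.SeedSequence` spawning —
identical configs reproduce outputs bit-for-bit, and every output records
its seed and config hash.

## Known limitations

- The level score's literal formula cannot reach 0 or 1 and is undefined
  for non-positive `R_V1 + R_IT` (see above).
- The elbow criterion needs a genuine curvature maximum; exactly linear
  RSS curves raise a "no elbow" error by design.
- Partial-correlation maps inherit the linear-control caveat above.
- The multitaper implementation loops over TF coordinates; at the full
  306-sensor, 50×66-grid scale a single subject's transform is minutes,
  not seconds. The desk-scale defaults keep end-to-end runs interactive.
- The stored TF coefficient is the coherent taper average. Under the
  default smoothing rule K = 1 everywhere, so this is simply the single
  taper's coefficient; for user-set parameters yielding K > 1 the
  coherent average underestimates power relative to the conventional
  incoherent mean of per-taper powers (general-purpose multitaper
  libraries also typically refuse time-bandwidth products this small,
  which is why the transform is implemented here).
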