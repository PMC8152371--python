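"""Generator: reproducibility, planted structure, reference pairs, hierarchies."""

import numpy as np
import pytest

from oscirsa import (GeneratorSpec, PlantedComponent, TFGrid, compute_rdm,
                     component_patterns, condition_phase_patterns,
                     condition_power_patterns, multitaper_tfr, rdm_correlation,
                     simulate_layered_features, simulate_meg_epochs,
                     simulate_reference_rdms, simulate_subjects, vectorize_rdm)
from oscirsa.complexity import center_features
from oscirsa.rdm import RDM


class TestEpochSimulation:
    def test_default_spec_dimensions(self):
        spec = GeneratorSpec(n_trials=1, noise_scale=0.5, seed=0)
        ep = simulate_meg_epochs(spec)
        assert ep.n_conditions == 92
        assert ep.n_sensors == 306
        assert ep.n_samples == 900
        assert ep.sfreq == 500.0
        assert ep.times()[0] == pytest.approx(-0.6)

    def test_reproducible_given_seed(self):
        spec = GeneratorSpec(n_conditions=4, n_sensors=6, n_trials=2,
                             epoch_window=(-0.1, 0.3), seed=42)
        a = simulate_meg_epochs(spec)
        b = simulate_meg_epochs(spec)
        assert np.array_equal(a.data, b.data)

    def test_nyquist_violation_rejected(self):
        comp = PlantedComponent(freq=300.0, time_window=(0.0, 0.1),
                                coding="none")
        with pytest.raises(ValueError, match="Nyquist"):
            GeneratorSpec(n_conditions=4, n_sensors=6, components=[comp])

    def test_noise_only_rdms_unstructured(self):
        """No planted signal: off-diagonal power RDM entries center on 1."""
        spec = GeneratorSpec(n_conditions=12, n_sensors=24, n_trials=4,
                             epoch_window=(-0.2, 0.6), seed=3)
        ep = simulate_meg_epochs(spec)
        grid = TFGrid(np.array([8.0, 15.0]), np.array([0.1, 0.3]))
        pats = condition_power_patterns(multitaper_tfr(ep, grid))
        offdiag = [vectorize_rdm(compute_rdm(pats.values[fi, ti]).matrix).mean()
                   for fi in range(2) for ti in range(2)]
        assert abs(np.mean(offdiag) - 1.0) < 0.15

    def test_power_coded_rdm_matches_planted_exactly(self, power_coded_epochs):
        """Noise-free power RDM equals the planted dB-pattern RDM (1e-6)."""
        spec, ep = power_coded_epochs
        grid = TFGrid(np.array([20.0]), np.array([0.3]))
        pats = condition_power_patterns(multitaper_tfr(ep, grid))
        rdm = compute_rdm(pats.values[0, 0])
        truth = component_patterns(spec)[0]["planted_rdm"]
        assert np.abs(rdm.matrix - truth.matrix).max() < 1e-6

    def test_phase_coded_rdm_matches_demodulation_oracle(self, phase_coded_epochs):
        """Noise-free phase RDM equals a closed-form demodulation oracle (1e-6).

        A real sinusoid's windowed demodulation is
        ``coef = (A/2) (T0 e^{i theta} + T2 e^{-i theta})`` with taper sums
        T0 and T2 (the negative-frequency leakage); the oracle evaluates
        this closed form directly from the planted phases.  Against the
        planted-pattern RDM itself the match holds at the leakage scale.
        """
        from scipy.signal.windows import dpss

        spec, ep = phase_coded_epochs
        comp = spec.components[0]
        f = comp.freq
        grid = TFGrid(np.array([f]), np.array([0.4]))
        pats = condition_phase_patterns(multitaper_tfr(ep, grid))
        rdm = compute_rdm(pats.values[0, 0])

        truth = component_patterns(spec)[0]
        phases = truth["phase_offsets"]  # (C, S)
        sf = spec.sfreq
        n_win = int(round(2.0 / f * sf))
        taper = dpss(n_win, 0.8)
        t_grid = 0.4
        ic = int(round((t_grid - ep.tmin) * sf))
        start = ic - n_win // 2
        t_abs = ep.tmin + (start + np.arange(n_win)) / sf
        # closed-form windowed demodulation of cos(2 pi f t + phi_cs)
        kernel = taper * np.exp(-2j * np.pi * f * (t_abs - t_grid))
        coef = np.einsum("n,csn->cs", kernel,
                         np.cos(2 * np.pi * f * t_abs[None, None, :]
                                + phases[:, :, None]))
        u = coef / np.abs(coef)
        oracle = compute_rdm(np.concatenate([u.real, u.imag], axis=1))
        assert np.abs(rdm.matrix - oracle.matrix).max() < 1e-6
        planted = truth["planted_rdm"]
        assert np.abs(rdm.matrix - planted.matrix).max() < 1e-2

    def test_power_coding_absent_from_phase_patterns(self, power_coded_epochs):
        """Power-coded trials leave no sensor pattern in the phase features.

        The oscillation phase is shared across sensors, so each condition's
        cos and sin feature blocks are constant across sensors — the phase
        patterns hold no geometry, only a per-condition random angle.
        """
        spec, ep = power_coded_epochs
        grid = TFGrid(np.array([20.0]), np.array([0.3]))
        pats = condition_phase_patterns(multitaper_tfr(ep, grid))
        vals = pats.values[0, 0]
        s = ep.n_sensors
        assert vals[:, :s].std(axis=1).max() < 1e-9
        assert vals[:, s:].std(axis=1).max() < 1e-9

    def test_subjects_differ_but_share_structure(self, small_refs):
        comp = PlantedComponent(freq=12.0, time_window=(0.1, 0.5),
                                coding="power", geometry=small_refs.latent_low,
                                amplitude_gain=6.0)
        spec = GeneratorSpec(n_conditions=16, n_sensors=16, n_trials=2,
                             epoch_window=(-0.2, 0.7), components=[comp],
                             noise_scale=0.3, seed=21)
        subs = simulate_subjects(spec, 3, geometry_jitter_sd=0.2)
        assert len(subs) == 3
        assert not np.array_equal(subs[0].data, subs[1].data)
        grid = TFGrid(np.array([12.0]), np.array([0.3]))
        planted = vectorize_rdm(small_refs.rdm_low)
        for ep in subs:
            pats = condition_power_patterns(multitaper_tfr(ep, grid))
            v = vectorize_rdm(compute_rdm(pats.values[0, 0]).matrix)
            assert np.corrcoef(v, planted)[0, 1] > 0.5


class TestReferencePairs:
    def test_identical_latents_give_correlation_one(self):
        pair = simulate_reference_rdms(10, 1.0, seed=1)
        assert np.array_equal(pair.latent_low, pair.latent_high)
        assert pair.achieved_correlation == pytest.approx(1.0)

    def test_mean_achieved_correlation_near_target(self):
        vals = [simulate_reference_rdms(92, 0.3, seed=s).achieved_correlation
                for s in range(1, 51)]
        assert abs(np.mean(vals) - 0.3) < 0.05

    def test_rdm_validity(self):
        pair = simulate_reference_rdms(12, 0.3, seed=3)
        for rdm in (pair.rdm_low, pair.rdm_high):
            m = rdm.matrix
            assert np.allclose(m, m.T)
            assert np.all(np.diag(m) == 0)
            assert m.min() >= 0 and m.max() <= 2

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            simulate_reference_rdms(10, -0.3, seed=0)


class TestLayeredFeatures:
    def _geoms(self, seed=4, n=16, d=30):
        rng = np.random.default_rng(seed)
        return rng.standard_normal((n, d)), rng.standard_normal((n, d))

    def test_endpoint_layers_match_their_geometries(self):
        low, high = self._geoms()
        fs = simulate_layered_features(16, 6, low, high, seed=1)
        cfs = center_features(fs)
        low_rdm = compute_rdm(low)
        high_rdm = compute_rdm(high)
        first = compute_rdm(cfs.layers[0])
        last = compute_rdm(cfs.layers[-1])
        assert (rdm_correlation(first, low_rdm, "spearman")
                > rdm_correlation(first, high_rdm, "spearman"))
        assert (rdm_correlation(last, high_rdm, "spearman")
                > rdm_correlation(last, low_rdm, "spearman"))

    def test_monotone_morph_in_rdm_correlation(self):
        low, high = self._geoms(seed=5)
        fs = simulate_layered_features(16, 8, low, high, seed=2,
                                       layer_noise_sd=0.0)
        cfs = center_features(fs)
        high_rdm = compute_rdm(high)
        rs = [rdm_correlation(compute_rdm(a), high_rdm) for a in cfs.layers]
        assert np.all(np.diff(rs) > -1e-9)

    def test_zero_offset_makes_centering_a_no_op(self):
        # at the full stimulus-set scale (92 images, 4x92 centering images)
        low, high = self._geoms(seed=6, n=92, d=50)
        fs = simulate_layered_features(92, 5, low, high, mean_offset_scale=0.0,
                                       seed=3)
        cfs = center_features(fs)
        for raw, cent in zip(fs.layers, cfs.layers):
            r1 = compute_rdm(raw)
            r2 = compute_rdm(cent)
            assert abs(rdm_correlation(r1, r2) - 1.0) < 0.02

    def test_offset_distorts_uncentered_rdms(self):
        low, high = self._geoms(seed=7)
        fs = simulate_layered_features(16, 5, low, high, mean_offset_scale=6.0,
                                       seed=4)
        cfs = center_features(fs)
        high_rdm = compute_rdm(high)
        raw_r = rdm_correlation(compute_rdm(fs.layers[-1]), high_rdm)
        cent_r = rdm_correlation(compute_rdm(cfs.layers[-1]), high_rdm)
        assert cent_r > raw_r + 0.2

    def test_default_centering_set_size_is_four_per_condition(self):
        low, high = self._geoms(n=16)
        fs = simulate_layered_features(16, 5, low, high, seed=5)
        assert fs.centering[0].shape[0] == 64

    def test_single_layer_rejected(self):
        low, high = self._geoms()
        with pytest.raises(ValueError, match="n_layers"):
            simulate_layered_features(16, 1, low, high)
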