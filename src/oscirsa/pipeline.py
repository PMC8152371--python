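"""End-to-end orchestration: simulate -> TF -> RDM -> RSA -> cluster -> score.

A single :class:`PipelineConfig` drives all stages; every intermediate is
persisted under the output directory, every random draw flows from the
config's seeds, and a run report (JSON + Markdown) summarises counts,
the chosen cluster number, per-cluster level/complexity scores, and the
fraction of significant coordinates, together with the config hash for
provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .cluster import distance_to_centroid_maps, rank_clusters, sweep_k
from .complexity import hierarchy_complexity, level_score, surrogate_test
from .rdm import RDMStack, build_rdm_stack, vectorize_rdm
from .rsa import group_significance, partial_correlation, rsa_map
from .simulate import (GeneratorSpec, PlantedComponent, simulate_layered_features,
                       simulate_reference_rdms, simulate_subjects)
from .tf import build_tf_grid, condition_phase_patterns, condition_power_patterns, \
    multitaper_tfr

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run, loadable from YAML.

    The default scale (24 conditions, 32 sensors, 5 subjects, a 12 x 20
    TF grid) is a desk-scale reduction that keeps every stage's behavior
    while completing in minutes on one CPU; the full-scale values are
    plain overrides.
    """

    # generator
    n_conditions: int = 24
    n_sensors: int = 32
    n_trials: int = 20
    sfreq: float = 500.0
    epoch_window: tuple = (-0.6, 1.2)
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    n_subjects: int = 5
    geometry_jitter_sd: float = 0.2
    target_reference_correlation: float = 0.3
    latent_dim: int = 20
    # planted components: list of dicts mirroring PlantedComponent fields,
    # with geometry given symbolically as 'low' or 'high' (reference latents)
    components: list = field(default_factory=lambda: [
        {"freq": 11.0, "time_window": (0.1, 0.6), "coding": "power",
         "geometry": "low", "amplitude_gain": 6.0, "amplitude_base": 1.0},
        {"freq": 5.0, "time_window": (0.2, 0.9), "coding": "phase",
         "geometry": "high", "phase_gain": 2.0, "amplitude_base": 1.0},
    ])
    # TF grid
    fmin: float = 4.0
    fmax: float = 40.0
    n_freqs: int = 12
    tmin: float = -0.2
    tmax: float = 0.95
    tstep: float = 0.06
    window_cycles: float = 2.0
    smoothing_factor: float = 0.4
    # RSA
    alpha: float = 0.05
    # clustering
    k_max: int = 8
    replicates: int = 5
    # complexity
    surrogate_iterations: int = 2000
    hierarchy_layers: tuple = (5, 8, 13)
    mean_offset_scale: float = 4.0
    # bookkeeping
    seed: int = 0
    output_dir: str = "oscirsa_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage summaries plus provenance; serialized next to the outputs."""

    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed,
                "stages": self.stages}

    def to_markdown(self) -> str:
        lines = ["# oscirsa run report", "",
                 f"- config hash: `{self.config_hash}`",
                 f"- seed: {self.seed}", ""]
        for name, info in self.stages.items():
            lines.append(f"## {name}")
            for k, v in info.items():
                if k == "elapsed_s":
                    lines.append(f"- {k}: {v:.2f}")
                else:
                    lines.append(f"- {k}: {v}")
            lines.append("")
        return "\n".join(lines)


def _resolve_components(cfg: PipelineConfig, refs) -> list[PlantedComponent]:
    comps = []
    for c in cfg.components:
        c = dict(c)
        geom = c.pop("geometry", None)
        if geom == "low":
            geometry = refs.latent_low
        elif geom == "high":
            geometry = refs.latent_high
        elif geom is None:
            geometry = None
        else:
            geometry = np.asarray(geom, dtype=float)
        comps.append(PlantedComponent(geometry=geometry,
                                      time_window=tuple(c.pop("time_window")), **c))
    return comps


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage, persisting intermediates under ``output_dir``.

    Idempotent given the config (all randomness flows from ``config.seed``);
    a failing stage aborts with its name while earlier outputs stay on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report = RunReport(config.config_hash(), config.seed)
    stage = "setup"
    t_all = time.time()
    try:
        # -- simulate -------------------------------------------------------
        stage = "simulate"
        t0 = time.time()
        refs = simulate_reference_rdms(config.n_conditions,
                                       config.target_reference_correlation,
                                       seed=config.seed,
                                       latent_dim=config.latent_dim)
        io.save_rdm(out / "reference_low.tsv", refs.rdm_low)
        io.save_rdm(out / "reference_high.tsv", refs.rdm_high)
        comps = _resolve_components(config, refs)
        spec = GeneratorSpec(
            n_conditions=config.n_conditions, n_sensors=config.n_sensors,
            n_trials=config.n_trials, sfreq=config.sfreq,
            epoch_window=tuple(config.epoch_window), components=comps,
            noise_exponent=config.noise_exponent,
            noise_scale=config.noise_scale, seed=config.seed)
        subjects = simulate_subjects(spec, config.n_subjects,
                                     config.geometry_jitter_sd)
        for si, ep in enumerate(subjects):
            io.save_epochs(out / f"epochs_sub{si:02d}", ep)
        report.stages[stage] = {
            "n_subjects": len(subjects),
            "n_conditions": config.n_conditions,
            "n_sensors": config.n_sensors,
            "n_trials": config.n_trials,
            "reference_correlation": round(refs.achieved_correlation, 4),
            "elapsed_s": time.time() - t0,
        }
        logger.info("stage=%s seed=%d elapsed=%.2fs", stage, config.seed,
                    time.time() - t0)

        # -- TF features and RDM stacks ------------------------------------
        stage = "tf_rdm"
        t0 = time.time()
        grid = build_tf_grid(config.fmin, config.fmax, config.n_freqs,
                             config.tmin, config.tmax, config.tstep,
                             config.window_cycles, config.smoothing_factor)
        stacks = []
        for si, ep in enumerate(subjects):
            tfr = multitaper_tfr(ep, grid)
            stack = build_rdm_stack([condition_power_patterns(tfr),
                                     condition_phase_patterns(tfr)])
            io.save_stack(out / f"stack_sub{si:02d}", stack)
            stacks.append(stack)
        n_unmasked = int(stacks[0].valid.sum())
        report.stages[stage] = {
            "n_freqs": grid.n_freqs, "n_times": grid.n_times,
            "n_unmasked_coords": n_unmasked,
            "rdm_vector_length": stacks[0].n_pairs,
            "elapsed_s": time.time() - t0,
        }
        logger.info("stage=%s seed=%d elapsed=%.2fs", stage, config.seed,
                    time.time() - t0)

        # -- RSA maps and group stats --------------------------------------
        stage = "rsa"
        t0 = time.time()
        per_subject = []  # (low_map, high_map) per subject
        for si, stack in enumerate(stacks):
            low, high = rsa_map(stack, refs)
            per_subject.append((low, high))
            for tgt, m in (("low", low), ("high", high)):
                for kind in m.kinds:
                    io.save_map(out / f"rsa_sub{si:02d}_{kind}_{tgt}",
                                m.kind_map(kind), grid,
                                {"subject": si, "kind": kind, "target": tgt})
        n_maps = len(per_subject) * 2 * len(per_subject[0][0].kinds)
        sig_fractions = {}
        for tgt_idx, tgt in enumerate(("low", "high")):
            for kind in per_subject[0][0].kinds:
                maps = [ms[tgt_idx].kind_map(kind) for ms in per_subject]
                gr = group_significance(maps, alpha=config.alpha)
                io.save_map(out / f"group_t_{kind}_{tgt}", gr.t_map, grid)
                io.save_map(out / f"group_fdr_{kind}_{tgt}",
                            gr.fdr_mask.astype(float), grid)
                defined = np.isfinite(gr.p_map)
                frac = float(gr.fdr_mask.sum() / max(defined.sum(), 1))
                sig_fractions[f"{kind}_{tgt}"] = round(frac, 4)
        report.stages[stage] = {
            "maps_per_subject": 2 * len(per_subject[0][0].kinds),
            "n_maps": n_maps,
            "significant_fraction": sig_fractions,
            "alpha": config.alpha,
            "elapsed_s": time.time() - t0,
        }
        logger.info("stage=%s seed=%d elapsed=%.2fs", stage, config.seed,
                    time.time() - t0)

        # -- clustering -----------------------------------------------------
        stage = "cluster"
        t0 = time.time()
        mean_vectors = np.mean([s.vectors for s in stacks], axis=0)
        valid = np.all([s.valid for s in stacks], axis=0)
        group_stack = RDMStack(mean_vectors, list(stacks[0].kinds),
                               stacks[0].freqs, stacks[0].times,
                               list(stacks[0].labels), valid)
        result = sweep_k(group_stack, k_max=config.k_max,
                         replicates=config.replicates, seed=config.seed)
        io.save_cluster_result(out / "clusters", result)
        dmaps = distance_to_centroid_maps(result, group_stack)
        for c, per_kind in dmaps.maps.items():
            for kind, m in per_kind.items():
                io.save_map(out / f"cluster{c}_dist_{kind}", m, grid)
        ranking = rank_clusters(result, group_stack)
        report.stages[stage] = {
            "chosen_k": result.chosen_k,
            "ranking": ranking,
            "n_points_clustered": len(result.assignments),
            "elapsed_s": time.time() - t0,
        }
        logger.info("stage=%s seed=%d elapsed=%.2fs", stage, config.seed,
                    time.time() - t0)

        # -- level and complexity scores -----------------------------------
        stage = "score"
        t0 = time.time()
        vlow = vectorize_rdm(refs.rdm_low)
        vhigh = vectorize_rdm(refs.rdm_high)
        hier = [simulate_layered_features(
                    config.n_conditions, nl, refs.latent_low, refs.latent_high,
                    mean_offset_scale=config.mean_offset_scale,
                    seed=config.seed + 101 + i, name=f"hier{nl}")
                for i, nl in enumerate(config.hierarchy_layers)]
        scores = {}
        for c in range(result.chosen_k):
            cen = result.centroids[c]
            r_v1 = partial_correlation(cen, vlow, vhigh)
            r_it = partial_correlation(cen, vhigh, vlow)
            entry = {"r_v1": round(r_v1, 4), "r_it": round(r_it, 4)}
            try:
                entry["level"] = round(level_score(r_v1, r_it), 4)
            except ValueError as err:
                entry["level"] = None
                entry["level_note"] = str(err)
            entry["p_low"] = surrogate_test(
                cen, vlow, vhigh, n_iter=config.surrogate_iterations,
                seed=config.seed * 1000 + c * 2)
            entry["p_high"] = surrogate_test(
                cen, vhigh, vlow, n_iter=config.surrogate_iterations,
                seed=config.seed * 1000 + c * 2 + 1)
            comp = hierarchy_complexity(cen, hier)
            entry["mean_position"] = round(comp.mean_position, 4)
            entry["per_hierarchy"] = [
                {"name": p["name"], "argmax_layer": p["argmax_layer"],
                 "n_layers": p["n_layers"], "position": round(p["position"], 4)}
                for p in comp.per_hierarchy]
            scores[str(c)] = entry
        io.save_json(out / "scores.json", {"kind": "scores", "clusters": scores})
        report.stages[stage] = {
            "n_clusters_scored": result.chosen_k,
            "surrogate_iterations": config.surrogate_iterations,
            "elapsed_s": time.time() - t0,
        }
        logger.info("stage=%s seed=%d elapsed=%.2fs", stage, config.seed,
                    time.time() - t0)
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {err}"
        ) from err

    report.stages["total"] = {"elapsed_s": time.time() - t_all}
    (out / "report.json").write_text(json.dumps(report.to_json(), indent=1))
    (out / "report.md").write_text(report.to_markdown())
    return report
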