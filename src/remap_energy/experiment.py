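"""End-to-end experiment driver: presets, staged pipeline, manifests.

The 'paper' preset carries the full-scale hyperparameters (256 px scenes,
128 px crops, 2 × 2,048 hidden units, T = 6, F = 7, lr 5e-4, batch 1,024,
τ = 0.1, 8 negatives, 91 classes); it is provided as a configuration, not as
something a laptop should run.  The 'desk' preset is the scaled-down study:
64 px scenes, 32 px crops, 2 × 256 hidden units, ~500 train / 50 test
scenes, batch 64 — sized to train in minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .analysis import (
    collect_activations,
    compute_similarity,
    feedback_inhibition_stats,
    fit_allocentric_decoder,
    hypothesis_correlation,
    lesion_experiment,
    select_units_by_beta,
    spatial_memory_analysis,
)
from .controls import (
    build_static_templates,
    compare_conditions,
    default_eval_indices,
    evaluate_all_conditions,
)
from .datasets import (
    SequenceDataset,
    WorldConfig,
    make_datasets,
    reduced_crop_side,
    shuffle_efference,
)
from .network import NetworkConfig, NetworkWeights
from .training import ObjectiveSpec, TrainingConfig, train_model

__all__ = ["ExperimentConfig", "PRESETS", "run_experiment", "select_display_sequence"]


@dataclass(frozen=True)
class ExperimentConfig:
    name: str
    world: WorldConfig
    network: NetworkConfig
    training: TrainingConfig
    objective_spec: ObjectiveSpec
    n_train_scenes: int
    n_test_scenes: int
    lesion_k: int
    decode_sequences_per_scene: int
    requires_force_on_cpu: bool = False

    def stage_hash(self, *parts: str) -> str:
        payload = json.dumps(
            {
                "world": dataclasses.asdict(self.world),
                "network": dataclasses.asdict(self.network),
                "training": dataclasses.asdict(self.training),
                "spec": dataclasses.asdict(self.objective_spec),
                "n_train": self.n_train_scenes,
                "n_test": self.n_test_scenes,
                "parts": parts,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _desk() -> ExperimentConfig:
    return ExperimentConfig(
        name="desk",
        world=WorldConfig(side=64, crop_side=32, n_fixations=7,
                          sequences_per_scene=10, n_texture_classes=8),
        network=NetworkConfig(crop_side=32, n_hidden_layers=2, hidden_size=256,
                              steps_per_fixation=6, scene_side=64),
        training=TrainingConfig(base_lr=0.002, batch_size=8, epochs=100,
                                objective="energy", lr_schedule="late-cosine",
                                final_lr_fraction=0.05, val_sequences=16),
        objective_spec=ObjectiveSpec(n_classes=8),
        n_train_scenes=500,
        n_test_scenes=50,
        lesion_k=4,
        decode_sequences_per_scene=3,
    )


def _paper() -> ExperimentConfig:
    return ExperimentConfig(
        name="paper",
        world=WorldConfig(side=256, crop_side=128, n_fixations=7, sequences_per_scene=10),
        network=NetworkConfig(crop_side=128, n_hidden_layers=2, hidden_size=2048,
                              steps_per_fixation=6, scene_side=256),
        training=TrainingConfig(base_lr=0.0005, batch_size=1024, epochs=150,
                                objective="energy"),
        objective_spec=ObjectiveSpec(temperature=0.1, n_negatives=8,
                                     positive_lag=2, n_classes=91),
        n_train_scenes=48236,
        n_test_scenes=2051,
        lesion_k=22,
        decode_sequences_per_scene=10,
        requires_force_on_cpu=True,
    )


def _variant(name: str, **net_updates) -> ExperimentConfig:
    base = _desk()
    return replace(base, name=name, network=replace(base.network, **net_updates))


PRESETS = {
    "desk": _desk,
    "paper": _paper,
    # architecture-variant presets for the robustness suite
    "desk-T4": lambda: _variant("desk-T4", steps_per_fixation=4),
    "desk-T8": lambda: _variant("desk-T8", steps_per_fixation=8),
    "desk-1x512": lambda: _variant("desk-1x512", n_hidden_layers=1, hidden_size=512),
    "desk-3x128": lambda: _variant("desk-3x128", n_hidden_layers=3, hidden_size=128),
}


def get_preset(name: str) -> ExperimentConfig:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")


def select_display_sequence(
    dataset: SequenceDataset,
    per_scene_loss: dict[str, float],
    sd_threshold: float = 0.25,
) -> str:
    """Scene with the lowest mean model loss among high-contrast scenes.

    Scenes qualify when their pixel standard deviation exceeds the threshold;
    if none do, the threshold is halved with a warning until one qualifies.
    """
    thr = sd_threshold
    while True:
        qualified = [
            sid for sid, s in dataset.scenes.items()
            if s.pixels.std() > thr and sid in per_scene_loss
        ]
        if qualified:
            break
        warnings.warn(f"no scene passes pixel-sd threshold {thr}; lowering")
        thr /= 2
        if thr < 1e-6:
            qualified = list(per_scene_loss)
            break
    return min(qualified, key=lambda sid: per_scene_loss[sid])


def _derive_seeds(master_seed: int, n: int) -> list[int]:
    return [int(x) for x in np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)]


def run_experiment(
    config: ExperimentConfig | str,
    seed: int = 0,
    out_dir: str | Path = "runs",
    force: bool = False,
    controls: tuple[str, ...] = ("no_efference", "small_crop"),
    verbose: bool = False,
) -> dict:
    """Dataset → training (energy + controls) → evaluation → analyses.

    Stage outputs are cached under a config-hash directory; re-running with
    the identical config and seed reuses them.  Returns the run manifest.
    """
    if isinstance(config, str):
        config = get_preset(config)
    if config.requires_force_on_cpu and not force:
        raise RuntimeError(
            f"preset {config.name!r} is full-scale; pass force=True to run it anyway"
        )
    out_dir = Path(out_dir) / f"{config.name}-{seed}-{config.stage_hash()}"
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    manifest = {
        "config_hash": config.stage_hash(),
        "preset": config.name,
        "seed": seed,
        "started": time.time(),
        "artifacts": {},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    seeds = _derive_seeds(seed, 8)

    # ---------------------------------------------------------------- data
    train_ds, test_ds = make_datasets(
        config.n_train_scenes, config.n_test_scenes, config.world, seeds[0]
    )
    shuffled_ds = shuffle_efference(test_ds, seeds[1])

    # ---------------------------------------------------------------- train
    def fit(tag: str, net: NetworkConfig, objective: str,
            ds=None, val=None) -> NetworkWeights:
        path = out_dir / f"weights-{tag}.npz"
        if path.exists() and not force:
            return NetworkWeights.load(path)
        tc = replace(config.training, objective=objective, seed=seeds[2])
        w, log = train_model(ds if ds is not None else train_ds, net, tc,
                             config.objective_spec,
                             val_dataset=val if val is not None else test_ds,
                             verbose=verbose)
        w.save(path, meta={"objective": objective, "seed": seeds[2]})
        log.to_frame().to_csv(out_dir / f"log-{tag}.csv", index=False)
        return w

    models = {"model": fit("energy", config.network, "energy")}
    models["untrained"] = fit("untrained", config.network, "none")
    if "no_efference" in controls:
        models["no_efference"] = fit(
            "no-efference", replace(config.network, use_efference=False), "energy"
        )
    if "small_crop" in controls:
        small_side = reduced_crop_side(config.network.crop_side)
        small_world = replace(config.world, crop_side=small_side)
        models["small_crop"] = fit(
            "small-crop",
            replace(config.network, crop_side=small_side),
            "energy",
            ds=replace(train_ds, config=small_world),
            val=replace(test_ds, config=small_world),
        )

    # ------------------------------------------------------------- evaluate
    templates = build_static_templates(train_ds)
    indices = default_eval_indices(test_ds)
    table = evaluate_all_conditions(models, test_ds, shuffled_ds, templates, indices)
    table.to_csv(out_dir / "loss_table.csv", index=False)
    losses = {c: g["loss"].to_numpy() for c, g in table.groupby("condition")}
    comparisons = {
        f"model_vs_{c}": dataclasses.asdict(
            compare_conditions(losses["model"], v, "model", c)
        )
        for c, v in losses.items()
        if c != "model"
    }
    (out_dir / "comparisons.json").write_text(json.dumps(comparisons, indent=2, default=str))

    # -------------------------------------------------------------- analyze
    results: dict = {
        "losses_mean": {c: float(v.mean()) for c, v in losses.items()},
        "n_eval_fixations": int(len(indices) * config.world.n_fixations),
        "n_eval_sequences": int(len(indices)),
    }
    results["comparisons"] = {
        k: {"t": v["t_statistic"], "p": v["p_value"]} for k, v in comparisons.items()
    }

    from .training import energy_loss as _energy_loss

    crops_e, effs_e, _ = test_ds.batch_arrays(indices)
    results["energy_loss_test"] = {}
    for tag in ("model", "untrained", "no_efference"):
        if tag in models:
            from .network import run_batch as _run_batch

            results["energy_loss_test"][tag] = float(
                _energy_loss(_run_batch(crops_e, effs_e, models[tag]))
            )

    fb = feedback_inhibition_stats(models["model"], test_ds, indices)
    results["feedback"] = {"mean": fb.mean, "ci": fb.ci, "n": fb.n}

    mat = collect_activations(
        models["model"], test_ds,
        max_sequences_per_scene=config.decode_sequences_per_scene,
    )
    fit_dec = fit_allocentric_decoder(mat, seed=seeds[3])
    mat_untrained = collect_activations(
        models["untrained"], test_ds,
        max_sequences_per_scene=config.decode_sequences_per_scene,
    )
    fit_untrained = fit_allocentric_decoder(mat_untrained, seed=seeds[3])
    results["decoding"] = {
        "r2_energy": fit_dec.r2.tolist(),
        "r2_untrained": fit_untrained.r2.tolist(),
        "n_rows": int(mat.X.shape[0]),
    }

    targeted = select_units_by_beta(fit_dec, config.lesion_k)
    lesion = lesion_experiment(models["model"], test_ds, targeted, seeds[4], indices)
    results["lesion"] = {
        "targeted_ids": lesion.targeted_ids.tolist(),
        "mean_intact": float(lesion.loss_intact.mean()),
        "mean_targeted": float(lesion.loss_targeted.mean()),
        "mean_random": float(lesion.loss_random.mean()),
        "p_targeted_vs_random": lesion.comparisons["targeted_vs_random"].p_value,
        "targeted_mean_activity": lesion.targeted_mean_activity,
        "population_mean_activity": lesion.population_mean_activity,
    }

    sim_intact = compute_similarity(models["model"], test_ds, indices)
    fit_intact = hypothesis_correlation(sim_intact)
    mask = np.zeros(config.network.n_hidden_total, dtype=bool)
    mask[targeted] = True
    sim_lesioned = compute_similarity(models["model"], test_ds, indices, lesion_mask=mask)
    fit_lesioned = hypothesis_correlation(sim_lesioned)
    results["similarity"] = {
        "intact": {"r_future": fit_intact.mean_r_future, "r_current": fit_intact.mean_r_current},
        "lesioned": {"r_future": fit_lesioned.mean_r_future, "r_current": fit_lesioned.mean_r_current},
    }

    from .controls import model_fixation_loss
    from .network import run_batch

    crops, effs, centers = test_ds.batch_arrays(indices)
    model_losses = model_fixation_loss(run_batch(crops, effs, models["model"]))
    memory = spatial_memory_analysis(model_losses, centers)
    results["spatial_memory"] = {
        "table": memory.table.tolist(),
        "thresholds": memory.thresholds,
    }

    # clustering of the strongest allocentric-coding units
    from .analysis import cluster_allocentric_units, unit_spatial_profiles

    n_cluster_units = min(4 * config.lesion_k, config.network.n_hidden_total)
    top_units = select_units_by_beta(fit_dec, n_cluster_units)
    profiles, coords_seen = unit_spatial_profiles(
        models["model"], test_ds, top_units, indices=indices
    )
    clusters = cluster_allocentric_units(profiles, coords_seen, seed=seeds[5])
    results["clustering"] = {
        "k": clusters.k,
        "silhouette_by_k": {str(k): v for k, v in clusters.silhouette_by_k.items()},
        "unit_ids": top_units.tolist(),
        "assignments": clusters.assignments.tolist(),
        "degenerate": clusters.degenerate,
    }

    per_scene = {
        test_ds.sequences[i].scene_id: float(model_losses[r].mean())
        for r, i in enumerate(indices)
    }
    results["display_scene"] = select_display_sequence(test_ds, per_scene)

    from .plots import plot_condition_losses, plot_similarity_matrix

    plot_condition_losses(table, out_dir / "condition_losses.png")
    plot_similarity_matrix(
        np.mean(sim_intact.matrices, axis=0),
        out_dir / "similarity_intact.png",
        config.network.steps_per_fixation,
    )

    (out_dir / "results.json").write_text(json.dumps(results, indent=2))
    manifest.update(
        finished=time.time(),
        artifacts={
            "loss_table": "loss_table.csv",
            "comparisons": "comparisons.json",
            "results": "results.json",
        },
    )
    manifest_path.write_text(json.dumps(manifest, indent=2))
    results["out_dir"] = str(out_dir)
    results["manifest"] = manifest
    return results
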