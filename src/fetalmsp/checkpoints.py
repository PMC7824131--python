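"""Training-front-end helpers and npz checkpoints for the two-stage system."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import gan, seed as seed_mod
from .pipeline import RunConfig, align_flip, crop_cube, filter_by_angle, CaseRecord


def train_pipeline_models(samples, config: RunConfig):
    """Align, filter and train stage 1 + stage 2 on the whole cohort."""
    records = [
        filter_by_angle(CaseRecord(case_id=str(i), sample=align_flip(s)),
                        config.angle_baseline)
        for i, s in enumerate(samples)
    ]
    train = [r.sample for r in records if r.included]
    if not train:
        raise ValueError("no cases left after the angle filter")
    seed_models, _ = seed_mod.train_seed_networks(
        train, config.seed_config, seed=config.rng_seed + 1000
    )
    hw = config.crop_half_width
    vols = [crop_cube(s.volume, s.gt_seed, hw) for s in train]
    msks = [crop_cube(s.gt_mask, s.gt_seed, hw) for s in train]
    generator, _, _ = gan.train_gan(
        vols, msks, config.gen_config, config.critic_config, config.loss_weights,
        epochs=config.gan_epochs, batch_size=config.gan_batch, lr=config.gan_lr,
        seed=config.rng_seed + 2000,
    )
    return generator, seed_models


def save_pipeline_models(path, generator: gan.Generator,
                         seed_models: seed_mod.SeedModels, config: RunConfig) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, a in enumerate(generator.state_dict()):
        arrays[f"gen_{i}"] = a
    for name in ("seg_sagittal", "seg_axial", "det_axial", "det_coronal"):
        for i, a in enumerate(getattr(seed_models, name).state_dict()):
            arrays[f"{name}_{i}"] = a
    meta = {
        "volume_size": generator.volume_size,
        "slice_size": seed_models.det_axial.slice_size,
        "gen_config": dataclasses.asdict(generator.config),
        "seed_config": dataclasses.asdict(seed_models.config),
        "crop_half_width": config.crop_half_width,
        "angle_baseline": config.angle_baseline,
        "fit_thresholds": list(config.fit_thresholds),
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_pipeline_models(path):
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        rng = np.random.default_rng(0)
        gen_cfg = gan.GeneratorConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in meta["gen_config"].items()
        })
        generator = gan.Generator(gen_cfg, meta["volume_size"], rng)
        generator.load_state_dict(
            [data[f"gen_{i}"] for i in range(len(generator.state_dict()))]
        )
        seed_cfg = seed_mod.SeedCascadeConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in meta["seed_config"].items()
        })
        models = seed_mod.SeedModels(
            seg_sagittal=seed_mod.UNetASPP(seed_cfg, rng),
            seg_axial=seed_mod.UNetASPP(seed_cfg, rng),
            det_axial=seed_mod.DetectNet(seed_cfg, meta["slice_size"], rng),
            det_coronal=seed_mod.DetectNet(seed_cfg, meta["slice_size"], rng),
            config=seed_cfg,
        )
        for name in ("seg_sagittal", "seg_axial", "det_axial", "det_coronal"):
            net = getattr(models, name)
            net.load_state_dict(
                [data[f"{name}_{i}"] for i in range(len(net.state_dict()))]
            )
        config = RunConfig(
            crop_half_width=meta["crop_half_width"],
            angle_baseline=meta["angle_baseline"],
            fit_thresholds=tuple(meta["fit_thresholds"]),
            gen_config=gen_cfg,
            seed_config=seed_cfg,
        )
    return generator, models, config
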