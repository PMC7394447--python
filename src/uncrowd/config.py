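"""YAML config handling and run manifests."""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import yaml

from .capsule_core import NetworkConfig
from .heads_losses import LossWeights, MarginParams
from .stimuli import AugmentationConfig, StimulusConfig
from .training import TrainConfig


def _build(cls, section: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for k, v in section.items():
        if isinstance(v, list):
            v = tuple(tuple(i) if isinstance(i, list) else i for i in v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path: str | Path | None = None, experiment: int = 1,
                overrides: dict | None = None) -> dict:
    """Build all config objects from a YAML file plus overrides.

    Returns {'stimulus', 'augmentation', 'network', 'train'} with the
    network class count and image shape made consistent with the
    experiment and canvas.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        for section, vals in overrides.items():
            raw.setdefault(section, {}).update(vals)
    stim = _build(StimulusConfig, raw.get("stimulus", {}))
    aug = _build(AugmentationConfig, raw.get("augmentation", {}))
    net_section = dict(raw.get("network", {}))
    net_section.setdefault("image_shape", (stim.height, stim.width))
    net_section.setdefault("n_capsule_types", 7 if experiment == 1 else 4)
    net = _build(NetworkConfig, net_section)
    train_section = dict(raw.get("training", {}))
    for key, cls in (("weights", LossWeights), ("margin", MarginParams),
                     ("stimulus", StimulusConfig),
                     ("augmentation", AugmentationConfig)):
        if key in train_section:
            train_section[key] = _build(cls, train_section[key])
    train_section.setdefault("experiment", experiment)
    train = _build(TrainConfig, train_section)
    train.stimulus = stim
    train.augmentation = aug
    return {"stimulus": stim, "augmentation": aug, "network": net,
            "train": train}


def scaled_config(experiment: int, steps: int | None = None) -> dict:
    """CPU-scale configuration used by the test suite and acceptance report.

    Reduced canvas/channels and a coarse primary-capsule grid; experiment 1
    trains with 3 routing iterations and evaluates at 8 (the model analogue
    of the long stimulus durations used in the human uncrowding experiment),
    experiment 2 trains at 8 and sweeps 1-8.
    """
    stim = StimulusConfig.small()
    if experiment == 1:
        net = NetworkConfig(
            image_shape=(stim.height, stim.width),
            conv_layers=((3, 12, 2), (3, 12, 2)), n_capsule_types=7,
            primary_dim=8, secondary_dim=12, primary_stride=3,
            recon_hidden=(64, 128), vernier_decoder_hidden=32,
            routing_iterations=8)
    else:
        net = NetworkConfig(
            image_shape=(stim.height, stim.width),
            conv_layers=((3, 8, 2), (3, 8, 2)), n_capsule_types=4,
            primary_dim=6, secondary_dim=8, primary_stride=3,
            recon_hidden=(64, 128), vernier_decoder_hidden=32,
            routing_iterations=8)
    aug = AugmentationConfig(noise_sd_range=(0.0, 0.1))
    train = TrainConfig(
        experiment=experiment,
        steps=steps if steps is not None else (4000 if experiment == 1 else 2000),
        batch_size=24, restart_period=600,
        routing_iterations_train=3 if experiment == 1 else 8,
        vernier_fraction=0.3, stimulus=stim, augmentation=aug)
    return {"stimulus": stim, "augmentation": aug, "network": net,
            "train": train}


def write_manifest(run_dir: str | Path, config: dict, seeds: list[int],
                   stages: dict) -> Path:
    """JSON manifest tying every artifact of a run to its configuration."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seeds": seeds,
        "config": {k: dataclasses.asdict(v) for k, v in config.items()},
        "stages": stages,
    }
    path = run_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
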