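"""End-to-end training of capsule and comparison networks.

Adam (batch 48, learning rate 4e-4) with cosine-decay warm restarts;
training data are generated on the fly and never contain vernier+flanker
compositions. Ensembles train several independently seeded networks;
experiment-2 ensembles are pruned by the ceiling/floor exclusion rule.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import heads_losses as hl
from .alt_architectures import AltHeadConfig, AltNetwork
from .capsule_core import CapsuleNetwork, CapsuleState, NetworkConfig
from .heads_losses import DecoderHeads, LossWeights, MarginParams
from .stimuli import (EXP1_CLASSES, EXP2_CLASSES, AugmentationConfig,
                      StimulusConfig, StimulusFrame, build_training_set)
from .autograd import sigmoid

LOSS_COLUMNS = ("step", "L_shape", "L_vernier", "L_reps", "L_recon", "L_loc",
                "L_total")


@dataclass
class TrainConfig:
    experiment: int = 1
    steps: int = 2000
    batch_size: int = 48
    learning_rate: float = 0.0004
    restart_period: int = 500         # cosine warm-restart period (steps)
    restart_mult: float = 2.0
    seed: int = 0
    routing_iterations_train: int | None = None  # None -> NetworkConfig value
    vernier_fraction: float | None = None   # None -> uniform class sampling
    weights: LossWeights = field(default_factory=LossWeights)
    margin: MarginParams = field(default_factory=MarginParams)
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)


@dataclass
class TrainedModel:
    """A network plus its decoder heads and label space."""

    net: object                     # CapsuleNetwork | AltNetwork
    heads: DecoderHeads
    classes: tuple[str, ...]
    experiment: int
    stimulus: StimulusConfig
    trained: bool = False

    @property
    def arch(self) -> str:
        return self.net.arch

    @property
    def is_capsnet(self) -> bool:
        return isinstance(self.net, CapsuleNetwork)

    def parameters(self) -> dict:
        merged = {f"net.{k}": v for k, v in self.net.params.items()}
        merged.update({f"heads.{k}": v for k, v in self.heads.params.items()})
        return merged

    def forward_outputs(self, images: np.ndarray,
                        iterations: int | None = None,
                        recon_mask: np.ndarray | None = None) -> dict:
        out = self.net.forward(images, iterations=iterations)
        if self.is_capsnet:
            secondary: CapsuleState = out
            shape_presence = hl.capsule_shape_norms(secondary)
            vernier_scores = self.heads.decode_vernier(
                secondary, vernier_index=self.classes.index("vernier"))
            source = secondary
        else:
            shape_presence = sigmoid(self.heads.decode_shape_scores(out))
            vernier_scores = self.heads.decode_vernier(out)
            source = out
        return {
            "secondary": out,
            "shape_presence": shape_presence,
            "vernier_scores": vernier_scores,
            "repetition_scores": self.heads.decode_repetitions(source),
            "location_scores": self.heads.decode_location(source),
            "reconstruction": self.heads.reconstruct(source, mask=recon_mask),
        }


@dataclass
class EnsembleResult:
    models: list[TrainedModel]
    histories: list[dict]
    seeds: list[int]
    accuracies: list[dict] = field(default_factory=list)  # per-network
    excluded: list[bool] = field(default_factory=list)
    failures: list[tuple[int, str]] = field(default_factory=list)

    def retained(self) -> list[TrainedModel]:
        if not self.excluded:
            return list(self.models)
        return [m for m, ex in zip(self.models, self.excluded) if not ex]


# ------------------------------------------------------------------ optimizer
class Adam:
    def __init__(self, params: dict, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def lr_schedule(step: int, config: TrainConfig) -> float:
    """Cosine decay with warm restarts; returns the base rate at restarts."""
    if step < 0:
        raise ValueError("step must be >= 0")
    period = config.restart_period
    t = step
    while t >= period:
        t -= period
        period = int(round(period * config.restart_mult))
    return config.learning_rate * 0.5 * (1.0 + np.cos(np.pi * t / period))


# ------------------------------------------------------------------- batches
def make_model(arch: str, net_config: NetworkConfig, experiment: int,
               stimulus: StimulusConfig, rng: np.random.Generator,
               head_config: AltHeadConfig | None = None) -> TrainedModel:
    classes = EXP1_CLASSES if experiment == 1 else EXP2_CLASSES
    if net_config.n_capsule_types != len(classes):
        raise ValueError(
            f"n_capsule_types must equal the class count ({len(classes)})")
    if net_config.image_shape != (stimulus.height, stimulus.width):
        raise ValueError("network image_shape must match the stimulus canvas")
    if arch == "capsnet":
        net = CapsuleNetwork(net_config, rng)
        heads = DecoderHeads(net_config, rng, len(classes), whole_layer=False)
    else:
        head_config = head_config or AltHeadConfig(head_kind=arch)
        if head_config.head_kind != arch:
            raise ValueError("head_config.head_kind must match arch")
        net = AltNetwork(net_config, head_config, rng)
        heads = DecoderHeads(net_config, rng, len(classes), whole_layer=True,
                             last_layer_size=net.units)
    return TrainedModel(net, heads, tuple(classes), experiment, stimulus)


def _batch_arrays(frames: list[StimulusFrame], classes: tuple[str, ...]):
    images = np.stack([f.image for f in frames])
    class_idx = np.array([classes.index(f.shape_class) for f in frames])
    onehot = np.eye(len(classes))[class_idx]
    offsets = [f.vernier_offset for f in frames]
    reps = np.array([f.n_repetitions for f in frames])
    xy = np.array([f.target_location for f in frames])
    return images, onehot, offsets, reps, xy


def compute_losses(model: TrainedModel, frames: list[StimulusFrame],
                   config: TrainConfig,
                   iterations: int | None = None) -> tuple:
    """Total loss Tensor plus the scalar value of each component."""
    images, onehot, offsets, reps, xy = _batch_arrays(frames, model.classes)
    recon_mask = onehot if model.is_capsnet else None
    out = model.forward_outputs(images, iterations=iterations,
                                recon_mask=recon_mask)
    components = {
        "shape_type": hl.margin_loss(out["shape_presence"], onehot,
                                     config.margin),
        "vernier_offset": hl.vernier_offset_loss(out["vernier_scores"], offsets),
        "reconstruction": hl.reconstruction_loss(images, out["reconstruction"]),
    }
    if model.experiment == 1:
        # repetitions: exp-1 groups are 1/3/5; verniers count as 1
        components["shape_repetitions"] = hl.shape_repetition_loss(
            out["repetition_scores"], reps)
        components["location"] = hl.location_loss(
            out["location_scores"], xy,
            (model.stimulus.height, model.stimulus.width))
    total = hl.total_loss(components, config.weights, model.experiment)
    values = {k: float(v.item()) for k, v in components.items()}
    values["total"] = float(total.item())
    return total, values


# ------------------------------------------------------------------- training
def train_one(model: TrainedModel, config: TrainConfig,
              rng: np.random.Generator | None = None,
              log_csv: str | Path | None = None) -> dict:
    """Train a single network; returns the loss history."""
    rng = rng or np.random.default_rng(config.seed)
    params = model.parameters()
    opt = Adam(params)
    history = {k: [] for k in ("step", "shape_type", "vernier_offset",
                               "shape_repetitions", "reconstruction",
                               "location", "total")}
    its = config.routing_iterations_train
    for step in range(config.steps):
        frames = build_training_set(model.experiment, config.batch_size, rng,
                                    model.stimulus, config.augmentation,
                                    vernier_fraction=config.vernier_fraction)
        for f in frames:  # never train on composed vernier+flanker frames
            if (f.vernier_offset != "none") != (f.shape_class == "vernier"):
                raise AssertionError(
                    "training frame mixes vernier and flanker content")
        total, values = compute_losses(model, frames, config, iterations=its)
        if not np.isfinite(values["total"]):
            raise RuntimeError(
                f"training diverged at step {step}: loss={values['total']}")
        opt.zero_grad()
        total.backward()
        opt.step(lr_schedule(step, config))
        history["step"].append(step)
        for k in ("shape_type", "vernier_offset", "shape_repetitions",
                  "reconstruction", "location"):
            history[k].append(values.get(k, 0.0))
        history["total"].append(values["total"])
    model.trained = True
    if log_csv is not None:
        write_loss_history(history, log_csv)
    return history


def write_loss_history(history: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LOSS_COLUMNS)
        for i, step in enumerate(history["step"]):
            writer.writerow([step,
                             history["shape_type"][i],
                             history["vernier_offset"][i],
                             history["shape_repetitions"][i],
                             history["reconstruction"][i],
                             history["location"][i],
                             history["total"][i]])


def train_ensemble(n_networks: int, seeds: list[int] | None,
                   net_config: NetworkConfig, train_config: TrainConfig,
                   arch: str = "capsnet",
                   head_config: AltHeadConfig | None = None) -> EnsembleResult:
    """Independently seeded trainings; failures are logged, not fatal."""
    if seeds is None:
        seeds = [train_config.seed + i for i in range(n_networks)]
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    models, histories, kept_seeds, failures = [], [], [], []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        try:
            model = make_model(arch, net_config, train_config.experiment,
                               train_config.stimulus, rng,
                               head_config=head_config)
            cfg = TrainConfig(**{**train_config.__dict__, "seed": seed})
            history = train_one(model, cfg, rng)
        except Exception as exc:  # keep surviving networks
            failures.append((seed, str(exc)))
            continue
        models.append(model)
        histories.append(history)
        kept_seeds.append(seed)
    return EnsembleResult(models, histories, kept_seeds, failures=failures)


# -------------------------------------------------------------- exclusion rule
def is_excluded(lines_acc: float, cuboids_acc: float,
                ceiling: float = 95.0, floor: float = 55.0) -> bool:
    """Exclude iff BOTH conditions are at ceiling or BOTH at floor (percent)."""
    both_ceiling = lines_acc >= ceiling and cuboids_acc >= ceiling
    both_floor = lines_acc <= floor and cuboids_acc <= floor
    return both_ceiling or both_floor


def exclusion_filter(ensemble: EnsembleResult,
                     accuracies: list[dict]) -> EnsembleResult:
    """Apply the experiment-2 ceiling/floor rule to an ensemble.

    ``accuracies``: one dict per network with percent-correct values under
    keys 'lines' and 'cuboids'.
    """
    if len(accuracies) != len(ensemble.models):
        raise ValueError("one accuracy record per network required")
    excluded = []
    for acc in accuracies:
        if "lines" not in acc or "cuboids" not in acc:
            raise ValueError("accuracies need 'lines' and 'cuboids' entries")
        excluded.append(is_excluded(acc["lines"], acc["cuboids"]))
    ensemble.accuracies = list(accuracies)
    ensemble.excluded = excluded
    return ensemble
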