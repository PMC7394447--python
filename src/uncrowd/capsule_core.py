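"""Capsule network forward computation.

Two valid convolutions with ELU, a third convolution reshaped into primary
capsules, and a secondary capsule layer reached through iterative
routing-by-agreement. Each (child position/type, parent type) pair carries
its own vote transform by default; position-shared transforms are available
as a lighter-weight option but lose fine position information.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autograd import Tensor, conv2d, einsum2, elu, parameter, softmax

SQUASH_EPS = 1e-16


@dataclass
class NetworkConfig:
    """Architecture hyperparameters; defaults fit one shape per receptive field."""

    conv_layers: tuple[tuple[int, int, int], ...] = ((3, 16, 2), (3, 16, 2))
    n_capsule_types: int = 7          # m: equals the experiment's class count
    primary_dim: int = 8              # n
    secondary_dim: int = 16
    routing_iterations: int = 3
    primary_kernel: int = 3
    primary_stride: int = 2
    vernier_decoder_hidden: int = 64
    recon_hidden: tuple[int, int] = (512, 1024)
    recon_sigmoid: bool = True
    share_position_weights: bool = False
    image_shape: tuple[int, int] = (40, 95)
    max_routing_iterations: int = 8

    def __post_init__(self):
        if len(self.conv_layers) != 2:
            raise ValueError("exactly two convolutional feature layers required")
        if not 1 <= self.routing_iterations <= 8:
            raise ValueError("routing_iterations must lie in [1, 8]")

    def conv_output_shape(self) -> tuple[int, int]:
        h, w = self.image_shape
        for k, _c, s in self.conv_layers:
            if h < k or w < k:
                raise ValueError(f"image too small for conv kernel {k}")
            h, w = (h - k) // s + 1, (w - k) // s + 1
        return h, w

    def primary_grid_shape(self) -> tuple[int, int]:
        h, w = self.conv_output_shape()
        k, s = self.primary_kernel, self.primary_stride
        if h < k or w < k:
            raise ValueError("feature map too small for the primary-capsule conv")
        return (h - k) // s + 1, (w - k) // s + 1

    @property
    def n_children(self) -> int:
        h, w = self.primary_grid_shape()
        return self.n_capsule_types * h * w

    @property
    def secondary_neurons(self) -> int:
        return self.n_capsule_types * self.secondary_dim


@dataclass
class CapsuleState:
    """Activation vectors of one capsule layer: (batch, capsules, dim)."""

    vectors: Tensor
    n_types: int

    @property
    def norms(self) -> Tensor:
        return norms_of(self.vectors)


def norms_of(vectors: Tensor) -> Tensor:
    sq = (vectors * vectors).sum(axis=-1)
    return (sq + SQUASH_EPS).sqrt()


def squash(s: Tensor) -> Tensor:
    """v = (|s|^2 / (1 + |s|^2)) * s / |s|; norm strictly below 1."""
    n2 = (s * s).sum(axis=-1, keepdims=True)
    scale = n2 / ((1.0 + n2) * (n2 + SQUASH_EPS).sqrt())
    return s * scale


def conv_features(image: Tensor, params: dict, config: NetworkConfig) -> Tensor:
    """Two valid convolutions, each followed by an ELU."""
    x = image
    for i, (k, _c, s) in enumerate(config.conv_layers):
        if x.shape[2] < k or x.shape[3] < k:
            raise ValueError(f"input too small at conv layer {i + 1} (kernel {k})")
        x = elu(conv2d(x, params[f"conv{i + 1}_w"], params[f"conv{i + 1}_b"],
                       stride=s))
    return x


def form_primary_capsules(features: Tensor, params: dict,
                          config: NetworkConfig) -> CapsuleState:
    """Third convolution reshaped into m capsule types of dimension n."""
    m, n = config.n_capsule_types, config.primary_dim
    w = params["conv3_w"]
    if w.shape[0] % (m * n) != 0 or w.shape[0] != m * n:
        raise ValueError(
            f"primary conv channels ({w.shape[0]}) must equal m*n ({m * n})")
    x = conv2d(features, w, params["conv3_b"], stride=config.primary_stride)
    B, _, H, W = x.shape
    # (B, m, n, H, W) -> (B, m, H, W, n) -> (B, m*H*W, n)
    caps = x.reshape(B, m, n, H, W).transpose((0, 1, 3, 4, 2))
    caps = caps.reshape(B, m * H * W, n)
    return CapsuleState(squash(caps), n_types=m)


def predict_votes(primary: CapsuleState, transform: Tensor,
                  config: NetworkConfig) -> Tensor:
    """Linear vote of each child capsule for each parent type.

    transform: (m_child_types, n_parents, n, d_out) when weights are shared
    across positions, else (n_children, n_parents, n, d_out).
    Returns (B, n_children, n_parents, d_out).
    """
    u = primary.vectors
    B, NC, n = u.shape
    m = primary.n_types
    P = NC // m
    n_parents, d_out = transform.shape[1], transform.shape[3]
    if config.share_position_weights:
        if transform.shape[0] != m:
            raise ValueError("transform type axis must match child types")
        u4 = u.reshape(B, m, P, n)
        votes = einsum2("bmpn,mjnd->bmpjd", u4, transform)
        votes = votes.reshape(B, NC, n_parents, d_out)
    else:
        if transform.shape[0] != NC:
            raise ValueError("transform child axis must match child count")
        votes = einsum2("bcn,cjnd->bcjd", u, transform)
    return votes


def route(votes: Tensor, iterations: int) -> CapsuleState:
    """Routing by agreement over (B, children, parents, d) votes.

    Coupling coefficients are the softmax over parents of logits that start
    at zero and grow by the scalar product between each vote and the
    parent's squashed output.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    B, NC, NP, d = votes.shape
    logits = Tensor(np.zeros((B, NC, NP), dtype=votes.data.dtype))
    v = None
    for it in range(iterations):
        couplings = softmax(logits, axis=2)
        s = einsum2("bcp,bcpd->bpd", couplings, votes)
        v = squash(s)
        if it < iterations - 1:
            agreement = einsum2("bcpd,bpd->bcp", votes, v)
            logits = logits + agreement
    return CapsuleState(v, n_types=NP)


def routing_couplings(votes: np.ndarray, iterations: int) -> np.ndarray:
    """Coupling coefficients after the last update (diagnostics / tests)."""
    votes_t = Tensor(votes)
    B, NC, NP, d = votes.shape
    logits = np.zeros((B, NC, NP, 1))
    couplings = None
    for it in range(iterations):
        e = np.exp(logits - logits.max(axis=2, keepdims=True))
        couplings = e / e.sum(axis=2, keepdims=True)
        s = (couplings * votes).sum(axis=1)
        n2 = (s * s).sum(axis=-1, keepdims=True)
        v = s * (n2 / ((1 + n2) * np.sqrt(n2 + SQUASH_EPS)))
        if it < iterations - 1:
            logits = logits + (votes * v[:, None]).sum(axis=-1, keepdims=True)
    return couplings[..., 0]


# ------------------------------------------------------------------ the model
class CapsuleNetwork:
    """Full capsule model: conv stack + primary capsules + routed secondaries."""

    arch = "capsnet"

    def __init__(self, config: NetworkConfig, rng: np.random.Generator,
                 dtype=np.float32):
        self.config = config
        self.dtype = dtype
        self.params: dict[str, Tensor] = {}
        self._init_params(rng)

    # weights: He-style fan-in scaling
    def _init_params(self, rng):
        cfg = self.config
        c_in = 1
        for i, (k, c, _s) in enumerate(cfg.conv_layers):
            scale = np.sqrt(2.0 / (c_in * k * k))
            self._add(f"conv{i + 1}_w", rng.normal(0, scale, (c, c_in, k, k)))
            self._add(f"conv{i + 1}_b", np.zeros(c))
            c_in = c
        m, n = cfg.n_capsule_types, cfg.primary_dim
        k = cfg.primary_kernel
        scale = np.sqrt(2.0 / (c_in * k * k))
        self._add("conv3_w", rng.normal(0, scale, (m * n, c_in, k, k)))
        self._add("conv3_b", np.zeros(m * n))
        d = cfg.secondary_dim
        if cfg.share_position_weights:
            shape = (m, m, n, d)
        else:
            shape = (cfg.n_children, m, n, d)
        self._add("route_w", rng.normal(0, np.sqrt(1.0 / n), shape))

    def _add(self, name, arr):
        self.params[name] = parameter(np.asarray(arr, dtype=self.dtype))

    # ------------------------------------------------------------- forward
    def forward(self, images: np.ndarray,
                iterations: int | None = None) -> CapsuleState:
        """images: (B, H, W) or (B, 1, H, W) -> secondary CapsuleState."""
        cfg = self.config
        iterations = cfg.routing_iterations if iterations is None else iterations
        if iterations > cfg.max_routing_iterations:
            warnings.warn(
                f"routing iterations {iterations} exceed the configured "
                f"maximum {cfg.max_routing_iterations}")
        x = np.asarray(images, dtype=self.dtype)
        if x.ndim == 3:
            x = x[:, None]
        feats = conv_features(Tensor(x), self.params, cfg)
        primary = form_primary_capsules(feats, self.params, cfg)
        votes = predict_votes(primary, self.params["route_w"], cfg)
        return route(votes, iterations)

    # ---------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **{k: v.data for k, v in self.params.items()})
        sidecar = path.with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump({"arch": self.arch, "config": asdict(self.config)}, fh,
                      indent=2, default=list)

    def load(self, path: str | Path) -> None:
        with np.load(Path(path)) as data:
            for k in self.params:
                self.params[k].data = data[k].astype(self.dtype)
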