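"""Decoders reading out of the secondary capsule layer and the loss terms.

Loss terms: margin loss on capsule norms (shape type), softmax cross
entropies for vernier offset / shape repetitions / location bins, and a
summed squared-error reconstruction loss. Total-loss weights default to
(0.5, 1, 0.4, 0.0005, 0.1); experiment 2 uses only the shape-type,
vernier-offset and reconstruction terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import (Tensor, elu, parameter, relu, sigmoid,
                       softmax_cross_entropy)
from .capsule_core import CapsuleState, NetworkConfig, norms_of

VERNIER_LABELS = ("left", "right", "none")
REPETITION_LABELS = (1, 3, 5)


@dataclass
class MarginParams:
    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_down: float = 0.5

    def __post_init__(self):
        if not 0 < self.m_minus < self.m_plus < 1:
            raise ValueError("need 0 < m_minus < m_plus < 1")
        if self.lambda_down <= 0:
            raise ValueError("lambda_down must be positive")


@dataclass
class LossWeights:
    alpha_shape_type: float = 0.5
    alpha_vernier_offset: float = 1.0
    alpha_shape_repetitions: float = 0.4
    alpha_reconstruction: float = 0.0005
    alpha_location: float = 0.1


# ------------------------------------------------------------------- losses
def margin_loss(norms: Tensor, targets: np.ndarray,
                params: MarginParams | None = None) -> Tensor:
    """Sum_k T_k max(0, m+ - |v_k|)^2 + lambda (1-T_k) max(0, |v_k| - m-)^2.

    ``norms``: (B, K) capsule norms in [0, 1). ``targets``: (B, K) indicator
    of present classes (several classes may be present at once). Returns the
    batch-mean loss.
    """
    params = params or MarginParams()
    if np.any(norms.data >= 1.0):
        raise ValueError("capsule norms must be < 1 (post-squash invariant)")
    t = np.asarray(targets, dtype=norms.data.dtype)
    present = relu(params.m_plus - norms) ** 2
    absent = relu(norms - params.m_minus) ** 2
    per_item = (present * t + absent * ((1.0 - t) * params.lambda_down)).sum(axis=-1)
    return per_item.mean()


def cross_entropy_loss(scores: Tensor, class_indices: np.ndarray,
                       n_classes: int | None = None) -> Tensor:
    """Mean softmax cross entropy against integer class labels."""
    n_classes = scores.shape[-1] if n_classes is None else n_classes
    onehot = np.eye(n_classes, dtype=scores.data.dtype)[np.asarray(class_indices)]
    return softmax_cross_entropy(scores, onehot).mean()


def vernier_offset_loss(scores: Tensor, true_offsets) -> Tensor:
    idx = np.array([VERNIER_LABELS.index(o) for o in np.atleast_1d(true_offsets)])
    return cross_entropy_loss(scores, idx, 3)


def shape_repetition_loss(scores: Tensor, true_repetitions) -> Tensor:
    reps = np.atleast_1d(true_repetitions)
    bad = set(reps.tolist()) - set(REPETITION_LABELS)
    if bad:
        raise ValueError(f"unmapped repetition values {sorted(bad)}")
    idx = np.array([REPETITION_LABELS.index(r) for r in reps])
    return cross_entropy_loss(scores, idx, 3)


def reconstruction_loss(input_image: np.ndarray, reconstruction: Tensor) -> Tensor:
    """Summed squared pixel difference, averaged over the batch."""
    target = np.asarray(input_image, dtype=reconstruction.data.dtype)
    if target.shape[-2:] != reconstruction.shape[-2:]:
        raise ValueError(
            f"image {target.shape} vs reconstruction {reconstruction.shape}")
    diff = reconstruction - Tensor(target.reshape(reconstruction.shape))
    per_image = (diff * diff).sum(axis=(-2, -1)) if diff.ndim > 2 else \
        (diff * diff).sum()
    return per_image.mean() if per_image.ndim else per_image


def location_loss(location_scores: tuple[Tensor, Tensor],
                  true_xy: np.ndarray, canvas_shape: tuple[int, int],
                  bin_width: int = 1) -> Tensor:
    """Sum over the x and y axes of per-axis coordinate cross entropies."""
    xy = np.atleast_2d(np.asarray(true_xy))
    h, w = canvas_shape
    if np.any(xy[:, 0] < 0) or np.any(xy[:, 0] >= w) or \
       np.any(xy[:, 1] < 0) or np.any(xy[:, 1] >= h):
        raise ValueError("true coordinates outside the canvas")
    total = None
    for axis, extent in ((0, w), (1, h)):
        scores = location_scores[axis]
        bins = scores.shape[-1]
        idx = np.minimum(xy[:, axis] // bin_width, bins - 1).astype(int)
        term = cross_entropy_loss(scores, idx, bins)
        total = term if total is None else total + term
    return total


def total_loss(components: dict, weights: LossWeights | None = None,
               experiment: int = 1) -> Tensor:
    """Weighted sum of the loss terms for the given experiment."""
    weights = weights or LossWeights()
    if experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    for name, comp in components.items():
        val = comp.data if isinstance(comp, Tensor) else comp
        if np.any(np.asarray(val) < 0):
            raise ValueError(f"negative loss component {name!r}")
    def get(name):
        c = components[name]
        return c if isinstance(c, Tensor) else Tensor(np.asarray(c, dtype=float))
    out = (weights.alpha_shape_type * get("shape_type")
           + weights.alpha_vernier_offset * get("vernier_offset")
           + weights.alpha_reconstruction * get("reconstruction"))
    if experiment == 1:
        out = (out + weights.alpha_shape_repetitions * get("shape_repetitions")
               + weights.alpha_location * get("location"))
    return out


# ------------------------------------------------------------------ decoders
class DecoderHeads:
    """All decoder heads; reads a (B, n_caps, d) secondary layer.

    For capsule models the vernier decoder reads only the vernier capsule;
    alternative architectures pass ``whole_layer=True`` and every head reads
    the full last layer.
    """

    def __init__(self, config: NetworkConfig, rng: np.random.Generator,
                 n_classes: int, whole_layer: bool = False,
                 last_layer_size: int | None = None, dtype=np.float32):
        self.config = config
        self.whole_layer = whole_layer
        self.n_classes = n_classes
        self.dtype = dtype
        d = config.secondary_dim
        full = last_layer_size or config.secondary_neurons
        vern_in = full if whole_layer else d
        self.params: dict[str, Tensor] = {}
        hid = config.vernier_decoder_hidden
        self._dense("vern1", vern_in, hid, rng)
        self._dense("vern2", hid, 3, rng)
        self._dense("reps1", full, hid, rng)
        self._dense("reps2", hid, 3, rng)
        h, w = config.image_shape
        h1, h2 = config.recon_hidden
        self._dense("rec1", full, h1, rng)
        self._dense("rec2", h1, h2, rng)
        self._dense("rec3", h2, h * w, rng)
        self._dense("loc_x", full, w, rng)
        self._dense("loc_y", full, h, rng)
        if whole_layer:
            self._dense("shape", full, n_classes, rng)

    def _dense(self, name: str, n_in: int, n_out: int,
               rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / n_in)
        self.params[f"{name}_w"] = parameter(
            rng.normal(0, scale, (n_in, n_out)).astype(self.dtype))
        self.params[f"{name}_b"] = parameter(np.zeros(n_out, dtype=self.dtype))

    def _apply(self, name: str, x: Tensor) -> Tensor:
        return x @ self.params[f"{name}_w"] + self.params[f"{name}_b"]

    # ------------------------------------------------------------- readouts
    def _flat(self, secondary) -> Tensor:
        if isinstance(secondary, CapsuleState):
            v = secondary.vectors
            return v.reshape(v.shape[0], v.shape[1] * v.shape[2])
        return secondary

    def decode_vernier(self, secondary, vernier_index: int = 0) -> Tensor:
        """3 scores over (left, right, no vernier)."""
        if self.whole_layer or not isinstance(secondary, CapsuleState):
            x = self._flat(secondary)
        else:
            x = secondary.vectors[:, vernier_index, :]
        return self._apply("vern2", relu(self._apply("vern1", x)))

    def decode_repetitions(self, secondary) -> Tensor:
        x = self._flat(secondary)
        return self._apply("reps2", relu(self._apply("reps1", x)))

    def decode_location(self, secondary) -> tuple[Tensor, Tensor]:
        x = self._flat(secondary)
        return self._apply("loc_x", x), self._apply("loc_y", x)

    def decode_shape_scores(self, last_layer: Tensor) -> Tensor:
        """Shape-type scores for whole-layer (non-capsule) readout."""
        return self._apply("shape", last_layer)

    def reconstruct(self, secondary, mask: np.ndarray | None = None) -> Tensor:
        """Decode an image; ``mask`` (B, n_caps) zeroes unselected capsules."""
        if isinstance(secondary, CapsuleState):
            v = secondary.vectors
            if mask is not None:
                mask = np.asarray(mask, dtype=v.data.dtype)
                if mask.sum() == 0:
                    raise ValueError("reconstruction mask selects no capsules")
                v = v * Tensor(mask[..., None])
            x = v.reshape(v.shape[0], v.shape[1] * v.shape[2])
        else:
            x = secondary
        h = elu(self._apply("rec1", x))
        h = elu(self._apply("rec2", h))
        out = self._apply("rec3", h)
        if self.config.recon_sigmoid:
            out = sigmoid(out)
        H, W = self.config.image_shape
        return out.reshape(out.shape[0], H, W)


def capsule_shape_norms(secondary: CapsuleState) -> Tensor:
    """Per-class norms used by the margin loss for capsule models."""
    return norms_of(secondary.vectors)
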