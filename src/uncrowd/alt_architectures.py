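"""Comparison models: the capsule layers replaced by a fully connected head.

Three variants share the capsule model's convolutional stack (including the
third convolution that would have been reshaped into primary capsules):

* ``ffcnn``    - a single feedforward fully connected layer;
* ``lateral``  - the same layer with learned lateral recurrent connections;
* ``topdown``  - the same layer feeding back into the (flattened) layer below.

The fully connected layer has exactly as many neurons as the capsule
model's secondary capsule layer, so the decoder heads see an input of
identical size; recurrent iteration counts mirror the routing iterations.
Recurrent updates are additive pre-activations followed by an ELU, with
weights tied across iterations; zeroed recurrent weights therefore
reproduce the feedforward network exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, conv2d, elu, parameter
from .capsule_core import NetworkConfig, conv_features

HEAD_KINDS = ("ffcnn", "lateral", "topdown")


@dataclass
class AltHeadConfig:
    head_kind: str = "ffcnn"
    hidden_units: int | None = None     # None -> capsule secondary neuron count
    recurrent_iterations: int | None = None  # None -> routing iterations

    def __post_init__(self):
        if self.head_kind not in HEAD_KINDS:
            raise ValueError(f"head_kind must be one of {HEAD_KINDS}")


def decode_all_from_last_layer(heads, activations) -> dict:
    """All decoder readouts from the entire last layer of an alt head.

    Unlike capsule models (which read the vernier offset from the secondary
    vernier capsule), the comparison networks decode every quantity from the
    full final layer.
    """
    from .autograd import sigmoid

    return {
        "vernier_scores": heads.decode_vernier(activations),
        "repetition_scores": heads.decode_repetitions(activations),
        "location_scores": heads.decode_location(activations),
        "reconstruction": heads.reconstruct(activations),
        "shape_presence": sigmoid(heads.decode_shape_scores(activations)),
    }


class AltNetwork:
    """Conv stack + fully connected head (feedforward / lateral / top-down)."""

    def __init__(self, config: NetworkConfig, head: AltHeadConfig,
                 rng: np.random.Generator, dtype=np.float32):
        self.config = config
        self.head = head
        self.arch = head.head_kind
        self.dtype = dtype
        units = head.hidden_units or config.secondary_neurons
        if units != config.secondary_neurons:
            raise ValueError(
                f"head width {units} breaks neuron-count parity with the "
                f"capsule layer ({config.secondary_neurons} neurons)")
        self.units = units
        self.iterations = head.recurrent_iterations or config.routing_iterations
        if self.iterations < 1:
            raise ValueError("recurrent_iterations must be >= 1")
        self.params: dict[str, Tensor] = {}
        self._init_params(rng)

    @property
    def feature_size(self) -> int:
        m, n = self.config.n_capsule_types, self.config.primary_dim
        h, w = self.config.primary_grid_shape()
        return m * n * h * w

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
        f = self.feature_size
        self._add("fc_w", rng.normal(0, np.sqrt(2.0 / f), (f, self.units)))
        self._add("fc_b", np.zeros(self.units))
        if self.head.head_kind == "lateral":
            self._add("lat_w", np.zeros((self.units, self.units)))
        elif self.head.head_kind == "topdown":
            self._add("td_w", np.zeros((self.units, f)))

    def _add(self, name, arr):
        self.params[name] = parameter(np.asarray(arr, dtype=self.dtype))

    # ------------------------------------------------------------- forward
    def _conv_stack(self, images: np.ndarray) -> Tensor:
        """Flattened pre-activation output of the third convolution."""
        x = np.asarray(images, dtype=self.dtype)
        if x.ndim == 3:
            x = x[:, None]
        feats = conv_features(Tensor(x), self.params, self.config)
        out = conv2d(feats, self.params["conv3_w"], self.params["conv3_b"],
                     stride=self.config.primary_stride)
        B = out.shape[0]
        return out.reshape(B, self.feature_size)

    def forward(self, images: np.ndarray,
                iterations: int | None = None) -> Tensor:
        """Returns the last-layer activation vector (B, units)."""
        kind = self.head.head_kind
        its = self.iterations if iterations is None else iterations
        if its < 1:
            raise ValueError("iterations must be >= 1")
        f_pre = self._conv_stack(images)
        f = elu(f_pre)
        pre = f @ self.params["fc_w"] + self.params["fc_b"]
        h = elu(pre)
        if kind == "ffcnn":
            return h
        if kind == "lateral":
            for _ in range(its - 1):
                h = elu(pre + h @ self.params["lat_w"])
            return h
        # top-down: the head output feeds back into the pre-activation below
        for _ in range(its - 1):
            f_t = elu(f_pre + h @ self.params["td_w"])
            h = elu(f_t @ self.params["fc_w"] + self.params["fc_b"])
        return h

    def save(self, path):
        import json
        from pathlib import Path
        from dataclasses import asdict
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **{k: v.data for k, v in self.params.items()})
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump({"arch": self.arch, "config": asdict(self.config),
                       "head": asdict(self.head)}, fh, indent=2, default=list)

    def load(self, path):
        with np.load(path) as data:
            for k in self.params:
                self.params[k].data = data[k].astype(self.dtype)
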