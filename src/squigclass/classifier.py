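"""Dropout-regularized 1D residual CNN for binary species classification.

The network maps a fixed-length normalized current-signal segment to the
probability that the read comes from the target species:

    conv(20ch, k=19, stride 3) -> BN -> ReLU -> maxpool(2)
    -> 4 residual stages x 2 bottleneck blocks (1-k-1 conv triplets,
       dropout after every activation, channels x1.5 per stage,
       stride-2 downsampling at the entry of stages >= 2)
    -> global mean pooling -> dense(1) -> sigmoid

Bottleneck skip paths use a 1x1 projection whenever channel count or
stride changes. During training 10% of layer outputs are dropped; at
inference dropout is a no-op.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from .nn import (
    Adam,
    BatchNorm1d,
    Conv1d,
    Dense,
    Dropout,
    GlobalAvgPool1d,
    Layer,
    MaxPool1d,
    Parameter,
    ReLU,
    RngBox,
    Sequential,
    sigmoid,
)

__all__ = [
    "ModelConfig",
    "ConfigurationError",
    "BottleneckBlock",
    "Classifier",
    "build_classifier",
]


class ConfigurationError(ValueError):
    """Model configuration incompatible with the input length."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults: the full-size network)."""

    input_length: int = 3000
    initial_channels: int = 20
    n_stages: int = 4
    blocks_per_stage: int = 2
    channel_growth: float = 1.5
    first_kernel: int = 19
    first_stride: int = 3
    block_kernel: int = 3
    dropout_rate: float = 0.10

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        for name in ("input_length", "initial_channels", "n_stages",
                     "blocks_per_stage", "first_stride"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("first_kernel", "block_kernel"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be odd and positive")
        if self.channel_growth <= 0:
            raise ValueError("channel_growth must be positive")

    def stage_channels(self) -> list[int]:
        """Channel width per stage: floor(initial * growth**stage)."""
        return [
            int(self.initial_channels * self.channel_growth**s)
            for s in range(self.n_stages)
        ]


class BottleneckBlock(Layer):
    """Residual bottleneck: 1x1 reduce -> kxk -> 1x1 expand, with skip.

    Dropout follows every activation; the skip is a strided 1x1
    projection when the shape changes, identity otherwise.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 dropout_rate: float, rng: np.random.Generator, rng_box: RngBox):
        mid = max(4, out_ch // 4)
        self.main = Sequential([
            Conv1d(in_ch, mid, 1, 1, rng), BatchNorm1d(mid),
            ReLU(), Dropout(dropout_rate, rng_box),
            Conv1d(mid, mid, kernel, stride, rng), BatchNorm1d(mid),
            ReLU(), Dropout(dropout_rate, rng_box),
            Conv1d(mid, out_ch, 1, 1, rng), BatchNorm1d(out_ch),
        ])
        if stride != 1 or in_ch != out_ch:
            self.proj: Sequential | None = Sequential(
                [Conv1d(in_ch, out_ch, 1, stride, rng), BatchNorm1d(out_ch)]
            )
        else:
            self.proj = None
        self.post = Sequential([ReLU(), Dropout(dropout_rate, rng_box)])

    def parameters(self) -> list[Parameter]:
        params = self.main.parameters()
        if self.proj is not None:
            params += self.proj.parameters()
        return params

    def out_length(self, L: int) -> int:
        return self.main.out_length(L)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = self.main.forward(x, training)
        skip = x if self.proj is None else self.proj.forward(x, training)
        return self.post.forward(y + skip, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.post.backward(grad)
        g_main = self.main.backward(g)
        g_skip = g if self.proj is None else self.proj.backward(g)
        return g_main + g_skip


class Classifier:
    """The built network plus its dropout RNG and config."""

    def __init__(self, cfg: ModelConfig, net: Sequential, rng_box: RngBox):
        self.cfg = cfg
        self.net = net
        self.rng_box = rng_box

    # -- inference ---------------------------------------------------------

    def forward_logits(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a (batch, input_length) segment matrix."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.cfg.input_length:
            raise ValueError(
                f"expected (batch, {self.cfg.input_length}) input, got {X.shape}"
            )
        return self.net.forward(X[:, None, :], training)[:, 0]

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """Probability of the target species for each segment, in (0, 1)."""
        return sigmoid(self.forward_logits(X, training))

    predict_proba = forward

    def backward(self, grad_logits: np.ndarray) -> None:
        self.net.backward(grad_logits[:, None].astype(np.float32))

    # -- bookkeeping -------------------------------------------------------

    def parameters(self) -> list[Parameter]:
        return self.net.parameters()

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def reseed_dropout(self, seed: int) -> None:
        self.rng_box.reseed(seed)

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.parameters(), lr=lr)

    # -- persistence -------------------------------------------------------

    def _state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(_batchnorms(self.net)):
            state[f"bn_{i}_mean"] = bn.running_mean
            state[f"bn_{i}_var"] = bn.running_var
        return state

    def save(self, path: str | os.PathLike) -> None:
        """Save weights (.npz) plus a sidecar JSON recording the config."""
        np.savez(path, **self._state_arrays())
        with open(str(path) + ".json", "w") as fh:
            json.dump(asdict(self.cfg), fh, indent=1)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "Classifier":
        with open(str(path) + ".json") as fh:
            cfg = ModelConfig(**json.load(fh))
        model = build_classifier(cfg)
        npz = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
        with np.load(npz) as data:
            for i, p in enumerate(model.parameters()):
                p.value = data[f"param_{i}"]
            for i, bn in enumerate(_batchnorms(model.net)):
                bn.running_mean = data[f"bn_{i}_mean"]
                bn.running_var = data[f"bn_{i}_var"]
        return model

    def copy_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self._state_arrays().values()]

    def restore_state(self, state: list[np.ndarray]) -> None:
        arrays = self._state_arrays()
        for key, saved in zip(list(arrays), state):
            arrays[key][...] = saved


def _batchnorms(layer: Layer) -> list[BatchNorm1d]:
    found: list[BatchNorm1d] = []
    if isinstance(layer, BatchNorm1d):
        found.append(layer)
    for attr in ("layers",):
        for sub in getattr(layer, attr, []):
            found.extend(_batchnorms(sub))
    if isinstance(layer, BottleneckBlock):
        found.extend(_batchnorms(layer.main))
        if layer.proj is not None:
            found.extend(_batchnorms(layer.proj))
        found.extend(_batchnorms(layer.post))
    return found


def build_classifier(cfg: ModelConfig, seed: int = 0) -> Classifier:
    """Construct the residual classifier; deterministic given ``seed``.

    Raises :class:`ConfigurationError` if ``cfg.input_length`` is too
    short to survive the downsampling chain.
    """
    rng = np.random.default_rng(seed)
    rng_box = RngBox(seed + 1)
    layers: list[Layer] = [
        Conv1d(1, cfg.initial_channels, cfg.first_kernel, cfg.first_stride, rng),
        BatchNorm1d(cfg.initial_channels),
        ReLU(),
        MaxPool1d(2),
    ]
    in_ch = cfg.initial_channels
    for s, out_ch in enumerate(cfg.stage_channels()):
        for b in range(cfg.blocks_per_stage):
            stride = 2 if (s >= 1 and b == 0) else 1
            layers.append(
                BottleneckBlock(in_ch, out_ch, cfg.block_kernel, stride,
                                cfg.dropout_rate, rng, rng_box)
            )
            in_ch = out_ch
    body = Sequential(layers)
    if body.out_length(cfg.input_length) < 1:
        raise ConfigurationError(
            f"input_length {cfg.input_length} collapses to zero length "
            f"after the downsampling chain"
        )
    layers.append(GlobalAvgPool1d())
    net = Sequential(layers)
    head = Dense(in_ch, 1, rng)
    net.layers.append(_DenseOnPooled(head))
    return Classifier(cfg, net, rng_box)


class _DenseOnPooled(Layer):
    """Adapter: dense head applied to the (N, C) pooled features."""

    def __init__(self, dense: Dense):
        self.dense = dense

    def parameters(self) -> list[Parameter]:
        return self.dense.parameters()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return self.dense.forward(x, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.dense.backward(grad)
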