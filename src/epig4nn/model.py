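"""The dilated residual convolutional G4 classifier.

The architecture follows the epiG4NN design: an input stem projecting the
encoded window to ``n_kernels`` channels, then K sequential convolutional
towers of pre-activation residual blocks. Each block applies
[batch-norm -> ReLU -> dilated same-padded conv] twice and adds the identity
shortcut; the tower k convolutions share kernel width W_k and dilation D_k.
The output of every residual block is additionally projected by a width-1
convolution to 32 channels and summed into a shared penultimate aggregation
layer, giving every block a short gradient path to the output. The head is
global average pooling over positions followed by a single affine logit and
a sigmoid.

The 4-channel (sequence-only) and 5-channel (sequence + epigenetic track)
variants differ only in the stem's input fan-in, so their parameter counts
match everywhere past the input layer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .nn import (BatchNorm1D, Conv1D, Dense, GlobalAvgPool, Layer, ReLU,
                 sigmoid)

PENULTIMATE_CHANNELS = 32


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the residual tower classifier.

    Defaults are the optimized full-scale setting: K = 3 towers with kernel
    widths [11, 11, 15], dilations [1, 4, 10], 32 kernels, four residual
    blocks per tower and a 1000-position input window.
    """

    n_towers: int = 3
    kernel_widths: Tuple[int, ...] = (11, 11, 15)
    dilations: Tuple[int, ...] = (1, 4, 10)
    n_kernels: int = 32
    blocks_per_tower: int = 4
    input_width: int = 1000
    input_channels: int = 5
    stem_width: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.kernel_widths) != self.n_towers or len(self.dilations) != self.n_towers:
            raise ValueError("kernel_widths and dilations must have n_towers entries")
        if any(w % 2 == 0 for w in self.kernel_widths) or self.stem_width % 2 == 0:
            raise ValueError("kernel widths must be odd")
        if self.input_channels not in (4, 5):
            raise ValueError("input_channels must be 4 or 5")


class _ResBlock:
    """Pre-activation residual block with two dilated convolutions."""

    def __init__(self, channels: int, width: int, dilation: int,
                 rng: np.random.Generator):
        self.bn1 = BatchNorm1D(channels)
        self.relu1 = ReLU()
        self.conv1 = Conv1D(channels, channels, width, dilation, rng)
        self.bn2 = BatchNorm1D(channels)
        self.relu2 = ReLU()
        self.conv2 = Conv1D(channels, channels, width, dilation, rng)

    def layers(self) -> List[Layer]:
        return [self.bn1, self.relu1, self.conv1, self.bn2, self.relu2, self.conv2]

    def forward(self, z: np.ndarray, training: bool) -> np.ndarray:
        h = self.bn1.forward(z, training)
        h = self.relu1.forward(h, training)
        h = self.conv1.forward(h, training)
        h = self.bn2.forward(h, training)
        h = self.relu2.forward(h, training)
        h = self.conv2.forward(h, training)
        return z + h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.conv2.backward(dout)
        d = self.relu2.backward(d)
        d = self.bn2.backward(d)
        d = self.conv1.backward(d)
        d = self.relu1.backward(d)
        d = self.bn1.backward(d)
        return dout + d


class PredictiveModel:
    """Residual tower network mapping (N, C, W) inputs to fold probabilities."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.n_kernels
        self.stem = Conv1D(config.input_channels, ch, config.stem_width, 1, rng)
        self.blocks: List[_ResBlock] = []
        self.projections: List[Conv1D] = []
        for k in range(config.n_towers):
            for _ in range(config.blocks_per_tower):
                self.blocks.append(
                    _ResBlock(ch, config.kernel_widths[k], config.dilations[k], rng)
                )
                self.projections.append(Conv1D(ch, PENULTIMATE_CHANNELS, 1, 1, rng))
        self.agg_relu = ReLU()
        self.pool = GlobalAvgPool()
        self.head = Dense(PENULTIMATE_CHANNELS, 1, rng)

    # -- plumbing ---------------------------------------------------------
    def layers(self) -> List[Layer]:
        out: List[Layer] = [self.stem]
        for block, proj in zip(self.blocks, self.projections):
            out.extend(block.layers())
            out.append(proj)
        out.extend([self.agg_relu, self.pool, self.head])
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for l in self.layers() for p in l.params.values()))

    def state_dict(self) -> Dict[str, np.ndarray]:
        state: Dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers()):
            for key, value in layer.params.items():
                state[f"layer{i}.{key}"] = value.copy()
            if isinstance(layer, BatchNorm1D):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers()):
            for key in layer.params:
                layer.params[key] = state[f"layer{i}.{key}"].copy()
            if isinstance(layer, BatchNorm1D):
                layer.running_mean = state[f"layer{i}.running_mean"].copy()
                layer.running_var = state[f"layer{i}.running_var"].copy()

    def astype(self, dtype) -> None:
        for layer in self.layers():
            layer.astype(dtype)

    # -- forward / backward ----------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a channels-first (N, C, W) batch."""
        z = self.stem.forward(x, training)
        agg = None
        for block, proj in zip(self.blocks, self.projections):
            z = block.forward(z, training)
            p = proj.forward(z, training)
            agg = p if agg is None else agg + p
        a = self.agg_relu.forward(agg, training)
        pooled = self.pool.forward(a, training)
        return self.head.forward(pooled, training)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits[:, None].astype(np.float32))
        d = self.pool.backward(d)
        dagg = self.agg_relu.backward(d)
        dz = None
        for block, proj in zip(reversed(self.blocks), reversed(self.projections)):
            dout = proj.backward(dagg)
            if dz is not None:
                dout = dout + dz
            dz = block.backward(dout)
        self.stem.backward(dz)

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Probabilities for (N, W, C) sample matrices, in input order.

        Runs in inference mode (batch-norm uses running statistics), so the
        result is deterministic and independent of batch composition.
        """
        xs = np.asarray(X, dtype=np.float32).transpose(0, 2, 1)
        out = []
        for i in range(0, len(xs), batch_size):
            out.append(sigmoid(self.forward_logits(xs[i:i + batch_size])))
        return np.concatenate(out) if out else np.empty(0)

    # -- persistence ------------------------------------------------------
    def save(self, path: str) -> None:
        state = self.state_dict()
        with open(path, "wb") as fh:
            np.savez_compressed(
                fh,
                __config__=np.frombuffer(
                    json.dumps(asdict(self.config)).encode(), dtype=np.uint8
                ),
                **state,
            )

    @classmethod
    def load(cls, path: str) -> "PredictiveModel":
        data = np.load(path)
        cfg = json.loads(bytes(data["__config__"]).decode())
        cfg["kernel_widths"] = tuple(cfg["kernel_widths"])
        cfg["dilations"] = tuple(cfg["dilations"])
        model = cls(ModelConfig(**cfg))
        state = {k: data[k] for k in data.files if k != "__config__"}
        model.load_state_dict(state)
        return model


def build_model(config: ModelConfig) -> PredictiveModel:
    """Construct a freshly initialized classifier from its configuration."""
    return PredictiveModel(config)


def predict(model: PredictiveModel, batch, batch_size: int = 256) -> np.ndarray:
    """Probabilities for a batch of (W, C) sample matrices."""
    X = np.stack([np.asarray(m) for m in batch])
    return model.predict_proba(X, batch_size=batch_size)


def class_weights(labels: Sequence[int]) -> Tuple[float, float]:
    """Balanced class weights w_c = N / (2 * n_c) for binary labels."""
    y = np.asarray(labels)
    n_neg = int(np.sum(y == 0))
    n_pos = int(np.sum(y == 1))
    if n_neg == 0 or n_pos == 0:
        raise ValueError("both classes must be present to compute class weights")
    n = n_neg + n_pos
    return n / (2.0 * n_neg), n / (2.0 * n_pos)
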