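"""The four-stream fall-phase classifier (4S-3DCNN).

The network takes the four fused images of a 16-frame window as a
128 x 128 x 4 x 3 input (height, width, depth, channels). Four splitting
layers route one depth slice — one RGB fused image — to each branch. Every
branch stacks three conv -> batchnorm -> ReLU blocks, each followed by a
max-pool, then global average pooling; filter counts double across the
blocks (64, 128, 256) while valid padding shrinks the spatial side
128 -> 63 -> 31 -> 15 -> 7 -> 5 -> 4. The four 256-wide GAP descriptors are
concatenated into a 1024-vector, passed through two FC -> batchnorm -> ReLU
blocks (widths 64 and 32), and a final 4-neuron FC with softmax scores the
four fall phases.

The nominal 3-D kernels have depth equal to the incoming channel count
(e.g. 3 x 3 x 64 over 64 channels), so each collapses to a full-channel 2-D
convolution; the layer table still reports the nominal shapes.

Two views of the model live here:

* :func:`build_model` — a framework-independent :class:`ModelGraph` of
  :class:`LayerRecord` entries with shapes and learnable-parameter counts,
  used for introspection, golden checks and the ``inspect-model`` command.
* :class:`FourStreamNet` — the runnable NumPy network (see
  :mod:`fallfusion.nn`) with forward, backward and checkpointing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .fusion import FusedStack


class ConfigurationError(ValueError):
    """Raised when a model configuration violates its structural rules."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the four-stream architecture.

    Defaults reproduce the reference architecture exactly. Invariants:
    filter counts double across successive conv layers; FC widths halve and
    end at the class count; pool windows are 3x3 or 2x2 (the published
    layer table uses 3x3 after the strided convolutions and 2x2 before the
    global average pool).
    """

    input_shape: tuple[int, int, int, int] = (128, 128, 4, 3)
    branch_conv_filters: tuple[int, ...] = (64, 128, 256)
    conv_kernels: tuple[tuple[int, int, int], ...] = ((4, 4, 3), (3, 3, 64), (3, 3, 128))
    conv_strides: tuple[tuple[int, int, int], ...] = ((2, 2, 3), (2, 2, 64), (1, 1, 128))
    pool_windows: tuple[tuple[int, int], ...] = ((3, 3), (3, 3), (2, 2))
    pool_strides: tuple[tuple[int, int], ...] = ((2, 2), (2, 2), (1, 1))
    fc_widths: tuple[int, ...] = (64, 32, 4)
    n_branches: int = 4

    @property
    def n_classes(self) -> int:
        return self.fc_widths[-1]

    @property
    def n_conv_blocks(self) -> int:
        return len(self.branch_conv_filters)

    def validate(self) -> None:
        if self.n_branches < 1:
            raise ConfigurationError("need at least one branch")
        if self.input_shape[2] != self.n_branches:
            raise ConfigurationError(
                "input depth must equal the number of branches "
                f"(got depth {self.input_shape[2]} vs {self.n_branches} branches)"
            )
        f = self.branch_conv_filters
        if any(f[i + 1] != 2 * f[i] for i in range(len(f) - 1)):
            raise ConfigurationError(
                f"filter counts must double across conv layers, got {f}"
            )
        w = self.fc_widths
        if len(w) >= 2 and any(w[i + 1] != w[i] // 2 for i in range(len(w) - 2)):
            raise ConfigurationError(f"FC widths must halve, got {w}")
        if not (
            len(self.conv_kernels)
            == len(self.conv_strides)
            == len(self.pool_windows)
            == len(self.pool_strides)
            == self.n_conv_blocks
        ):
            raise ConfigurationError("per-block kernel/stride/pool tuples must align")
        # shape propagation performs the remaining (size/parity) checks
        branch_spatial_trace(self)


def _conv_out(side: int, k: int, s: int) -> int:
    return (side - k) // s + 1


def branch_spatial_trace(config: ModelConfig) -> list[int]:
    """Spatial side after the input and each conv/pool of one branch.

    For the default configuration: [128, 63, 31, 15, 7, 5, 4].
    Raises :class:`ConfigurationError` on non-positive sizes or a pool
    window other than 2x2 or 3x3.
    """
    side = config.input_shape[0]
    trace = [side]
    for i in range(config.n_conv_blocks):
        k, s = config.conv_kernels[i][0], config.conv_strides[i][0]
        side = _conv_out(side, k, s)
        if side <= 0:
            raise ConfigurationError(f"conv block {i + 1} collapses the feature map")
        trace.append(side)
        pk, ps = config.pool_windows[i][0], config.pool_strides[i][0]
        if pk not in (2, 3):
            raise ConfigurationError(f"pool {i + 1} window must be 2x2 or 3x3, got {pk}x{pk}")
        side = _conv_out(side, pk, ps)
        if side <= 0:
            raise ConfigurationError(f"pool {i + 1} collapses the feature map")
        trace.append(side)
    return trace


@dataclass(frozen=True)
class LayerRecord:
    """One layer of the enumerated graph, mirroring the architecture table."""

    name: str
    kind: str  # input|split|conv|batchnorm|relu|maxpool|gap|concat|fc|softmax|classification
    branch: object  # 1-based branch index, or "shared"
    output_shape: tuple[int, int, int, int]  # (H, W, D, C)
    learnable_param_count: int = 0


@dataclass(frozen=True)
class ModelGraph:
    """Ordered layer enumeration of the constructed model."""

    config: ModelConfig
    layers: tuple[LayerRecord, ...]

    @property
    def total_params(self) -> int:
        return sum(l.learnable_param_count for l in self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def concat_width(self) -> int:
        return next(l for l in self.layers if l.kind == "concat").output_shape[-1]


def build_model(config: ModelConfig = ModelConfig()) -> ModelGraph:
    """Enumerate the model layer by layer with shapes and parameter counts.

    Enumeration convention (67 layers for the default configuration):
    1 input + n_branches splitting layers + per branch (conv, batchnorm,
    ReLU) x blocks interleaved with one max-pool per block + one GAP per
    branch + 1 concatenation + two (FC, batchnorm, ReLU) blocks + the final
    FC + softmax + classification output.
    """
    config.validate()
    h, w, depth, ch = config.input_shape
    layers: list[LayerRecord] = [
        LayerRecord("input", "input", "shared", (h, w, depth, ch))
    ]
    for b in range(1, config.n_branches + 1):
        layers.append(LayerRecord(f"split_b{b}", "split", b, (h, w, 1, ch)))
    for b in range(1, config.n_branches + 1):
        side, in_ch = h, ch
        for i in range(config.n_conv_blocks):
            out_ch = config.branch_conv_filters[i]
            kh, kw = config.conv_kernels[i][:2]
            sh = config.conv_strides[i][0]
            side = _conv_out(side, kh, sh)
            n_par = kh * kw * in_ch * out_ch + out_ch
            shape = (side, side, 1, out_ch)
            layers.append(LayerRecord(f"conv{i + 1}_b{b}", "conv", b, shape, n_par))
            layers.append(
                LayerRecord(f"bn{i + 1}_b{b}", "batchnorm", b, shape, 2 * out_ch)
            )
            layers.append(LayerRecord(f"relu{i + 1}_b{b}", "relu", b, shape))
            pk = config.pool_windows[i][0]
            ps = config.pool_strides[i][0]
            side = _conv_out(side, pk, ps)
            layers.append(
                LayerRecord(f"pool{i + 1}_b{b}", "maxpool", b, (side, side, 1, out_ch))
            )
            in_ch = out_ch
        layers.append(LayerRecord(f"gap_b{b}", "gap", b, (1, 1, 1, in_ch)))
    concat_width = config.n_branches * config.branch_conv_filters[-1]
    layers.append(LayerRecord("concat", "concat", "shared", (1, 1, 1, concat_width)))
    width_in = concat_width
    n_fc = len(config.fc_widths)
    for i, width in enumerate(config.fc_widths):
        n_par = width_in * width + width
        shape = (1, 1, 1, width)
        layers.append(LayerRecord(f"fc{i + 1}", "fc", "shared", shape, n_par))
        if i < n_fc - 1:  # hidden FC blocks carry batchnorm + ReLU
            layers.append(LayerRecord(f"fc_bn{i + 1}", "batchnorm", "shared", shape, 2 * width))
            layers.append(LayerRecord(f"fc_relu{i + 1}", "relu", "shared", shape))
        width_in = width
    out_shape = (1, 1, 1, config.n_classes)
    layers.append(LayerRecord("softmax", "softmax", "shared", out_shape))
    layers.append(LayerRecord("classification", "classification", "shared", out_shape))
    return ModelGraph(config=config, layers=tuple(layers))


def propagate_shapes(graph: ModelGraph) -> ModelGraph:
    """Recompute every output shape from the configuration's shape rules
    (out = floor((in - kernel) / stride) + 1 per spatial dimension) and
    return the refreshed graph. Raises on any inconsistency."""
    fresh = build_model(graph.config)
    for old, new in zip(graph.layers, fresh.layers):
        if (old.name, old.kind) != (new.name, new.kind):
            raise ConfigurationError(
                f"graph inconsistent with its configuration at layer {old.name}"
            )
    return fresh


def count_parameters(graph: ModelGraph) -> int:
    """Total learnable parameters: conv/FC weights and biases plus the
    batchnorm scale and shift pairs."""
    return graph.total_params


def params_millions(graph: ModelGraph, decimals: int = 1) -> float:
    """Parameter count in millions, truncated (not rounded) to ``decimals``."""
    scale = 10**decimals
    return int(graph.total_params / 1e6 * scale) / scale


def summary_table(graph: ModelGraph) -> str:
    """Plain-text layer table in the style of the architecture's published table."""
    rows = [f"{'Layer':<18}{'Kind':<16}{'Branch':<8}{'Output shape':<20}{'Params':>10}"]
    rows.append("-" * len(rows[0]))
    for l in graph.layers:
        shape = " x ".join(str(s) for s in l.output_shape)
        rows.append(
            f"{l.name:<18}{l.kind:<16}{str(l.branch):<8}{shape:<20}{l.learnable_param_count:>10,}"
        )
    rows.append("-" * len(rows[0]))
    rows.append(
        f"Layers: {graph.n_layers}   Parameters: {graph.total_params:,} "
        f"({params_millions(graph)} M)"
    )
    return "\n".join(rows)


def graph_to_json(graph: ModelGraph) -> str:
    """Model summary as JSON (layer records plus totals)."""
    return json.dumps(
        {
            "layers": [asdict(l) for l in graph.layers],
            "n_layers": graph.n_layers,
            "total_params": graph.total_params,
            "params_millions_truncated": params_millions(graph),
        },
        indent=1,
    )


# ---------------------------------------------------------------------------
# runnable network


class FourStreamNet:
    """Runnable NumPy realization of the four-stream classifier.

    Parameters
    ----------
    config : ModelConfig
    seed : int
        Seeds the Glorot-uniform weight initialization.
    dtype : numpy dtype
        float32 for training; float64 is used by the gradient checks.
    """

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0, dtype=np.float32):
        config.validate()
        self.config = config
        self.dtype = np.dtype(dtype)
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.branches = []
        for b in range(config.n_branches):
            in_ch = config.input_shape[3]
            stack = []
            for i in range(config.n_conv_blocks):
                out_ch = config.branch_conv_filters[i]
                stack.append(
                    nn.Conv2d(
                        in_ch,
                        out_ch,
                        config.conv_kernels[i][:2],
                        config.conv_strides[i][:2],
                        rng,
                        dtype=dtype,
                        name=f"conv{i + 1}_b{b + 1}",
                    )
                )
                stack.append(nn.BatchNorm(out_ch, dtype=dtype, name=f"bn{i + 1}_b{b + 1}"))
                stack.append(nn.ReLU())
                stack.append(nn.MaxPool2d(config.pool_windows[i], config.pool_strides[i]))
                in_ch = out_ch
            stack.append(nn.GlobalAvgPool())
            self.branches.append(stack)
        self.head = []
        width_in = config.n_branches * config.branch_conv_filters[-1]
        for i, width in enumerate(config.fc_widths):
            self.head.append(nn.Linear(width_in, width, rng, dtype=dtype, name=f"fc{i + 1}"))
            if i < len(config.fc_widths) - 1:
                self.head.append(nn.BatchNorm(width, dtype=dtype, name=f"fc_bn{i + 1}"))
                self.head.append(nn.ReLU())
            width_in = width

    # -- introspection -----------------------------------------------------

    @property
    def graph(self) -> ModelGraph:
        return build_model(self.config)

    def params(self) -> list[nn.Param]:
        out = []
        for stack in self.branches:
            for layer in stack:
                out.extend(layer.params())
        for layer in self.head:
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    # -- execution ---------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        h, w, depth, ch = self.config.input_shape
        if x.ndim == 4:
            x = x[None]
        if x.ndim != 5 or x.shape[1:] != (depth, h, w, ch):
            raise ValueError(
                f"expected sample(s) of shape ({depth},{h},{w},{ch}), got {x.shape}"
            )
        return x

    def forward_descriptors(self, x: np.ndarray, train: bool = False) -> list[np.ndarray]:
        """Per-branch GAP descriptors, each ``(N, C)``; branch k sees only
        depth slice k of the input."""
        x = self._check_input(x)
        descs = []
        for b, stack in enumerate(self.branches):
            xb = np.ascontiguousarray(x[:, b])  # (N, H, W, 3), channels last
            for layer in stack:
                xb = layer.forward(xb, train=train)
            descs.append(xb)
        return descs

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch ``(N, depth, H, W, 3)`` (or a single sample)."""
        descs = self.forward_descriptors(x, train=train)
        z = np.concatenate(descs, axis=1)
        self._desc_widths = [d.shape[1] for d in descs]
        for layer in self.head:
            z = layer.forward(z, train=train)
        return z

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from a loss gradient on the logits."""
        dz = dlogits
        for layer in reversed(self.head):
            dz = layer.backward(dz)
        offset = 0
        for width, stack in zip(self._desc_widths, self.branches):
            db = dz[:, offset : offset + width]
            offset += width
            for layer in reversed(stack):
                db = layer.backward(db)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (rows sum to 1) in evaluation mode."""
        return nn.softmax(self.forward(x, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=-1)

    # -- checkpointing -----------------------------------------------------

    def save(self, path) -> None:
        """Save parameters and batchnorm running statistics as an ``.npz``."""
        arrays = {}
        for i, p in enumerate(self.params()):
            arrays[f"param_{i}"] = p.value
        for j, bn in enumerate(self._batchnorms()):
            arrays[f"bn_{j}_mean"] = bn.running_mean
            arrays[f"bn_{j}_var"] = bn.running_var
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    def _batchnorms(self):
        out = []
        for stack in self.branches:
            out.extend(l for l in stack if isinstance(l, nn.BatchNorm))
        out.extend(l for l in self.head if isinstance(l, nn.BatchNorm))
        return out

    @classmethod
    def load(cls, path, dtype=np.float32) -> "FourStreamNet":
        data = np.load(path)
        raw = json.loads(bytes(data["config_json"]).decode())
        cfg = ModelConfig(
            input_shape=tuple(raw["input_shape"]),
            branch_conv_filters=tuple(raw["branch_conv_filters"]),
            conv_kernels=tuple(tuple(k) for k in raw["conv_kernels"]),
            conv_strides=tuple(tuple(s) for s in raw["conv_strides"]),
            pool_windows=tuple(tuple(p) for p in raw["pool_windows"]),
            pool_strides=tuple(tuple(p) for p in raw["pool_strides"]),
            fc_widths=tuple(raw["fc_widths"]),
            n_branches=raw["n_branches"],
        )
        net = cls(cfg, dtype=dtype)
        for i, p in enumerate(net.params()):
            p.value = data[f"param_{i}"].astype(dtype)
            p.grad = np.zeros_like(p.value)
        for j, bn in enumerate(net._batchnorms()):
            bn.running_mean = data[f"bn_{j}_mean"].astype(dtype)
            bn.running_var = data[f"bn_{j}_var"].astype(dtype)
        return net

    def state_copy(self) -> dict:
        """Snapshot of parameters and running stats (for checkpoint selection)."""
        return {
            "params": [p.value.copy() for p in self.params()],
            "bn": [(bn.running_mean.copy(), bn.running_var.copy()) for bn in self._batchnorms()],
        }

    def load_state(self, state: dict) -> None:
        for p, v in zip(self.params(), state["params"]):
            p.value = v.copy()
        for bn, (m, v) in zip(self._batchnorms(), state["bn"]):
            bn.running_mean, bn.running_var = m.copy(), v.copy()


def forward(net: FourStreamNet, sample) -> np.ndarray:
    """Class-probability vector for one fused stack.

    ``sample`` may be a :class:`~fallfusion.fusion.FusedStack` or a
    ``(4, 128, 128, 3)`` array; probabilities are nonnegative and sum to 1.
    """
    if isinstance(sample, FusedStack):
        sample = sample.as_array()
    probs = net.predict_proba(sample)
    return probs[0] if probs.shape[0] == 1 else probs
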