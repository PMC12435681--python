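"""ATHER2: a two-branch lightweight CNN for HER2 scoring.

The network stem (3x3 conv, 2x2 max pool) downsamples the input patch,
then the graph forks.  The left branch uses strided 3x3 convolutions with
a CBAM attention block and dropout; the right branch uses 3x3 and 5x5
convolutions with batch normalization.  Each branch ends in global average
pooling (128 features); the two vectors are concatenated and fed to a
128-unit dense layer and a classification head (1 sigmoid unit for binary,
softmax otherwise).  Convolutions use leaky-ReLU activations and "same"
padding (output side ``ceil(in/stride)``); max pooling uses "valid"
padding (``floor((in-k)/stride)+1``) — the unique pair of conventions
consistent with the published layer table.

This module provides both a framework-free architecture description with a
shape-inference calculus (:func:`ather2_graph`, :func:`shape_trace`) and a
runnable model built on the numpy engine (:func:`build_ather2`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attention import CBAMConfig, append_cbam
from .nn import Model, ModelBuilder, ParamCount
from .nn.layers import (BatchNorm, Concat, Conv2D, Dense, Dropout,
                        GlobalAvgPool2D, LeakyReLU, MaxPool2D, Sigmoid,
                        Softmax)

__all__ = [
    "LayerSpec", "ArchitectureGraph", "ShapeTrace", "ParamCount",
    "conv_output_size", "pool_output_size", "ather2_graph", "shape_trace",
    "build_ather2", "count_parameters", "model_summary",
]


# ------------------------------------------------------------- shape calculus

def conv_output_size(in_size: int, kernel: int, stride: int) -> int:
    """Spatial side after a same-padding convolution: ``ceil(in/stride)``."""
    if in_size < 1 or kernel < 1 or stride < 1:
        raise ValueError("in_size, kernel and stride must be positive")
    return math.ceil(in_size / stride)


def pool_output_size(in_size: int, kernel: int, stride: int) -> int:
    """Spatial side after valid-padding pooling: ``floor((in-k)/stride)+1``."""
    if in_size < 1 or kernel < 1 or stride < 1:
        raise ValueError("in_size, kernel and stride must be positive")
    if in_size < kernel:
        raise ValueError(f"pool kernel {kernel} exceeds input size {in_size}")
    return (in_size - kernel) // stride + 1


# --------------------------------------------------------- architecture graph

@dataclass(frozen=True)
class LayerSpec:
    name: str
    kind: str  # conv | maxpool | cbam | dropout | batchnorm | gap | dense | concat | input
    kernel: int | None = None
    stride: int | None = None
    channels_or_units: int | None = None
    rate: float | None = None
    branch: str = "common"
    with_cbam: bool = False

    def __post_init__(self):
        if self.kind in ("conv", "maxpool") and (self.kernel < 1 or self.stride < 1):
            raise ValueError(f"{self.name}: kernel and stride must be >= 1")
        if self.kind == "dropout" and not (0 <= self.rate < 1):
            raise ValueError(f"{self.name}: dropout rate must be in [0, 1)")


@dataclass
class ArchitectureGraph:
    layers: list[LayerSpec]
    predecessors: dict[str, tuple[str, ...]]
    variant: str = "full"
    num_classes: int = 2

    def __post_init__(self):
        names = [l.name for l in self.layers]
        inputs = [l for l in self.layers if l.kind == "input"]
        if len(inputs) != 1:
            raise ValueError("graph must have exactly one input node")
        sinks = set(names) - {p for preds in self.predecessors.values() for p in preds}
        if len(sinks) != 1:
            raise ValueError(f"graph must have exactly one output node, found {sorted(sinks)}")

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)


def _branch_rows(variant: str) -> list[LayerSpec]:
    left = [
        LayerSpec("L-1", "conv", 3, 3, 64, branch="left", with_cbam=True),
        LayerSpec("L-2", "maxpool", 3, 2, branch="left"),
        LayerSpec("L-3", "dropout", rate=0.10, branch="left"),
        LayerSpec("L-4", "conv", 3, 3, 128, branch="left"),
        LayerSpec("L-5", "maxpool", 3, 2, branch="left"),
        LayerSpec("L-6", "dropout", rate=0.10, branch="left"),
        LayerSpec("L-7", "gap", branch="left"),
    ]
    right = [
        LayerSpec("R-1", "conv", 3, 1, 32, branch="right"),
        LayerSpec("R-2", "maxpool", 3, 1, branch="right"),
        LayerSpec("R-3", "conv", 3, 2, 64, branch="right"),
        LayerSpec("R-4", "maxpool", 3, 2, branch="right"),
        LayerSpec("R-5", "batchnorm", branch="right"),
        LayerSpec("R-6", "conv", 5, 2, 128, branch="right"),
        LayerSpec("R-7", "maxpool", 3, 3, branch="right"),
        LayerSpec("R-8", "gap", branch="right"),
    ]
    if variant == "left_only":
        return left
    if variant == "right_only":
        return right
    return left + right


def ather2_graph(num_classes: int = 2, variant: str = "full") -> ArchitectureGraph:
    if variant not in ("full", "left_only", "right_only"):
        raise ValueError(f"unknown variant {variant!r}")
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    rows = [
        LayerSpec("C-0", "input", channels_or_units=3),
        LayerSpec("C-1", "conv", 3, 1, 16),
        LayerSpec("C-2", "maxpool", 2, 2),
    ]
    rows += _branch_rows(variant)
    head_units = 1 if num_classes == 2 else num_classes
    if variant == "full":
        rows.append(LayerSpec("C-3", "concat", branch="head"))
    rows.append(LayerSpec("C-4", "dense", channels_or_units=128, branch="head"))
    rows.append(LayerSpec("C-5", "dense", channels_or_units=head_units, branch="head"))

    preds: dict[str, tuple[str, ...]] = {"C-1": ("C-0",), "C-2": ("C-1",)}
    chain = {"left": [l.name for l in rows if l.branch == "left"],
             "right": [l.name for l in rows if l.branch == "right"]}
    for names in chain.values():
        for prev, cur in zip(["C-2"] + names, names):
            preds[cur] = (prev,)
    if variant == "full":
        preds["C-3"] = ("L-7", "R-8")
        preds["C-4"] = ("C-3",)
    else:
        preds["C-4"] = (chain["left"] or chain["right"])[-1:]
        preds["C-4"] = tuple(preds["C-4"])
    preds["C-5"] = ("C-4",)
    return ArchitectureGraph(rows, preds, variant=variant, num_classes=num_classes)


# ----------------------------------------------------------------- shape trace

@dataclass
class ShapeTrace:
    entries: list[tuple[str, tuple]] = field(default_factory=list)

    def shape(self, name: str) -> tuple:
        for n, s in self.entries:
            if n == name:
                return s
        raise KeyError(name)

    def as_dict(self) -> dict:
        return dict(self.entries)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(n, " x ".join(map(str, s))) for n, s in self.entries],
            columns=["layer", "output_size"],
        )


def shape_trace(graph: ArchitectureGraph, input_size: tuple) -> ShapeTrace:
    """Per-layer output shapes computed with the conv/pool calculus."""
    h, w, c = input_size
    shapes: dict[str, tuple] = {}
    trace = ShapeTrace()
    for spec in graph.layers:
        if spec.kind == "input":
            out = (h, w, spec.channels_or_units or c)
        else:
            srcs = [shapes[p] for p in graph.predecessors[spec.name]]
            s = srcs[0]
            if spec.kind == "conv":
                out = (conv_output_size(s[0], spec.kernel, spec.stride),
                       conv_output_size(s[1], spec.kernel, spec.stride),
                       spec.channels_or_units)
            elif spec.kind == "maxpool":
                try:
                    out = (pool_output_size(s[0], spec.kernel, spec.stride),
                           pool_output_size(s[1], spec.kernel, spec.stride),
                           s[2])
                except ValueError as e:
                    raise ValueError(f"layer {spec.name}: {e}") from None
            elif spec.kind in ("dropout", "batchnorm", "cbam"):
                out = s
            elif spec.kind == "gap":
                out = (s[2],)
            elif spec.kind == "concat":
                out = (sum(x[-1] for x in srcs),)
            elif spec.kind == "dense":
                out = (spec.channels_or_units,)
            else:  # pragma: no cover
                raise ValueError(f"unknown layer kind {spec.kind!r}")
            if any(d < 1 for d in out):
                raise ValueError(f"layer {spec.name}: non-positive output shape {out}")
        shapes[spec.name] = out
        trace.entries.append((spec.name, out))
    return trace


# --------------------------------------------------------------- runnable model

def build_ather2(input_size=(512, 512, 3), num_classes: int = 2,
                 variant: str = "full", cbam_cfg: CBAMConfig | None = None,
                 seed: int = 0, leaky_alpha: float = 0.3):
    """Build the runnable ATHER2 model.  Returns ``(model, graph)``.

    Raises a descriptive error (naming the failing layer) when the input is
    too small to survive the stack of strides.
    """
    h, w, c = input_size
    if c != 3:
        raise ValueError("ATHER2 expects RGB input (3 channels)")
    if h < 64 or w < 64:
        raise ValueError("input spatial dims must be at least 64")
    cbam_cfg = cbam_cfg or CBAMConfig()
    graph = ather2_graph(num_classes=num_classes, variant=variant)
    shape_trace(graph, input_size)  # validates all strides fit
    rng = np.random.default_rng(seed)

    b = ModelBuilder("C-0")
    channels = {"C-0": 3}

    def conv(spec: LayerSpec, src: str) -> str:
        cin = channels[src]
        b.add(f"{spec.name}_conv",
              Conv2D(cin, spec.channels_or_units, spec.kernel, spec.stride,
                     "same", rng=rng, name=spec.name),
              src)
        out = b.add(f"{spec.name}_act", LeakyReLU(leaky_alpha))
        channels[out] = spec.channels_or_units
        if spec.with_cbam:
            out = append_cbam(b, out, spec.channels_or_units, cbam_cfg, rng,
                              prefix=f"{spec.name}_cbam")
            channels[out] = spec.channels_or_units
        return out

    node_of = {"C-0": "C-0"}
    for spec in graph.layers:
        if spec.kind == "input":
            continue
        srcs = [node_of[p] for p in graph.predecessors[spec.name]]
        src = srcs[0]
        if spec.kind == "conv":
            out = conv(spec, src)
        elif spec.kind == "maxpool":
            out = b.add(spec.name, MaxPool2D(spec.kernel, spec.stride), src)
            channels[out] = channels[src]
        elif spec.kind == "dropout":
            out = b.add(spec.name, Dropout(spec.rate), src)
            channels[out] = channels[src]
        elif spec.kind == "batchnorm":
            out = b.add(spec.name, BatchNorm(channels[src], name=spec.name), src)
            channels[out] = channels[src]
        elif spec.kind == "gap":
            out = b.add(spec.name, GlobalAvgPool2D(), src)
            channels[out] = channels[src]
        elif spec.kind == "concat":
            out = b.add(spec.name, Concat(), tuple(srcs))
            channels[out] = sum(channels[s] for s in srcs)
        elif spec.kind == "dense":
            units = spec.channels_or_units
            b.add(f"{spec.name}_dense",
                  Dense(channels[src], units, rng=rng, name=spec.name), src)
            if spec.name == "C-5":
                act = Sigmoid() if units == 1 else Softmax()
            else:
                act = LeakyReLU(leaky_alpha)
            out = b.add(f"{spec.name}_act", act)
            channels[out] = units
        node_of[spec.name] = out

    model = b.build(node_of["C-5"])
    model.meta = {"arch": "ather2", "input_size": tuple(input_size),
                  "num_classes": num_classes, "variant": variant,
                  "cbam": {"reduction_ratio": cbam_cfg.reduction_ratio,
                           "spatial_kernel": cbam_cfg.spatial_kernel,
                           "mlp_bias": cbam_cfg.mlp_bias},
                  "seed": seed}
    return model, graph


def count_parameters(model: Model) -> ParamCount:
    return model.count_parameters()


def model_summary(model: Model, input_size=(96, 96, 3)) -> pd.DataFrame:
    """Per-node summary (name, op, output shape, parameter count) from one
    forward pass on a zero input."""
    tape = model.forward(np.zeros((1, *input_size), dtype=np.float32))
    rows = []
    seen = set()
    for node in model.nodes:
        nparams = 0
        if id(node.layer) not in seen:
            seen.add(id(node.layer))
            nparams = sum(p.value.size for p in node.layer.parameters())
        rows.append({
            "node": node.name,
            "op": type(node.layer).__name__,
            "output_shape": tuple(tape.outputs[node.name].shape[1:]),
            "params": int(nparams),
        })
    return pd.DataFrame(rows)
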