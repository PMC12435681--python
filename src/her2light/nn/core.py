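"""Minimal reverse-mode autodiff engine for small CNNs on CPU.

Models are directed acyclic graphs of named nodes; each node wraps a layer
(an op with parameters) and the names of its input nodes.  Data layout is
NHWC throughout and arithmetic is float32.  A forward pass records a
:class:`Tape` (per-node outputs and caches) so several independent passes
through one model can coexist; the backward pass walks the graph in reverse
topological order and accumulates parameter gradients into
``Parameter.grad``.  Layer instances may be shared between nodes (weight
sharing); gradients then simply accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DTYPE = np.float32


class Parameter:
    """A trainable (or frozen) array with an accumulated gradient."""

    __slots__ = ("value", "grad", "trainable", "regularized", "name")

    def __init__(self, value, trainable=True, regularized=False, name=""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.regularized = regularized
        self.name = name

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Parameter({self.name!r}, shape={self.value.shape}, trainable={self.trainable})"


class Layer:
    """Base op.  Subclasses implement ``forward`` and ``backward``.

    ``forward`` returns ``(output, cache)``; ``backward`` receives the
    upstream gradient plus the cache and returns one gradient per input.
    Parameter gradients are accumulated in place.
    """

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, inputs, training, rng):
        raise NotImplementedError

    def backward(self, grad, cache):
        raise NotImplementedError


@dataclass(frozen=True)
class Node:
    name: str
    layer: Layer
    inputs: tuple[str, ...]


@dataclass
class Tape:
    """Record of one forward pass."""

    outputs: dict = field(default_factory=dict)
    caches: dict = field(default_factory=dict)


@dataclass
class ParamCount:
    trainable: int
    non_trainable: int

    @property
    def total(self) -> int:
        return self.trainable + self.non_trainable


class Model:
    """A DAG of named nodes with a single input and a single output node."""

    def __init__(self, nodes: list[Node], input_name: str, output_name: str):
        self.nodes = list(nodes)
        self.input_name = input_name
        self.output_name = output_name
        self._by_name = {n.name: n for n in self.nodes}
        if len(self._by_name) != len(self.nodes):
            raise ValueError("duplicate node names in model graph")
        for n in self.nodes:
            for src in n.inputs:
                if src != input_name and src not in self._by_name:
                    raise ValueError(f"node {n.name!r} references unknown input {src!r}")
        if output_name not in self._by_name:
            raise ValueError(f"unknown output node {output_name!r}")

    # ------------------------------------------------------------------ graph
    def node(self, name: str) -> Node:
        try:
            return self._by_name[name]
        except KeyError:
            close = [n for n in self._by_name if name.split("_")[0] in n]
            hint = f"; similar: {close[:5]}" if close else ""
            raise KeyError(f"no node named {name!r}{hint}") from None

    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def weighted_layers(self) -> list[tuple[str, Layer]]:
        """Unique layers owning parameters, in topological (node) order."""
        seen, out = set(), []
        for n in self.nodes:
            if n.layer.parameters() and id(n.layer) not in seen:
                seen.add(id(n.layer))
                out.append((n.name, n.layer))
        return out

    def parameters(self) -> list[Parameter]:
        seen, out = set(), []
        for _, layer in self.weighted_layers():
            for p in layer.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def count_parameters(self) -> ParamCount:
        tr = sum(int(p.value.size) for p in self.parameters() if p.trainable)
        nt = sum(int(p.value.size) for p in self.parameters() if not p.trainable)
        return ParamCount(trainable=tr, non_trainable=nt)

    # --------------------------------------------------------------- forward
    def forward(self, x, training: bool = False, rng=None) -> Tape:
        x = np.asarray(x, dtype=DTYPE)
        tape = Tape()
        tape.outputs[self.input_name] = x
        for n in self.nodes:
            ins = [tape.outputs[src] for src in n.inputs]
            out, cache = n.layer.forward(ins, training, rng)
            tape.outputs[n.name] = out
            tape.caches[n.name] = cache
        return tape

    def predict(self, x, batch_size: int = 32) -> np.ndarray:
        """Inference-mode probabilities, batched to bound memory."""
        x = np.asarray(x, dtype=DTYPE)
        outs = [
            self.forward(x[i : i + batch_size]).outputs[self.output_name]
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    # -------------------------------------------------------------- backward
    def backward(self, tape: Tape, seed: dict, stop_at: str | None = None) -> dict:
        """Back-propagate from ``seed`` gradients ({node name: dL/d(out)}).

        Returns gradients w.r.t. every node output reached.  Parameter
        gradients accumulate into ``Parameter.grad`` (call
        :meth:`zero_grad` first when training).  ``stop_at`` may name a
        node whose upstream computation can be skipped (Grad-CAM).
        """
        grads: dict[str, np.ndarray] = {
            k: np.asarray(v, dtype=DTYPE) for k, v in seed.items()
        }
        for n in reversed(self.nodes):
            g = grads.get(n.name)
            if g is None:
                continue
            in_grads = n.layer.backward(g, tape.caches[n.name])
            for src, ig in zip(n.inputs, in_grads):
                if ig is None:
                    continue
                if src in grads:
                    grads[src] = grads[src] + ig
                else:
                    grads[src] = ig
            if stop_at is not None and n.name == stop_at:
                break
        return grads

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # ------------------------------------------------------------ state dict
    def get_weights(self) -> dict[str, np.ndarray]:
        return {p.name or f"param{i}": p.value.copy() for i, p in enumerate(self.parameters())}

    def set_weights(self, weights: dict) -> None:
        for i, p in enumerate(self.parameters()):
            key = p.name or f"param{i}"
            if key not in weights:
                raise KeyError(f"missing weight {key!r}")
            val = np.asarray(weights[key], dtype=DTYPE)
            if val.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {key!r}: {val.shape} vs {p.value.shape}")
            p.value[...] = val

    def save_weights(self, path) -> None:
        np.savez(path, **self.get_weights())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.set_weights(dict(data))


class ModelBuilder:
    """Incremental constructor for :class:`Model` graphs."""

    def __init__(self, input_name: str = "input"):
        self.input_name = input_name
        self.nodes: list[Node] = []
        self._last = input_name

    def add(self, name: str, layer: Layer, inputs=None) -> str:
        if inputs is None:
            inputs = (self._last,)
        elif isinstance(inputs, str):
            inputs = (inputs,)
        self.nodes.append(Node(name=name, layer=layer, inputs=tuple(inputs)))
        self._last = name
        return name

    @property
    def last(self) -> str:
        return self._last

    def build(self, output_name: str | None = None) -> Model:
        return Model(self.nodes, self.input_name, output_name or self._last)


def variance_scaling(rng, shape, fan_in, scale: float = 2.0) -> np.ndarray:
    """Truncated-normal fan-in initializer (He-style)."""
    std = np.sqrt(scale / max(fan_in, 1))
    w = rng.standard_normal(size=shape) * std
    return np.clip(w, -2 * std, 2 * std).astype(DTYPE)
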