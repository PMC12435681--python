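"""EfficientNetV2-B0 backbone and block pruning.

Block pruning truncates the backbone after a named *stop layer* (the last
layer of a retained block), then appends a 7x7, 192-channel projection
convolution and a classification head.  Removing blocks from the top keeps
the low-level feature extractors — which carry most of the signal in
histopathology patches — while roughly halving the parameter count per
removed block.  Five nested subnetworks (SBN1..SBN5) result; SBN4 (blocks
1-4, stop layer ``block4c_add``) is the PrunEff4 model.

The backbone is built with the canonical layer-naming scheme
(``block{stage}{letter}_{op}``) so stop layers are plain data.  The head
appended to every pruned subnetwork is: conv 7x7x192 (same padding) ->
batch norm -> leaky ReLU -> GAP -> dense 1024 -> dense output.  With this
head the parameter totals of all five subnetworks (and, with a
GAP -> batch norm -> dense-1024 head, of the unpruned model) reproduce the
published counts exactly; see docs/methods.md for the reconstruction.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

import numpy as np

from .nn import Model, ModelBuilder
from .nn.layers import (Add, BatchNorm, Conv2D, Dense, DepthwiseConv2D,
                        ExpandSpatial, GlobalAvgPool2D, LeakyReLU, Multiply,
                        Sigmoid, SiLU, Softmax)

__all__ = [
    "PruneSpec", "SubnetworkCatalog", "SUBNETWORK_LEVELS", "list_stop_layers",
    "build_backbone", "prune_backbone", "attach_projection_head",
    "build_pruneff",
]

# EfficientNetV2-B0 stage table: (kind, kernel, stride, expand, cin, cout,
# repeats, se_ratio). SE ratio applies to the block's input channel count.
_V2B0_STAGES = [
    ("fused", 3, 1, 1, 32, 16, 1, None),
    ("fused", 3, 2, 4, 16, 32, 2, None),
    ("fused", 3, 2, 4, 32, 48, 2, None),
    ("mbconv", 3, 2, 4, 48, 96, 3, 0.25),
    ("mbconv", 3, 1, 6, 96, 112, 5, 0.25),
    ("mbconv", 3, 2, 6, 112, 192, 8, 0.25),
]
_STEM_FILTERS = 32
_TOP_FILTERS = 1280
_HEAD_HIDDEN = 1024
_PROJECTION_FILTERS = 192
_PROJECTION_KERNEL = 7


@dataclass(frozen=True)
class PruneSpec:
    name: str
    blocks_kept: tuple[int, ...]
    stop_layer: str


class SubnetworkCatalog(dict):
    """Ordered {name: PruneSpec}, largest subnetwork first."""


SUBNETWORK_LEVELS = ["SBN5", "SBN4", "SBN3", "SBN2", "SBN1"]

_CATALOG_ROWS = [
    PruneSpec("SBN5", (1, 2, 3, 4, 5), "block5e_add"),
    PruneSpec("SBN4", (1, 2, 3, 4), "block4c_add"),
    PruneSpec("SBN3", (1, 2, 3), "block3b_add"),
    PruneSpec("SBN2", (1, 2), "block2b_add"),
    PruneSpec("SBN1", (1,), "block1a_project_activation"),
]


def list_stop_layers() -> SubnetworkCatalog:
    return SubnetworkCatalog((s.name, s) for s in _CATALOG_ROWS)


# ----------------------------------------------------------------- backbone

def _letters():
    import string
    return string.ascii_lowercase


def _conv_bn_act(b: ModelBuilder, src: str, name: str, cin: int, cout: int,
                 kernel: int, stride: int, rng, act=True) -> str:
    b.add(f"{name}_conv", Conv2D(cin, cout, kernel, stride, "same",
                                 use_bias=False, rng=rng, name=name), src)
    out = b.add(f"{name}_bn", BatchNorm(cout, name=f"{name}_bn"))
    if act:
        out = b.add(f"{name}_activation", SiLU())
    return out


def _se(b: ModelBuilder, src: str, name: str, channels: int, se_filters: int,
        rng) -> str:
    b.add(f"{name}_se_squeeze", GlobalAvgPool2D(), src)
    b.add(f"{name}_se_reduce", Dense(channels, se_filters, rng=rng,
                                     name=f"{name}_se_reduce"))
    b.add(f"{name}_se_reduce_act", SiLU())
    b.add(f"{name}_se_expand", Dense(se_filters, channels, rng=rng,
                                     name=f"{name}_se_expand"))
    b.add(f"{name}_se_sigmoid", Sigmoid())
    b.add(f"{name}_se_reshape", ExpandSpatial())
    return b.add(f"{name}_se_excite", Multiply(), (src, f"{name}_se_reshape"))


def build_backbone(seed: int = 0) -> Model:
    """The EfficientNetV2-B0 feature path (stem, blocks 1-6, top conv).

    Freshly initialized; a weights file in the model's own npz format may be
    loaded afterwards with ``model.load_weights``.
    """
    rng = np.random.default_rng(seed)
    b = ModelBuilder("input")
    channels = {"input": 3}
    out = _conv_bn_act(b, "input", "stem", 3, _STEM_FILTERS, 3, 2, rng)
    channels[out] = _STEM_FILTERS

    for stage_idx, (kind, k, stride, expand, cin, cout, repeats, se_ratio) in \
            enumerate(_V2B0_STAGES, start=1):
        for rep, letter in zip(range(repeats), _letters()):
            name = f"block{stage_idx}{letter}"
            s = stride if rep == 0 else 1
            bin_ = cin if rep == 0 else cout
            src = out
            if kind == "fused":
                if expand == 1:
                    out = _conv_bn_act(b, src, f"{name}_project", bin_, cout,
                                       k, s, rng, act=True)
                else:
                    mid = _conv_bn_act(b, src, f"{name}_expand", bin_,
                                       bin_ * expand, k, s, rng)
                    out = _conv_bn_act(b, mid, f"{name}_project",
                                       bin_ * expand, cout, 1, 1, rng, act=False)
            else:  # mbconv
                mid = _conv_bn_act(b, src, f"{name}_expand", bin_,
                                   bin_ * expand, 1, 1, rng)
                b.add(f"{name}_dwconv2", DepthwiseConv2D(bin_ * expand, k, s,
                                                         "same", rng=rng,
                                                         name=f"{name}_dwconv2"),
                      mid)
                b.add(f"{name}_bn", BatchNorm(bin_ * expand, name=f"{name}_bn"))
                mid = b.add(f"{name}_activation", SiLU())
                se_filters = max(1, int(bin_ * (se_ratio or 0)))
                mid = _se(b, mid, name, bin_ * expand, se_filters, rng)
                out = _conv_bn_act(b, mid, f"{name}_project", bin_ * expand,
                                   cout, 1, 1, rng, act=False)
            if s == 1 and bin_ == cout:
                out = b.add(f"{name}_add", Add(), (src, out))
            channels[out] = cout

    out = _conv_bn_act(b, out, "top", _V2B0_STAGES[-1][5], _TOP_FILTERS, 1, 1, rng)
    channels[out] = _TOP_FILTERS
    model = b.build(out)
    model.meta = {"arch": "efficientnetv2b0", "channels": channels, "seed": seed}
    return model


def _node_channels(model: Model, name: str) -> int:
    channels = model.meta.get("channels", {})
    if name in channels:
        return channels[name]
    # fall back: infer from a tiny forward pass
    tape = model.forward(np.zeros((1, 64, 64, 3), dtype=np.float32))
    return tape.outputs[name].shape[-1]


def prune_backbone(backbone: Model, stop_layer: str) -> Model:
    """Truncate ``backbone`` after ``stop_layer``.

    The returned extractor shares layer instances with the backbone, so
    retained weights are preserved bit-identically and its output equals the
    backbone's intermediate activation at the stop layer.
    """
    names = backbone.node_names()
    if stop_layer not in names:
        near = difflib.get_close_matches(stop_layer, names, n=3)
        raise KeyError(f"no layer named {stop_layer!r} in backbone; "
                       f"nearest matches: {near}")
    idx = names.index(stop_layer)
    pruned = Model(backbone.nodes[: idx + 1], backbone.input_name, stop_layer)
    pruned.meta = dict(backbone.meta)
    pruned.meta["stop_layer"] = stop_layer
    return pruned


def _classification_tail(b: ModelBuilder, src: str, in_features: int,
                         num_classes: int, rng) -> str:
    units = 1 if num_classes == 2 else num_classes
    b.add("head_hidden", Dense(in_features, _HEAD_HIDDEN, rng=rng,
                               name="head_hidden"), src)
    b.add("head_hidden_act", LeakyReLU(0.3))
    b.add("predictions", Dense(_HEAD_HIDDEN, units, rng=rng, name="predictions"))
    return b.add("predictions_act", Sigmoid() if units == 1 else Softmax())


def attach_projection_head(extractor: Model, num_classes: int,
                           seed: int = 0) -> Model:
    """Append the projection conv (7x7x192, same padding) + BN + leaky ReLU
    -> GAP -> dense head.  Only the appended layers are freshly initialized."""
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    rng = np.random.default_rng(seed)
    cin = _node_channels(extractor, extractor.output_name)
    b = ModelBuilder(extractor.input_name)
    b.nodes = list(extractor.nodes)
    b._last = extractor.output_name
    b.add("head_proj_conv", Conv2D(cin, _PROJECTION_FILTERS, _PROJECTION_KERNEL,
                                   1, "same", use_bias=True, rng=rng,
                                   name="head_proj"))
    b.add("head_proj_bn", BatchNorm(_PROJECTION_FILTERS, name="head_proj_bn"))
    b.add("head_proj_act", LeakyReLU(0.3))
    b.add("avg_pool", GlobalAvgPool2D())
    out = _classification_tail(b, "avg_pool", _PROJECTION_FILTERS, num_classes, rng)
    model = b.build(out)
    model.meta = dict(extractor.meta)
    model.meta.update(num_classes=num_classes)
    return model


def build_pruneff(level: str, num_classes: int, pretrained: bool = False,
                  seed: int = 0, backbone_weights=None) -> Model:
    """Build a pruned subnetwork (``SBN1``..``SBN5``) or the unpruned model
    (``full``; GAP + BN + dense head, no projection conv).

    ``pretrained=True`` requires ``backbone_weights`` (an npz of backbone
    parameters saved with ``Model.save_weights``); no checkpoint is bundled
    with the package.
    """
    backbone = build_backbone(seed=seed)
    if pretrained:
        if backbone_weights is None:
            raise ValueError(
                "pretrained=True needs backbone_weights: no pretrained "
                "checkpoint is bundled; pass a weights file saved from a "
                "previously trained backbone")
        backbone.load_weights(backbone_weights)
    if level == "full":
        rng = np.random.default_rng(seed)
        b = ModelBuilder(backbone.input_name)
        b.nodes = list(backbone.nodes)
        b._last = backbone.output_name
        b.add("avg_pool", GlobalAvgPool2D())
        b.add("head_bn", BatchNorm(_TOP_FILTERS, name="head_bn"))
        out = _classification_tail(b, "head_bn", _TOP_FILTERS, num_classes, rng)
        model = b.build(out)
        model.meta = dict(backbone.meta)
        model.meta.update(num_classes=num_classes, level="full")
        return model
    catalog = list_stop_layers()
    if level not in catalog:
        raise KeyError(f"unknown subnetwork level {level!r}; "
                       f"choose from {SUBNETWORK_LEVELS + ['full']}")
    extractor = prune_backbone(backbone, catalog[level].stop_layer)
    model = attach_projection_head(extractor, num_classes, seed=seed)
    model.meta.update(level=level)
    return model
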