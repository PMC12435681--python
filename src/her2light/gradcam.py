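"""Grad-CAM class activation maps for the numpy-engine models.

For a chosen convolutional layer with activation maps A_k, the gradient of
the target-class score (the pre-softmax/pre-sigmoid logit) is
back-propagated to that layer; each map's weight is the spatial mean of its
gradient, and the raw heatmap is ReLU(sum_k alpha_k A_k).  The raw map is
bilinearly upsampled to the input resolution and min-max normalized, then
optionally alpha-blended over the input as a colour overlay.  A
quantitative localization score against a ground-truth mask (fraction of
heatmap mass inside the mask, and its enrichment over the mask's area
fraction) turns the qualitative "does the model look at stained membranes"
check into a number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .nn import Model
from .nn.core import DTYPE
from .nn.layers import Conv2D, DepthwiseConv2D, Sigmoid, Softmax

__all__ = ["Heatmap", "gradcam", "overlay", "localization_score",
           "conv_node_names"]


@dataclass
class Heatmap:
    raw: np.ndarray        # target-layer resolution, values >= 0
    upsampled: np.ndarray  # input resolution, in [0, 1]
    target_layer: str
    target_class: int


def conv_node_names(model: Model) -> list[str]:
    """Names of all convolution nodes (Grad-CAM targets)."""
    return [n.name for n in model.nodes
            if isinstance(n.layer, (Conv2D, DepthwiseConv2D))]


def _resolve_target(model: Model, name: str) -> str:
    """Accept a conv node name or a layer-table name like ``L-4``; Grad-CAM
    uses the post-activation feature maps of that convolution."""
    candidates = [name, f"{name}_conv"]
    for cand in candidates:
        try:
            node = model.node(cand)
        except KeyError:
            continue
        if not isinstance(node.layer, (Conv2D, DepthwiseConv2D)):
            raise ValueError(f"{name!r} is not a convolutional layer "
                             f"(found {type(node.layer).__name__})")
        # prefer the activation that directly consumes this conv
        from .nn.layers import LeakyReLU, ReLU, SiLU
        for n in model.nodes:
            if n.inputs == (cand,) and isinstance(n.layer, (LeakyReLU, ReLU, SiLU)):
                return n.name
        return cand
    raise KeyError(f"no convolutional layer named {name!r}; conv layers: "
                   f"{conv_node_names(model)[:8]}...")


def _logit_seed(model: Model, tape, target_class):
    """Seed gradient at the pre-activation logits of the output head."""
    out_node = model.node(model.output_name)
    if not isinstance(out_node.layer, (Sigmoid, Softmax)):
        raise ValueError("model output must be a sigmoid/softmax activation")
    logit_name = out_node.inputs[0]
    probs = tape.outputs[model.output_name]
    logits = tape.outputs[logit_name]
    if logits.shape[-1] == 1:  # binary sigmoid head
        if target_class is None:
            target_class = int(probs[0, 0] >= 0.5)
        seed = np.array([[1.0 if target_class == 1 else -1.0]], dtype=DTYPE)
    else:
        if target_class is None:
            target_class = int(probs[0].argmax())
        if not 0 <= target_class < logits.shape[-1]:
            raise ValueError(f"target_class {target_class} out of range")
        seed = np.zeros_like(logits)
        seed[0, target_class] = 1.0
    return logit_name, seed, target_class


def gradcam(model: Model, image: np.ndarray, target_layer: str,
            target_class: int | None = None) -> Heatmap:
    """Compute a Grad-CAM heatmap for one (H, W, 3) image."""
    image = np.asarray(image, dtype=DTYPE)
    if image.ndim != 3:
        raise ValueError("gradcam expects a single (H, W, C) image")
    node_name = _resolve_target(model, target_layer)
    x = image[None]
    tape = model.forward(x, training=False)
    logit_name, seed, target_class = _logit_seed(model, tape, target_class)
    grads = model.backward(tape, {logit_name: seed}, stop_at=node_name)
    if node_name not in grads:
        raise ValueError(f"no differentiable path from the output to {target_layer!r}")
    acts = tape.outputs[node_name][0]          # (h, w, c)
    grad = grads[node_name][0]
    alpha = grad.mean(axis=(0, 1))             # GAP of the gradients
    raw = np.maximum((acts * alpha).sum(axis=-1), 0.0)
    up = resize(raw, image.shape[:2], order=1, mode="edge",
                anti_aliasing=False, preserve_range=True)
    up = np.maximum(up, 0.0)
    if up.max() > 0:
        up = (up - up.min()) / (up.max() - up.min())
    return Heatmap(raw=raw, upsampled=up.astype(float),
                   target_layer=target_layer, target_class=target_class)


def overlay(heatmap: Heatmap, image: np.ndarray, alpha: float = 0.4,
            cmap: str = "jet") -> np.ndarray:
    """Alpha-blend the colormapped heatmap over the input image (both in
    [0, 1]); alpha=0 returns the image, alpha=1 the pure colormap."""
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib import colormaps

    image = np.asarray(image, dtype=float)
    hm = heatmap.upsampled
    if hm.shape != image.shape[:2]:
        raise ValueError("heatmap and image spatial dims differ")
    colored = colormaps[cmap](hm)[..., :3]
    return np.clip((1 - alpha) * image + alpha * colored, 0, 1)


def localization_score(heatmap: Heatmap, mask: np.ndarray):
    """(fraction of heatmap mass inside the mask, enrichment ratio).

    Enrichment 1 means the heatmap is no more concentrated on the masked
    structures than a uniform map; >1 means preferential attention."""
    mask = np.asarray(mask).astype(bool)
    hm = heatmap.upsampled
    if mask.shape != hm.shape:
        raise ValueError("mask must match the upsampled heatmap shape")
    if not mask.any():
        raise ValueError("mask has no positive pixels")
    total = hm.sum()
    if total == 0:
        return 0.0, 0.0
    score = float(hm[mask].sum() / total)
    area_fraction = mask.mean()
    return score, float(score / area_fraction)
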