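"""Training protocol: Adam, reduce-LR-on-plateau, early stopping,
flip/shift augmentation, layer freezing, and the two pretraining workflows
(generic transfer vs domain-specific pretraining followed by fine-tuning
with a re-initialized head).

Validation accuracy is the monitored quantity.  When it fails to improve
for ``plateau_patience`` epochs the learning rate is multiplied by
``lr_factor`` (0.1: a factor-of-ten reduction) and the wait counter resets;
training stops early after ``early_stop_patience`` stale epochs and the
best-validation-accuracy weights are restored.  Everything is reproducible
from ``TrainConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import Adam, Model, cross_entropy, predictions_from_probs
from .nn.core import DTYPE, Node
from .nn.layers import Dense, Sigmoid, Softmax

__all__ = [
    "AugmentConfig", "TrainConfig", "PretrainPlan", "TrainingHistory",
    "lr_schedule_step", "augment_batch", "freeze_first_layers", "train",
    "evaluate", "replace_head", "domain_pretrain_finetune",
]

# Initial learning rates used in the study: 6e-2 for freshly initialized
# networks, 6e-3 when fine-tuning with frozen layers, 6e-4 for full
# fine-tuning of a pretrained network.
LR_FRESH, LR_FROZEN_FINETUNE, LR_FULL_FINETUNE = 6e-2, 6e-3, 6e-4


@dataclass(frozen=True)
class AugmentConfig:
    horizontal_flip: bool = True
    vertical_flip: bool = True
    width_shift_fraction: float = 0.1
    height_shift_fraction: float = 0.1
    fill_mode: str = "nearest"  # nearest | reflect | constant

    def __post_init__(self):
        if not (0 <= self.width_shift_fraction < 0.5
                and 0 <= self.height_shift_fraction < 0.5):
            raise ValueError("shift fractions must be in [0, 0.5)")
        if self.fill_mode not in ("nearest", "reflect", "constant"):
            raise ValueError(f"unknown fill_mode {self.fill_mode!r}")

    @property
    def enabled(self) -> bool:
        return (self.horizontal_flip or self.vertical_flip
                or self.width_shift_fraction > 0 or self.height_shift_fraction > 0)


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = LR_FRESH
    lr_factor: float = 0.1
    plateau_patience: int = 5
    early_stop_patience: int = 10
    max_epochs: int = 80
    batch_size: int = 24
    l2: float = 1e-4
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must be in (0, 1)")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    def __len__(self):
        return len(self.val_accuracy)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self) + 1),
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
            "learning_rate": self.learning_rate,
        })


def _replay_lr(val_accuracies, cfg: TrainConfig) -> float:
    """Learning rate after observing the given validation-accuracy trace."""
    lr, best, wait = cfg.initial_lr, -np.inf, 0
    for acc in val_accuracies:
        if acc > best:
            best, wait = acc, 0
        else:
            wait += 1
            if wait >= cfg.plateau_patience:
                lr *= cfg.lr_factor
                wait = 0
    return lr


def lr_schedule_step(history: TrainingHistory, cfg: TrainConfig) -> float:
    """Next epoch's learning rate given the history so far."""
    if len(history) < 1:
        raise ValueError("lr_schedule_step needs at least one completed epoch")
    return _replay_lr(history.val_accuracy, cfg)


def augment_batch(images: np.ndarray, cfg: AugmentConfig, rng) -> np.ndarray:
    """Independent per-image flips (p=0.5 per enabled axis) and integer-pixel
    translations within +-shift_fraction of each dimension."""
    images = np.asarray(images)
    if not cfg.enabled:
        return images
    out = np.empty_like(images)
    h, w = images.shape[1:3]
    dy_max = int(cfg.height_shift_fraction * h)
    dx_max = int(cfg.width_shift_fraction * w)
    pad_mode = {"nearest": "edge", "reflect": "reflect", "constant": "constant"}[cfg.fill_mode]
    for i, img in enumerate(images):
        if cfg.horizontal_flip and rng.random() < 0.5:
            img = img[:, ::-1]
        if cfg.vertical_flip and rng.random() < 0.5:
            img = img[::-1]
        dy = int(rng.integers(-dy_max, dy_max + 1)) if dy_max else 0
        dx = int(rng.integers(-dx_max, dx_max + 1)) if dx_max else 0
        if dy or dx:
            img = np.pad(img, ((abs(dy), abs(dy)), (abs(dx), abs(dx)), (0, 0)),
                         mode=pad_mode)
            y0 = abs(dy) - dy
            x0 = abs(dx) - dx
            img = img[y0 : y0 + h, x0 : x0 + w]
        out[i] = img
    return out


def _is_bn_statistic(p) -> bool:
    return p.name.endswith(("moving_mean", "moving_variance"))


def freeze_first_layers(model: Model, n: int) -> Model:
    """Freeze the first ``n`` weighted layers (topological order from the
    input); remaining layers are left/made trainable."""
    weighted = model.weighted_layers()
    if not 0 <= n <= len(weighted):
        raise ValueError(f"n must be in [0, {len(weighted)}], got {n}")
    for i, (_, layer) in enumerate(weighted):
        for p in layer.parameters():
            if not _is_bn_statistic(p):
                p.trainable = i >= n
    return model


def _num_classes_of(model: Model) -> int:
    out_dim = None
    node = model.node(model.output_name)
    dense = model.node(node.inputs[0])
    out_dim = dense.layer.w.value.shape[1]
    return 2 if out_dim == 1 else out_dim


def _check_labels(y, model: Model, what: str):
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError(f"{what} dataset is empty")
    k = _num_classes_of(model)
    if y.min() < 0 or y.max() >= k:
        raise ValueError(f"{what} labels must be in [0, {k}), got "
                         f"range [{y.min()}, {y.max()}]")
    return y.astype(int)


def evaluate(model: Model, x, y, batch_size: int = 32):
    """Inference-mode (loss, accuracy) on a labelled set."""
    probs = model.predict(x, batch_size=batch_size)
    loss, _ = cross_entropy(probs, np.asarray(y).astype(int), probs.shape[-1])
    acc = float((predictions_from_probs(probs) == np.asarray(y)).mean())
    return loss, acc


def train(model: Model, train_set, val_set, cfg: TrainConfig):
    """Fit ``model`` on ``train_set`` = (images, labels); returns
    ``(model, TrainingHistory)`` with best-validation weights restored."""
    x_train, y_train = train_set
    x_val, y_val = val_set
    x_train = np.asarray(x_train, dtype=DTYPE)
    x_val = np.asarray(x_val, dtype=DTYPE)
    y_train = _check_labels(y_train, model, "train")
    y_val = _check_labels(y_val, model, "validation")

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.initial_lr, weight_decay=cfg.l2)
    history = TrainingHistory()
    best_acc, best_weights, best_epoch = -np.inf, None, -1
    lr, wait_lr, wait_stop = cfg.initial_lr, 0, 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_train))
        losses, correct = [], 0
        opt.lr = lr
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = augment_batch(x_train[idx], cfg.augment, rng)
            yb = y_train[idx]
            tape = model.forward(xb, training=True, rng=rng)
            probs = tape.outputs[model.output_name]
            loss, grad = cross_entropy(probs, yb, probs.shape[-1],
                                       l2=cfg.l2, model=model)
            model.zero_grad()
            model.backward(tape, {model.output_name: grad})
            opt.step()
            losses.append(loss)
            correct += int((predictions_from_probs(probs) == yb).sum())

        val_loss, val_acc = evaluate(model, x_val, y_val,
                                     batch_size=cfg.batch_size)
        history.train_loss.append(float(np.mean(losses)))
        history.train_accuracy.append(correct / len(x_train))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.learning_rate.append(lr)

        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_weights = {k: v.copy() for k, v in model.get_weights().items()}
            wait_lr = wait_stop = 0
        else:
            wait_lr += 1
            wait_stop += 1
            if wait_lr >= cfg.plateau_patience:
                lr *= cfg.lr_factor
                wait_lr = 0
            if wait_stop >= cfg.early_stop_patience:
                history.stopped_early = True
                break

    if best_weights is not None:
        model.set_weights(best_weights)
    history.best_epoch = best_epoch
    return model, history


# ------------------------------------------------------------- pretraining

@dataclass
class PretrainPlan:
    source_train: tuple
    source_val: tuple
    num_source_classes: int
    target_train: tuple
    target_val: tuple
    num_target_classes: int
    frozen_layer_count: int = 0
    head_reinit: bool = True  # the head is always re-initialized


def replace_head(model: Model, num_classes: int, seed: int = 0) -> Model:
    """Swap the final dense layer (and its activation) for a freshly
    initialized head of the requested arity; all other layers keep their
    instances, hence their weights."""
    rng = np.random.default_rng(seed)
    out_node = model.node(model.output_name)
    dense_name = out_node.inputs[0]
    dense_node = model.node(dense_name)
    if not isinstance(dense_node.layer, Dense):
        raise ValueError("model output is not activation(dense(...))")
    in_features = dense_node.layer.w.value.shape[0]
    units = 1 if num_classes == 2 else num_classes
    new_dense = Dense(in_features, units, rng=rng,
                      name=dense_node.layer.w.name.rsplit("/", 1)[0])
    new_act = Sigmoid() if units == 1 else Softmax()
    nodes = []
    for n in model.nodes:
        if n.name == dense_name:
            nodes.append(Node(n.name, new_dense, n.inputs))
        elif n.name == model.output_name:
            nodes.append(Node(n.name, new_act, n.inputs))
        else:
            nodes.append(n)
    new_model = Model(nodes, model.input_name, model.output_name)
    new_model.meta = dict(getattr(model, "meta", {}))
    new_model.meta["num_classes"] = num_classes
    return new_model


def domain_pretrain_finetune(builder, plan: PretrainPlan,
                             pretrain_cfg: TrainConfig,
                             finetune_cfg: TrainConfig):
    """Two-stage workflow: train on the source task, transplant the feature
    extractor (head re-initialized at target arity, optionally freezing the
    first ``frozen_layer_count`` weighted layers), fine-tune on the target.

    ``builder(num_classes, seed)`` must return a runnable model.  Returns
    ``(model, pretrain_history, finetune_history)``.
    """
    model = builder(plan.num_source_classes, pretrain_cfg.seed)
    model, hist1 = train(model, plan.source_train, plan.source_val, pretrain_cfg)
    model = replace_head(model, plan.num_target_classes, seed=finetune_cfg.seed)
    freeze_first_layers(model, plan.frozen_layer_count)
    model, hist2 = train(model, plan.target_train, plan.target_val, finetune_cfg)
    return model, hist1, hist2
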