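"""Adam optimizer and cross-entropy losses."""

from __future__ import annotations

import numpy as np

from .core import DTYPE, Model


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay  # L2 on parameters flagged `regularized`
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if not p.trainable:
                continue
            g = p.grad
            if self.weight_decay and p.regularized:
                g = g + 2.0 * self.weight_decay * p.value
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)


def cross_entropy(probs: np.ndarray, y: np.ndarray, num_classes: int,
                  l2: float = 0.0, model: Model | None = None):
    """Mean cross-entropy loss and its gradient w.r.t. the model output.

    ``probs`` is a (N, 1) sigmoid output (binary, y in {0,1}) or an (N, K)
    softmax output (y integer labels).  The optional L2 penalty term is
    reported in the loss for monitoring; its gradient is applied by the
    optimizer's weight decay.
    """
    n = len(y)
    eps = 1e-7
    p = np.clip(probs, eps, 1 - eps)
    if probs.shape[-1] == 1:
        yf = y.astype(DTYPE).reshape(-1, 1)
        loss = -(yf * np.log(p) + (1 - yf) * np.log(1 - p)).mean()
        grad = ((p - yf) / (p * (1 - p))) / n
    else:
        onehot = np.eye(probs.shape[-1], dtype=DTYPE)[y]
        loss = -(onehot * np.log(p)).sum(axis=-1).mean()
        grad = -(onehot / p) / n
    if l2 and model is not None:
        loss += l2 * sum(float((q.value ** 2).sum())
                         for q in model.parameters() if q.regularized)
    return float(loss), grad.astype(DTYPE)


def predictions_from_probs(probs: np.ndarray) -> np.ndarray:
    """Class indices: 0.5 threshold for a sigmoid column, argmax otherwise."""
    if probs.shape[-1] == 1:
        return (probs[:, 0] >= 0.5).astype(int)
    return probs.argmax(axis=-1)
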