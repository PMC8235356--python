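"""Optimizer, plateau learning-rate schedule and the fit loop.

Training follows the protocol used throughout the package: categorical
cross-entropy on one-hot labels, 30% of the provided data held out for
validation, learning rate cut by a fixed factor when the validation loss
fails to improve for ``patience`` consecutive epochs, training stopped
after continued stagnation, and the weights restored to those at the best
validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def one_hot(y, n_classes):
    out = np.zeros((len(y), n_classes), np.float32)
    out[np.arange(len(y)), y] = 1.0
    return out


def softmax_cross_entropy(logits, y_onehot):
    """Mean categorical cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(logits)
    loss = float(-np.sum(y_onehot * np.log(np.clip(p, 1e-12, None))) / n)
    return loss, (p - y_onehot) / n


@dataclass
class TrainingConfig:
    """Hyperparameters of the fit loop (times in epochs)."""

    val_fraction: float = 0.30
    patience_epochs: int = 10
    initial_lr: float = 1e-3
    lr_factor: float = 0.1
    max_epochs: int = 200
    batch_size: int = 32
    stop_after_reductions: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")


class PlateauScheduler:
    """Reduce-on-plateau learning rate control with early stopping.

    Feed one validation loss per epoch to :meth:`step`.  After ``patience``
    consecutive epochs without improvement the learning rate is multiplied
    by ``factor`` (an event ``("reduce_lr", epoch, new_lr)`` is recorded);
    after ``stop_after_reductions`` reductions with no intervening
    improvement, ``step`` returns False to stop training.
    """

    def __init__(self, initial_lr=1e-3, patience=10, factor=0.1,
                 stop_after_reductions=2):
        self.lr = float(initial_lr)
        self.patience = patience
        self.factor = factor
        self.stop_after_reductions = stop_after_reductions
        self.best = np.inf
        self.best_epoch = -1
        self.epochs_since_best = 0
        self.reductions_since_best = 0
        self.events = []
        self.epoch = 0

    def step(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; returns False to stop."""
        self.epoch += 1
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.best_epoch = self.epoch
            self.epochs_since_best = 0
            self.reductions_since_best = 0
            return True
        self.epochs_since_best += 1
        if self.epochs_since_best % self.patience == 0:
            self.reductions_since_best += 1
            if self.reductions_since_best > self.stop_after_reductions:
                self.events.append(("stop", self.epoch, self.lr))
                return False
            self.lr *= self.factor
            self.events.append(("reduce_lr", self.epoch, self.lr))
        return True


class Adam:
    def __init__(self, tensors, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.tensors = tensors  # list of (layer, name, array)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(a) for _, _, a in tensors]
        self.v = [np.zeros_like(a) for _, _, a in tensors]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for i, (layer, name, arr) in enumerate(self.tensors):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            arr -= self.lr * corr * self.m[i] / (np.sqrt(self.v[i]) + self.eps)


def train_val_split(n, val_fraction, rng, labels=None):
    """Shuffled split; stratified by label when labels are given."""
    idx = np.arange(n)
    if labels is None:
        rng.shuffle(idx)
        n_val = max(1, int(round(val_fraction * n)))
        return idx[n_val:], idx[:n_val]
    labels = np.asarray(labels)
    train, val = [], []
    for lab in np.unique(labels):
        sub = idx[labels == lab]
        rng.shuffle(sub)
        n_val = max(1, int(round(val_fraction * len(sub)))) if len(sub) > 1 else 0
        val.extend(sub[:n_val])
        train.extend(sub[n_val:])
    train, val = np.array(train), np.array(val)
    rng.shuffle(train)
    return train, val


def fit(model, x, y, n_classes, config: TrainingConfig,
        loss_and_grad=softmax_cross_entropy, forward_kwargs=None):
    """Train a Sequential model; returns a history dict.

    ``x``/``y`` are the full provided data; the validation split is made
    internally.  The model is left holding the weights of the best
    validation epoch.
    """
    rng = np.random.default_rng(config.seed)
    tr, va = train_val_split(len(x), config.val_fraction, rng, labels=y)
    if len(tr) == 0 or len(va) == 0:
        raise ValueError("not enough data for a train/validation split")
    y_oh = one_hot(np.asarray(y), n_classes)
    sched = PlateauScheduler(config.initial_lr, config.patience_epochs,
                             config.lr_factor, config.stop_after_reductions)
    opt = Adam(model.param_tensors(), lr=sched.lr)
    history = {"train_loss": [], "val_loss": [], "lr": [], "events": sched.events}
    best_state = model.state()
    for epoch in range(config.max_epochs):
        order = rng.permutation(tr)
        losses = []
        for start in range(0, len(order), config.batch_size):
            bi = order[start:start + config.batch_size]
            logits = model.forward(x[bi], training=True)
            loss, dlogits = loss_and_grad(logits, y_oh[bi])
            model.backward(dlogits.astype(np.float32))
            opt.lr = sched.lr
            opt.step()
            losses.append(loss)
        val_logits = model.forward(x[va], training=False)
        val_loss, _ = loss_and_grad(val_logits, y_oh[va])
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["lr"].append(sched.lr)
        improved = val_loss < sched.best
        keep_going = sched.step(val_loss)
        if improved:
            best_state = model.state()
        if not keep_going:
            break
    model.restore(best_state)
    history["best_epoch"] = sched.best_epoch
    return history
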