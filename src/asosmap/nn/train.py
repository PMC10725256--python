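"""Training loop: SGD with the 1cycle learning-rate policy, plus checkpoints.

The score head is sigmoid-activated in both modes; regression minimizes the
mean squared error against continuous targets in [0, 1], classification the
binary cross-entropy against {0, 1} labels.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .network import HeadSpec, Network, TrainConfig, UNetSpec

__all__ = [
    "one_cycle_lr",
    "train_model",
    "evaluate_nrmse",
    "save_checkpoint",
    "load_checkpoint",
]


def one_cycle_lr(step: int, total_steps: int, max_lr: float,
                 pct_start: float = 0.3, div_factor: float = 25.0,
                 final_div_factor: float = 1e4) -> float:
    """Learning rate at ``step``: cosine warm-up to ``max_lr``, cosine anneal
    down to ``max_lr / (div_factor * final_div_factor)`` within one cycle."""
    initial = max_lr / div_factor
    final = initial / final_div_factor
    up_steps = max(1, int(round(pct_start * total_steps)))
    if step < up_steps:
        t = step / up_steps
        return initial + (max_lr - initial) * (1 - np.cos(np.pi * t)) / 2
    t = (step - up_steps) / max(1, total_steps - up_steps)
    return final + (max_lr - final) * (1 + np.cos(np.pi * t)) / 2


def _loss_and_grad(pred: np.ndarray, target: np.ndarray, mode: str):
    n = len(pred)
    if mode == "regression":
        diff = pred - target
        return float(np.mean(diff * diff)), (2.0 / n) * diff
    if mode == "classification":
        p = np.clip(pred, 1e-7, 1 - 1e-7)
        loss = -float(np.mean(target * np.log(p) + (1 - target) * np.log(1 - p)))
        grad = (p - target) / (p * (1 - p)) / n
        return loss, grad
    raise ValueError(f"unknown mode {mode!r}")


def _epoch_loss(network: Network, x: np.ndarray, y: np.ndarray, mode: str,
                batch_size: int) -> float:
    losses, weights = [], []
    for i in range(0, len(x), batch_size):
        pred = network.forward(x[i:i + batch_size], train=False)
        loss, _ = _loss_and_grad(pred, y[i:i + batch_size], mode)
        losses.append(loss)
        weights.append(len(pred))
    return float(np.average(losses, weights=weights))


def train_model(network: Network, x_train: np.ndarray, y_train: np.ndarray,
                x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
                config: TrainConfig | None = None,
                rotate_augment: bool = True) -> dict:
    """Train in place; returns a history dict and restores the best-val weights
    (best-train when no validation set is given)."""
    config = config or TrainConfig()
    if len(x_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    params = network.parameters()
    velocity = [np.zeros_like(p.data) for p in params]

    n = len(x_train)
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    total_steps = config.epochs * steps_per_epoch
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best = (np.inf, None)
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            if rotate_augment:
                ks = rng.integers(0, 4, size=len(idx))
                xb = np.stack([np.rot90(im, k, axes=(1, 2)) for im, k in zip(xb, ks)])
            lr = one_cycle_lr(step, total_steps, config.max_lr)
            pred = network.forward(xb, train=True)
            loss, gpred = _loss_and_grad(pred, yb, config.mode)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, step {step}: loss={loss}"
                )
            for p in params:
                p.zero_grad()
            network.backward(gpred.astype(pred.dtype))
            for p, v in zip(params, velocity):
                g = p.grad + config.weight_decay * p.data
                v *= config.momentum
                v -= lr * g
                p.data += v
            epoch_losses.append(loss)
            history["lr"].append(lr)
            step += 1
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if x_val is not None and len(x_val):
            vloss = _epoch_loss(network, x_val, y_val, config.mode, config.batch_size)
            history["val_loss"].append(vloss)
            monitor = vloss
        else:
            monitor = history["train_loss"][-1]
        if monitor < best[0]:
            best = (monitor, [p.data.copy() for p in params])
    if best[1] is not None:
        for p, data in zip(params, best[1]):
            p.data[...] = data
    history["best_loss"] = best[0]
    return history


def evaluate_nrmse(predictions, targets, y_min: float = 0.0, y_max: float = 1.0) -> float:
    """Root-mean-square error normalized by the target range."""
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictions.size == 0 or predictions.shape != targets.shape:
        raise ValueError("predictions and targets must be equal-length and non-empty")
    mse = float(np.mean((predictions - targets) ** 2))
    return float(np.sqrt(mse) / (y_max - y_min))


def _bn_layers(network: Network):
    blocks = network.unet.enc + [network.unet.bottleneck] + network.unet.dec
    return [b.bn for b in blocks]


def save_checkpoint(network: Network, path, train_config: TrainConfig | None = None,
                    extra_meta: dict | None = None) -> None:
    """Single-archive checkpoint: weights, batch-norm statistics and specs."""
    meta = {
        "unet_spec": dataclasses.asdict(network.unet_spec),
        "head_spec": dataclasses.asdict(network.head_spec),
        "train_tile_size": network.train_tile_size,
        "train_config": dataclasses.asdict(train_config) if train_config else None,
        "extra": extra_meta or {},
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(network.parameters())}
    for i, bn in enumerate(_bn_layers(network)):
        arrays[f"bn_{i}_mean"] = bn.running_mean
        arrays[f"bn_{i}_var"] = bn.running_var
    np.savez_compressed(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> tuple[Network, dict]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        network = Network(
            unet_spec=UNetSpec(**meta["unet_spec"]),
            head_spec=HeadSpec(**meta["head_spec"]),
            train_tile_size=meta["train_tile_size"],
        )
        for i, p in enumerate(network.parameters()):
            p.data[...] = data[f"param_{i}"]
        for i, bn in enumerate(_bn_layers(network)):
            bn.running_mean[...] = data[f"bn_{i}_mean"]
            bn.running_var[...] = data[f"bn_{i}_var"]
    return network, meta
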