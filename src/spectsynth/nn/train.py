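"""Training harness: u-net configurations, schedules, Adam, model store.

A :class:`UNetConfig` mirrors one row of the study's network table: which
noise realization the training pairs use, how many projections go in and
out, the cyclic expansion target, the angular shift theta between input
and output projections, dataset sizes and the learning-rate schedule.
Training minimizes the L1 loss on normalized stacks with Adam and keeps
the weights of the epoch with the lowest validation loss (earliest epoch
wins ties).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .unet import UNet3D

__all__ = [
    "LRSchedule", "step_schedule", "linear_schedule",
    "UNetConfig", "TrainedModel", "Adam", "train",
]

F32 = np.float32


@dataclass(frozen=True)
class LRSchedule:
    """Learning-rate schedule; ``kind`` is ``step`` (halving every
    ``halve_every`` epochs) or ``linear`` (from ``initial`` to ``final``
    over all epochs).  Epochs are 1-based."""

    kind: str
    initial: float
    halve_every: int = 0
    final: float = 0.0

    def __call__(self, epoch: int, total_epochs: int) -> float:
        if self.kind == "step":
            return self.initial * 0.5 ** ((epoch - 1) // self.halve_every)
        if self.kind == "linear":
            if total_epochs <= 1:
                return self.initial
            frac = (epoch - 1) / (total_epochs - 1)
            return self.initial + (self.final - self.initial) * frac
        raise ValueError(f"unknown schedule kind {self.kind!r}")


def step_schedule(initial: float, halve_every: int) -> LRSchedule:
    return LRSchedule("step", initial, halve_every=halve_every)


def linear_schedule(initial: float, final: float) -> LRSchedule:
    return LRSchedule("linear", initial, final=final)


@dataclass(frozen=True)
class UNetConfig:
    """One network of the study."""

    label: str
    noise_realization: str = "A"
    n_input: int = 30
    n_output: int = 30
    cyclic_target: int = 32
    rotation_shift_deg: float = 6.0
    n_train: int = 105
    n_val: int = 10
    epochs: int = 15
    lr_schedule: LRSchedule = field(
        default_factory=lambda: step_schedule(7e-4, 5))
    batch_size: int = 5
    base_channels: int = 4
    depth: int = 3
    negative_slope: float = 0.01
    #: ``noisy`` for angular-interpolation networks (the target is the
    #: same noise realization at shifted angles); ``noise-free`` for a
    #: pure-denoising network (theta = 0).
    target_kind: str = "noisy"

    def __post_init__(self):
        if self.cyclic_target < self.n_input:
            raise ValueError("cyclic target must be >= input length")

    def build(self, seed: int = 0) -> UNet3D:
        return UNet3D(self.base_channels, self.depth,
                      self.negative_slope, seed=seed)


@dataclass
class TrainedModel:
    weights: list[np.ndarray]
    config: UNetConfig
    best_val_loss: float
    best_epoch: int
    history: pd.DataFrame

    def build_network(self) -> UNet3D:
        net = self.config.build()
        net.set_weights(self.weights)
        return net

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint (weights + config + loss history)."""
        payload = {
            "weights": self.weights,
            "config": asdict(self.config),
            "best_val_loss": self.best_val_loss,
            "best_epoch": self.best_epoch,
            "history": self.history.to_dict("list"),
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        cfgd = payload["config"]
        cfgd["lr_schedule"] = LRSchedule(**cfgd["lr_schedule"])
        return cls(payload["weights"], UNetConfig(**cfgd),
                   payload["best_val_loss"], payload["best_epoch"],
                   pd.DataFrame(payload["history"]))


class Adam:
    """Adam optimizer with the reference defaults."""

    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (lr / bias1) * m / (np.sqrt(v / bias2) + self.eps)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train(config: UNetConfig, inputs: np.ndarray, targets: np.ndarray,
          val_inputs: np.ndarray, val_targets: np.ndarray,
          seed: int = 0, verbose: bool = False) -> TrainedModel:
    """Train a u-net on normalized stack pairs.

    ``inputs``/``targets`` have shape (n, D, H, W); stacks must already
    be cyclically expanded and normalized.  Fully reproducible under
    ``seed`` (weight init and batch shuffling).
    """
    if len(inputs) == 0:
        raise ValueError("empty training set")
    inputs = np.asarray(inputs, dtype=F32)[..., None]
    targets = np.asarray(targets, dtype=F32)[..., None]
    val_inputs = np.asarray(val_inputs, dtype=F32)[..., None]
    val_targets = np.asarray(val_targets, dtype=F32)[..., None]

    net = config.build(seed=seed)
    opt = Adam(net.parameters())
    rng = np.random.default_rng(seed + 1)

    best = (np.inf, -1, None)  # val loss, epoch, weights
    rows = []
    for epoch in range(1, config.epochs + 1):
        lr = config.lr_schedule(epoch, config.epochs)
        losses = []
        for idx in _batches(len(inputs), config.batch_size, rng):
            net.zero_grad()
            loss = net.loss_and_grad(inputs[idx], targets[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            opt.step(lr)
            losses.append(loss)
        train_loss = float(np.mean(losses))
        val_losses = []
        for i in range(0, len(val_inputs), config.batch_size):
            pred = net.predict(val_inputs[i:i + config.batch_size])
            val_losses.append(
                np.abs(pred - val_targets[i:i + config.batch_size]).mean())
        val_loss = float(np.mean(val_losses)) if val_losses else train_loss
        rows.append((epoch, lr, train_loss, val_loss))
        if verbose:
            print(f"[{config.label}] epoch {epoch:3d} lr={lr:.2e} "
                  f"train={train_loss:.5f} val={val_loss:.5f}")
        if val_loss < best[0]:  # strict: earliest epoch wins ties
            best = (val_loss, epoch, net.get_weights())

    history = pd.DataFrame(rows,
                           columns=["epoch", "lr", "train_loss", "val_loss"])
    return TrainedModel(best[2], config, best[0], best[1], history)
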