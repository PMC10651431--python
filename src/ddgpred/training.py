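"""End-to-end training: Adam, linear warmup/decay, per-example updates.

The recipe follows common practice for fine-tuning transformer regressors:
batch size one, three epochs, and a learning rate ramped linearly from 0 to
its peak over the first 30% of all training examples, then linearly back to
0.  Total steps for the schedule = epochs x dataset size.  The loss is mean
squared error, matching the RMSE-centric evaluation.

The peak learning rate is a free parameter: 1e-5 is the right order for
fine-tuning a large language-model backbone, while the small NumPy heads
used in CPU-only work train well around 1e-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import VariantPair


@dataclass
class TrainConfig:
    peak_lr: float = 1e-5
    warmup_fraction: float = 0.30
    epochs: int = 3
    batch_size: int = 1
    seed: int = 0
    freeze_backbone: bool = False
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ValueError("warmup fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size != 1:
            raise ValueError("only per-example updates (batch size 1) are supported")


def lr_at(step: float, total_steps: int, config: TrainConfig) -> float:
    """Piecewise-linear learning rate: 0 at step 0, peak at
    ``warmup_fraction * total_steps``, 0 at ``total_steps``."""
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    peak_step = config.warmup_fraction * total_steps
    if step <= peak_step:
        return config.peak_lr * step / peak_step if peak_step > 0 else 0.0
    return config.peak_lr * (total_steps - step) / (total_steps - peak_step)


class Adam:
    """Plain Adam over a dict of named parameter arrays (updated in place)."""

    def __init__(self, arrays: dict[str, np.ndarray], config: TrainConfig):
        self.arrays = arrays
        self.config = config
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        c = self.config
        self.t += 1
        bc1 = 1.0 - c.adam_beta1 ** self.t
        bc2 = 1.0 - c.adam_beta2 ** self.t
        for name, p in self.arrays.items():
            g = grads.get(name)
            if g is None:
                continue
            self.m[name] = c.adam_beta1 * self.m[name] + (1 - c.adam_beta1) * g
            self.v[name] = c.adam_beta2 * self.v[name] + (1 - c.adam_beta2) * g * g
            p -= lr * (self.m[name] / bc1) / (np.sqrt(self.v[name] / bc2) + c.adam_eps)


@dataclass
class TrainResult:
    loss_trace: np.ndarray
    epoch_losses: list = field(default_factory=list)


def train_initialized(model, pairs: list[VariantPair], targets: np.ndarray,
                      config: TrainConfig) -> TrainResult:
    """Per-example MSE training of an already-initialised head.

    Data order is reshuffled once per epoch from the run seed; the schedule
    step s uses ``lr_at(s + 1)`` so the very first update is not a no-op.
    Deterministic: same seed and data give identical final weights on the
    mock backbone.  Aborts on a non-finite loss.
    """
    n = len(pairs)
    if n == 0:
        raise ValueError("empty training set")
    targets = np.asarray(targets, dtype=float)
    arrays = model.trainable_arrays()
    optimizer = Adam(arrays, config)
    total_steps = config.epochs * n
    rng = np.random.default_rng(config.seed)
    losses = np.empty(total_steps)
    epoch_losses = []
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for idx in order:
            pair, target = pairs[idx], targets[idx]
            y, cache = model._forward(pair)
            err = y - target
            loss = err * err
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at step {step} (prediction {y!r}); "
                    "lower the learning rate")
            grads = model._backward(2.0 * err, cache)
            optimizer.step(grads, lr_at(step + 1, total_steps, config))
            losses[step] = loss
            epoch_loss += loss
            step += 1
        epoch_losses.append(epoch_loss / n)
    model.loss_trace_ = losses
    return TrainResult(loss_trace=losses, epoch_losses=epoch_losses)


def train(head_spec_or_all, dataset: list[VariantPair], backbone,
          config: TrainConfig | None = None, hidden_width: int = 128,
          antisymmetric: bool = False):
    """Train one head (``(source, merge)`` tuple) or, with ``"all"``, the
    five-member ensemble.  Returns the fitted estimator; its
    ``loss_trace_`` carries the per-example losses.
    """
    from .heads import EnsembleRegressor, HeadRegressor

    config = config or TrainConfig()
    if len(dataset) == 0:
        raise ValueError("empty training set")
    common = dict(hidden_width=hidden_width,
                  learning_rate=config.peak_lr,
                  warmup_fraction=config.warmup_fraction,
                  epochs=config.epochs, seed=config.seed,
                  freeze_backbone=config.freeze_backbone,
                  antisymmetric=antisymmetric)
    if head_spec_or_all == "all":
        model = EnsembleRegressor(backbone_factory=lambda: backbone, **common)
    else:
        source, merge = head_spec_or_all
        model = HeadRegressor(embedding_source=source, merge=merge,
                              backbone=backbone, **common)
    model.fit(dataset)
    return model
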