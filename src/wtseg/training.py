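"""Training loop: Adam + masked categorical cross-entropy + plateau decay.

Defaults mirror the published training recipe: 200 epochs of 600
iterations, batch size 4 for the U-Net and 16 for the DenseNet, initial
learning rate 5e-4 halved after a validation-loss plateau of 5 epochs,
categorical cross-entropy over annotated pixels only.  Desk-scale runs
shrink epochs/iterations, not the recipe.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._nn import Adam
from .annotations import LabeledImage
from .networks import NetworkSpec, softmax
from .patches import AugmentationConfig, PatchSpec, augment, resample_image, sample_patch
from .taxonomy import UNANNOTATED

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "PatchSampler",
    "masked_cross_entropy",
    "plateau_scheduler",
    "lr_schedule_from_history",
    "train",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    epochs: int = 200
    iterations_per_epoch: int = 600
    batch_size: int = 4  # 4 for u-net, 16 for dense-net
    initial_lr: float = 0.0005
    decay_factor: float = 0.5
    plateau_patience: int = 5
    val_patches: int = 32  # patches drawn per validation pass
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.iterations_per_epoch, self.batch_size,
               self.val_patches) <= 0:
            raise ValueError("all sizes must be positive")
        if self.plateau_patience < 1:
            raise ValueError("plateau patience must be at least 1")
        if not (0 < self.decay_factor <= 1 and self.initial_lr > 0):
            raise ValueError("invalid learning-rate parameters")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    val_class_dice: list[list[float]] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i in range(len(self.train_loss)):
                fh.write(json.dumps({
                    "epoch": i,
                    "train_loss": self.train_loss[i],
                    "val_loss": self.val_loss[i],
                    "learning_rate": self.learning_rate[i],
                    "val_class_dice": self.val_class_dice[i],
                }) + "\n")


def masked_cross_entropy(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean −log p(true class) over annotated pixels.

    ``probabilities`` is (..., K) on the simplex; ``labels`` matches its
    leading shape and may contain the reserved unannotated value, which
    contributes nothing.  A batch with no annotated pixel is an error —
    resample instead.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    lab = np.asarray(labels)
    if p.shape[:-1] != lab.shape:
        raise ValueError(f"shape mismatch: {p.shape[:-1]} vs {lab.shape}")
    mask = lab != UNANNOTATED
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no annotated pixels in batch; resample")
    idx = lab[mask].astype(np.intp)
    true_p = p[mask, idx]
    return float(-np.log(np.maximum(true_p, 1e-12)).mean())


def _loss_and_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Fused softmax + masked cross-entropy with the logit gradient."""
    p = softmax(logits)
    mask = labels != UNANNOTATED
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no annotated pixels in batch; resample")
    idx = labels[mask].astype(np.intp)
    loss = float(-np.log(np.maximum(p[mask, idx], 1e-12)).mean())
    d = p.copy()
    d[mask, idx] -= 1.0
    d[~mask] = 0.0
    return loss, (d / n).astype(np.float32)


def plateau_scheduler(
    val_losses: list[float],
    initial_lr: float = 0.0005,
    factor: float = 0.5,
    patience: int = 5,
) -> float:
    """Learning rate implied by a validation-loss history.

    Pure function: the rate is halved (multiplied by ``factor``) every
    time the loss fails to improve strictly for ``patience`` consecutive
    epochs, with the counter reset after each decay.
    """
    lr = initial_lr
    best = np.inf
    stale = 0
    for v in val_losses:
        if v < best:
            best = v
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                lr *= factor
                stale = 0
    return lr


def lr_schedule_from_history(
    val_losses: list[float], initial_lr: float, factor: float, patience: int
) -> list[float]:
    """Per-epoch rates: entry i is the rate used *during* epoch i (so it
    reflects the plateaus seen in epochs < i)."""
    return [
        plateau_scheduler(val_losses[:i], initial_lr, factor, patience)
        for i in range(len(val_losses))
    ]


class PatchSampler:
    """Draws augmented training batches from a fixed set of cases.

    Images are resampled to the working spacing once at construction;
    per-class pixel index lists are precomputed for balanced sampling.
    """

    def __init__(
        self,
        images: list[LabeledImage],
        patch_spec: PatchSpec,
        augmentation: AugmentationConfig | None = None,
    ):
        if not images:
            raise ValueError("sampler needs at least one case")
        self.spec = patch_spec
        self.augmentation = augmentation
        self.images = [resample_image(im, patch_spec.spacing) for im in images]
        self.images = [
            im for im in self.images if (im.labels != UNANNOTATED).any()
        ]
        if not self.images:
            raise ValueError("no annotated pixels in any case")

    def sample(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        image = self.images[rng.integers(len(self.images))]
        px, lab = sample_patch(image, self.spec, rng)
        if self.augmentation is not None:
            px, lab = augment(px, lab, self.augmentation, rng)
        return px, lab

    def batch(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        pairs = [self.sample(rng) for _ in range(n)]
        x = np.stack([p for p, _ in pairs]).astype(np.float32)
        y = np.stack([l for _, l in pairs])
        return x, y


def _validate(model, sampler: PatchSampler, n_patches: int, batch: int,
              n_classes: int, rng: np.random.Generator) -> tuple[float, list[float]]:
    losses = []
    inter = np.zeros(n_classes)
    pred_tot = np.zeros(n_classes)
    true_tot = np.zeros(n_classes)
    done = 0
    while done < n_patches:
        b = min(batch, n_patches - done)
        x, y = sampler.batch(b, rng)
        probs = softmax(model.forward_logits(x))
        losses.append(masked_cross_entropy(probs, y))
        pred = probs.argmax(axis=-1)
        mask = y != UNANNOTATED
        for k in range(n_classes):
            inter[k] += np.sum((pred == k) & (y == k) & mask)
            pred_tot[k] += np.sum((pred == k) & mask)
            true_tot[k] += np.sum((y == k) & mask)
        done += b
    with np.errstate(invalid="ignore", divide="ignore"):
        dice = 2 * inter / (pred_tot + true_tot)
    return float(np.mean(losses)), [float(d) for d in dice]


def train(
    model,
    sampler: PatchSampler,
    val_sampler: PatchSampler,
    config: TrainingConfig,
    out_dir: str | Path | None = None,
) -> tuple[object, TrainingHistory]:
    """Run the training loop; returns the best-validation model state.

    Fully seeded: the batch stream derives from ``config.seed`` and the
    validation stream from (seed, epoch), so trajectories are exactly
    reproducible in single-threaded mode.  Non-finite loss aborts.
    """
    n_classes = model.spec.n_classes
    opt = Adam(model.params(), lr=config.initial_lr)
    rng = np.random.default_rng([config.seed, 11])
    history = TrainingHistory()
    best_val = np.inf
    best_params = None
    logger.info("training %s/%s: %s", model.spec.family, model.spec.preset, config)
    for epoch in range(config.epochs):
        opt.lr = plateau_scheduler(
            history.val_loss, config.initial_lr, config.decay_factor,
            config.plateau_patience,
        )
        epoch_losses = []
        for _ in range(config.iterations_per_epoch):
            x, y = sampler.batch(config.batch_size, rng)
            logits = model.forward_logits(x)
            loss, dlogits = _loss_and_grad(logits, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss}"
                )
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_losses.append(loss)
        vrng = np.random.default_rng([config.seed, 13, epoch])
        val_loss, val_dice = _validate(
            model, val_sampler, config.val_patches, config.batch_size,
            n_classes, vrng,
        )
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.learning_rate.append(opt.lr)
        history.val_class_dice.append(val_dice)
        if val_loss < best_val:
            best_val = val_loss
            best_params = [p.copy() for p, _ in model.params()]
        logger.info(
            "epoch %d: train=%.4f val=%.4f lr=%.2e", epoch,
            history.train_loss[-1], val_loss, opt.lr,
        )
    if best_params is not None:
        for (p, _), saved in zip(model.params(), best_params):
            p[...] = saved
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .networks import save_model

        save_model(model, out / "checkpoint")
        history.save(out / "history.jsonl")
    return model, history
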