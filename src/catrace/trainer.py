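"""Multi-task training: weighted cross-entropy, lambda scheduling,
augmentation, prior masking, gradient clipping, and checkpointing.

The total loss is a convex combination of three voxel-classification
losses (backbone / Calpha / amino-acid type),

    L_total = lambda_b * L_b + lambda_c * L_c + lambda_a * L_a,

with each component a class-weighted softmax cross-entropy averaged over
voxels.  The lambdas start at (0.6, 0.3, 0.1) and switch to
(0.25, 0.4, 0.35) at the configured epoch (default 25); an optional
linear ramp over the five preceding epochs is config-selectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .nn import Tensor
from .nn import tensor as T
from .constants import N_AA
from .network import FusionSegNet, save_checkpoint
from .struct_codec import LabelMasks


class ConfigError(ValueError):
    """Raised for invalid training configuration."""


LAMBDAS_EARLY = (0.6, 0.3, 0.1)
LAMBDAS_LATE = (0.25, 0.4, 0.35)


@dataclass
class LossWeights:
    """Task lambdas plus per-class weights for each task head."""

    lambda_b: float
    lambda_c: float
    lambda_a: float
    class_weights_b: np.ndarray = field(default_factory=lambda: np.ones(4))
    class_weights_c: np.ndarray = field(default_factory=lambda: np.ones(4))
    class_weights_a: np.ndarray = field(default_factory=lambda: np.ones(N_AA + 1))

    def __post_init__(self) -> None:
        if abs(self.lambda_b + self.lambda_c + self.lambda_a - 1.0) > 1e-9:
            raise ConfigError(
                f"lambdas must sum to 1, got "
                f"{self.lambda_b + self.lambda_c + self.lambda_a}")
        for w in (self.class_weights_b, self.class_weights_c, self.class_weights_a):
            if np.any(np.asarray(w) <= 0):
                raise ConfigError("all class weights must be positive")


@dataclass
class TrainConfig:
    lr: float = 1e-4
    grad_clip: float = 1.0
    epochs: int = 30
    switch_epoch: int = 25
    ramp: bool = False            # linear lambda ramp over the 5 epochs before the switch
    mask_prob: float = 0.4        # probability a sample is trained density-only
    augment: bool = True
    spatial_augment: bool = True  # 90-degree rotations, flips, translation
    noise_sd: float = 0.03        # augmentation noise sigma (density intensity units)
    blur_sd_max: float = 0.8      # max Gaussian blur sigma in voxels
    intensity_range: float = 0.1  # multiplicative intensity scale in 1 +/- range
    max_shift: int = 4            # max augmentation translation in voxels per axis
    class_weight_mode: str = "inverse"  # "inverse" frequency or "uniform"
    val_fraction: float = 0.2
    val_every: int = 1            # validate every N epochs (always on the last)
    plateau_patience: int = 3
    plateau_factor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mask_prob <= 1.0:
            raise ConfigError("mask_prob must lie in [0, 1]")
        if self.lr <= 0:
            raise ConfigError("lr must be positive")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def weighted_cross_entropy(logits, labels, class_weights) -> Tensor:
    """Class-weighted softmax cross-entropy, mean over samples.

    ``logits``: Tensor or array of shape (K, *sample_dims); ``labels``:
    integer array of shape sample_dims with values in [0, K);
    ``class_weights``: length-K positive vector.  Returns a scalar Tensor
    equal to -1/N sum_n w_{y_n} log softmax(x_n)_{y_n}.
    """
    x = logits if isinstance(logits, Tensor) else Tensor(np.asarray(logits))
    return T.weighted_ce(x, np.asarray(labels), np.asarray(class_weights))


def multitask_loss(logits: tuple, labels: tuple, weights: LossWeights):
    """Lambda-weighted combination of the three task losses.

    ``logits`` = (backbone, calpha, amino) Tensors; ``labels`` = the
    matching integer label volumes.  Returns (total, (L_b, L_c, L_a)).
    """
    lb = weighted_cross_entropy(logits[0], labels[0], weights.class_weights_b)
    lc = weighted_cross_entropy(logits[1], labels[1], weights.class_weights_c)
    la = weighted_cross_entropy(logits[2], labels[2], weights.class_weights_a)
    total = T.add(T.add(T.mul(lb, weights.lambda_b), T.mul(lc, weights.lambda_c)),
                  T.mul(la, weights.lambda_a))
    return total, (lb, lc, la)


def lambda_schedule(epoch: int, config: TrainConfig) -> tuple[float, float, float]:
    """Task lambdas for a 1-based epoch number."""
    if epoch < 1:
        raise ConfigError("epoch numbering starts at 1")
    sw = config.switch_epoch
    if epoch >= sw:
        return LAMBDAS_LATE
    if config.ramp and epoch >= sw - 5:
        t = (epoch - (sw - 5)) / 5.0
        lam = tuple((1 - t) * e + t * l for e, l in zip(LAMBDAS_EARLY, LAMBDAS_LATE))
        return lam
    return LAMBDAS_EARLY


def compute_class_weights(label_volumes, n_classes: int) -> np.ndarray:
    """Inverse-frequency class weights normalized to mean 1.

    Classes absent from the data receive the mean weight (1.0) so the
    weight vector stays finite and positive.
    """
    counts = np.zeros(n_classes, dtype=np.float64)
    for lab in label_volumes:
        counts += np.bincount(np.asarray(lab).reshape(-1), minlength=n_classes)
    w = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
    present = w > 0
    if not present.any():
        return np.ones(n_classes)
    w[present] /= w[present].mean()
    w[~present] = 1.0
    return w


# ---------------------------------------------------------------------------
# augmentation and prior masking
# ---------------------------------------------------------------------------

def _spatial_op(vol: np.ndarray, axes_perm, flips, shift):
    """Apply rot90 composition (axis permutation + flips), extra flips, and
    integer translation with zero fill to the trailing three axes."""
    nd = vol.ndim
    sp = tuple(range(nd - 3))  # leading channel axes untouched
    perm = sp + tuple(nd - 3 + a for a in axes_perm)
    out = np.transpose(vol, perm)
    for ax, f in enumerate(flips):
        if f:
            out = np.flip(out, axis=nd - 3 + ax)
    if any(shift):
        shifted = np.zeros_like(out)
        src = [slice(None)] * nd
        dst = [slice(None)] * nd
        for ax, s in enumerate(shift):
            n = out.shape[nd - 3 + ax]
            s = int(np.clip(s, -(n - 1), n - 1))
            if s >= 0:
                dst[nd - 3 + ax] = slice(s, n)
                src[nd - 3 + ax] = slice(0, n - s)
            else:
                dst[nd - 3 + ax] = slice(0, n + s)
                src[nd - 3 + ax] = slice(-s, n)
        shifted[tuple(dst)] = out[tuple(src)]
        out = shifted
    return np.ascontiguousarray(out)


def augment_pair(density: np.ndarray, prior: np.ndarray | None,
                 masks: LabelMasks, seed: int,
                 config: TrainConfig | None = None):
    """Seeded training augmentation.

    Intensity operations (Gaussian noise, blur, intensity scaling) apply
    to the density only; spatial operations (90-degree rotations, flips,
    integer translation) apply identically to density, prior, and all
    label masks (which move by pure index permutation, i.e.
    nearest-neighbor).  Cubic spatial shape required so 90-degree
    rotations preserve the shape.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(seed)
    d = np.asarray(density, dtype=np.float32).copy()
    # intensity ops: density only
    if cfg.intensity_range > 0:
        d *= 1.0 + rng.uniform(-cfg.intensity_range, cfg.intensity_range)
    if cfg.blur_sd_max > 0:
        sd = rng.uniform(0.0, cfg.blur_sd_max)
        if sd > 1e-3:
            d = ndimage.gaussian_filter(d, sigma=(0,) * (d.ndim - 3) + (sd,) * 3)
    if cfg.noise_sd > 0:
        d = d + rng.normal(0.0, cfg.noise_sd, d.shape).astype(np.float32)
    # spatial ops: identical on every aligned volume
    if cfg.spatial_augment:
        axes_perm = rng.permutation(3)
        flips = rng.integers(0, 2, 3).astype(bool)
        shift = (rng.integers(-cfg.max_shift, cfg.max_shift + 1, 3)
                 if cfg.max_shift else (0, 0, 0))
    else:
        axes_perm, flips, shift = np.arange(3), np.zeros(3, bool), (0, 0, 0)

    def sp(v):
        return _spatial_op(np.asarray(v), axes_perm, flips, shift)

    d2 = sp(d)
    p2 = None if prior is None else sp(np.asarray(prior, dtype=np.float32))
    m2 = LabelMasks(backbone=sp(masks.backbone), calpha=sp(masks.calpha),
                    amino=sp(masks.amino))
    return d2.astype(np.float32), p2, m2


def mask_prior(prior, seed: int, mask_prob: float):
    """Seeded per-sample prior dropout: returns the prior or None."""
    if not 0.0 <= mask_prob <= 1.0:
        raise ConfigError("mask_prob must lie in [0, 1]")
    if prior is None or mask_prob == 0.0:
        return prior
    if mask_prob == 1.0:
        return None
    rng = np.random.default_rng(seed)
    return None if rng.random() < mask_prob else prior


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _sample_loss(model: FusionSegNet, density, prior, masks: LabelMasks,
                 weights: LossWeights):
    d = density if density.ndim == 4 else density[None]
    bb, ca, aa = model(d, prior)
    return multitask_loss((bb, ca, aa),
                          (masks.backbone, masks.calpha, masks.amino), weights)


def train(model: FusionSegNet, dataset, config: TrainConfig,
          checkpoint_path=None, log_path=None):
    """Train on a list of (density, prior-or-None, LabelMasks) samples.

    Per step: schedule lambdas by epoch, optionally augment and mask the
    prior, compute the multitask loss, backprop, clip the global gradient
    norm, and apply one optimizer step.  Tracks an 80/20 train/validation
    split, reduce-on-plateau learning-rate decay, and the best-validation
    parameter state.  Returns ``(best_state, history)`` where ``history``
    is a list of per-epoch records; if ``checkpoint_path`` is given the
    best state is also written there.
    """
    samples = list(dataset)
    if not samples:
        raise ConfigError("dataset is empty")
    n_val = int(round(len(samples) * config.val_fraction))
    if n_val == 0 or n_val == len(samples):
        train_set, val_set = samples, samples
    else:
        train_set, val_set = samples[:-n_val], samples[-n_val:]

    if config.class_weight_mode == "inverse":
        cw_b = compute_class_weights([s[2].backbone for s in train_set], 4)
        cw_c = compute_class_weights([s[2].calpha for s in train_set], 4)
        cw_a = compute_class_weights([s[2].amino for s in train_set], N_AA + 1)
    elif config.class_weight_mode == "uniform":
        cw_b, cw_c, cw_a = np.ones(4), np.ones(4), np.ones(N_AA + 1)
    else:
        raise ConfigError(f"unknown class_weight_mode {config.class_weight_mode!r}")

    params = model.parameters()
    opt = nn.Adam(params, lr=config.lr)
    plateau = nn.ReduceOnPlateau(opt, patience=config.plateau_patience,
                                 factor=config.plateau_factor)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    best_val = np.inf
    best_state = model.state_dict()
    log_f = open(log_path, "w") if log_path else None
    try:
        for epoch in range(1, config.epochs + 1):
            lb, lc, la = lambda_schedule(epoch, config)
            weights = LossWeights(lb, lc, la, cw_b, cw_c, cw_a)
            model.train()
            ep_losses = []
            for density, prior, masks in train_set:
                aug_seed = int(rng.integers(0, 2 ** 31))
                mask_seed = int(rng.integers(0, 2 ** 31))
                d, p, m = (augment_pair(density, prior, masks, aug_seed, config)
                           if config.augment else (density, prior, masks))
                p = mask_prior(p, mask_seed, config.mask_prob)
                total, _ = _sample_loss(model, d, p, m, weights)
                step_loss = float(total.data)
                if not np.isfinite(step_loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} "
                        f"(lambdas {lb, lc, la}, lr {opt.lr:g})")
                model.zero_grad()
                total.backward()
                nn.clip_grad_norm(params, config.grad_clip)
                opt.step()
                ep_losses.append(step_loss)
            train_loss = float(np.mean(ep_losses))
            if epoch % config.val_every == 0 or epoch == config.epochs:
                model.eval()
                val_losses = []
                for density, prior, masks in val_set:
                    total, _ = _sample_loss(model, np.asarray(density, np.float32),
                                            prior, masks, weights)
                    val_losses.append(float(total.data))
                val_loss = float(np.mean(val_losses))
            else:
                val_loss = train_loss
            plateau.step(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_state = model.state_dict()
            rec = {"epoch": epoch, "train_loss": train_loss,
                   "val_loss": val_loss, "lr": opt.lr,
                   "lambdas": [lb, lc, la]}
            history.append(rec)
            if log_f:
                log_f.write(json.dumps(rec) + "\n")
    finally:
        if log_f:
            log_f.close()
    model.load_state_dict(best_state)
    if checkpoint_path is not None:
        save_checkpoint(model, Path(checkpoint_path),
                        extra={"best_val_loss": best_val,
                               "epochs": config.epochs, "seed": config.seed})
    return best_state, history


def backbone_voxel_accuracy(model: FusionSegNet, density, prior,
                            masks: LabelMasks) -> float:
    """Fraction of voxels whose argmax backbone class equals the label."""
    model.eval()
    d = np.asarray(density, dtype=np.float32)
    bb, _, _ = model(d if d.ndim == 4 else d[None], prior)
    pred = np.argmax(bb.data, axis=0)
    return float(np.mean(pred == masks.backbone))
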