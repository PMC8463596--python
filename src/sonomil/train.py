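"""Training engine: preprocessing, augmentation, optimization, model selection.

A training example is one breast (its whole image set); one optimizer step
is taken per breast. Images are augmented geometrically (flip / rotation /
translation / scale / shear), resized with bilinear interpolation, and
standardized by the training split's global pixel mean and standard
deviation (stored in the checkpoint so inference applies the identical
transform). Model selection keeps the epoch with the highest validation
AUROC of the malignant head; ensembling averages breast-level predictions
of the top-k models from a random hyperparameter search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .mil import BreastPrediction, MILModel, ModelConfig
from .nn import AdamW
from .stats import auroc


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters for a single training run."""

    lr: float = 6e-3
    beta: float = 1e-2  # saliency L1 weight
    weight_decay: float = 1e-5
    pool_frac: float = 0.25  # top-t pooling fraction
    epochs: int = 15
    grad_accum: int = 4  # breasts per optimizer step
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 or self.weight_decay < 0:
            raise ValueError("lr must be > 0 and weight_decay >= 0")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 < self.pool_frac <= 1.0:
            raise ValueError(f"pool_frac must be in (0, 1], got {self.pool_frac}")
        if self.epochs < 0:
            raise ValueError(f"epochs must be >= 0, got {self.epochs}")
        if self.grad_accum < 1:
            raise ValueError(f"grad_accum must be >= 1, got {self.grad_accum}")


@dataclass(frozen=True)
class AugmentConfig:
    """Geometric training augmentation ranges (angles in degrees)."""

    hflip_prob: float = 0.5
    vflip_prob: float = 0.0
    rotation_deg: float = 45.0
    translate_frac: float = 0.10
    scale_range: tuple[float, float] = (0.7, 1.5)
    shear_deg: float = 25.0

    def validate(self) -> None:
        if not 0 <= self.hflip_prob <= 1 or not 0 <= self.vflip_prob <= 1:
            raise ValueError("flip probabilities must be in [0, 1]")
        if self.scale_range[0] <= 0 or self.scale_range[1] < self.scale_range[0]:
            raise ValueError(f"bad scale_range {self.scale_range}")


@dataclass(frozen=True)
class SearchSpace:
    """Random-search ranges: log10-uniform rates, uniform pooling fraction."""

    lr_log10: tuple[float, float] = (-5.5, -4.0)
    beta_log10: tuple[float, float] = (-3.0, 0.5)
    weight_decay_log10: tuple[float, float] = (-6.0, -3.5)
    pool_frac_range: tuple[float, float] = (0.1, 0.5)
    n_trials: int = 30


IDENTITY_AUG = AugmentConfig(
    hflip_prob=0.0, vflip_prob=0.0, rotation_deg=0.0, translate_frac=0.0,
    scale_range=(1.0, 1.0), shear_deg=0.0,
)

# Desk-scale augmentation: the class defaults above are the full-scale policy
# (appropriate for 256-px inputs and long schedules); short runs on 64-px
# phantoms use this milder, resolution-matched profile by default.
TINY_AUGMENT = AugmentConfig(
    hflip_prob=0.5, vflip_prob=0.0, rotation_deg=10.0, translate_frac=0.05,
    scale_range=(0.95, 1.05), shear_deg=0.0,
)


# ---------------------------------------------------------------------------
# preprocessing


def _to_float01(raw: np.ndarray) -> np.ndarray:
    img = np.asarray(raw)
    if img.dtype == np.uint8:
        img = img.astype(np.float64) / 255.0
    else:
        img = img.astype(np.float64)
    return img


def _resize_bilinear(img2d: np.ndarray, size: int) -> np.ndarray:
    if img2d.shape == (size, size):
        return img2d.copy()
    pim = Image.fromarray(img2d.astype(np.float32), mode="F")
    out = pim.resize((size, size), resample=Image.BILINEAR)
    return np.asarray(out, dtype=np.float64)


def preprocess(
    raw_image: np.ndarray,
    size: int,
    mean: float = 0.0,
    std: float = 1.0,
    per_image_minmax: bool = False,
) -> np.ndarray:
    """Resize to (size, size, 3) and normalize.

    Grayscale inputs are replicated across 3 channels. Default normalization
    subtracts ``mean`` and divides by ``std`` (the training split's global
    statistics); ``per_image_minmax`` rescales each image to [0, 1] instead.
    """
    img = _to_float01(raw_image)
    if img.ndim not in (2, 3):
        raise ValueError(f"expected a 2-D or 3-D image, got shape {img.shape}")
    if img.ndim == 2 and (img.shape[0] < 8 or img.shape[1] < 8):
        raise ValueError(f"image too small: {img.shape}")
    if img.ndim == 2:
        resized = _resize_bilinear(img, size)
        out = np.repeat(resized[:, :, None], 3, axis=2)
    else:
        out = np.stack(
            [_resize_bilinear(img[:, :, c], size) for c in range(img.shape[2])], axis=2
        )
        if out.shape[2] == 1:
            out = np.repeat(out, 3, axis=2)
    if per_image_minmax:
        lo, hi = out.min(), out.max()
        out = (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)
    else:
        out = (out - mean) / std
    return out


def norm_stats(image_sets: Sequence[Sequence[np.ndarray]]) -> tuple[float, float]:
    """Global pixel mean/std over a training split (images scaled to [0, 1])."""
    total = 0.0
    total_sq = 0.0
    n = 0
    for images in image_sets:
        for img in images:
            x = _to_float01(img)
            total += x.sum()
            total_sq += (x**2).sum()
            n += x.size
    mean = total / n
    var = max(total_sq / n - mean**2, 1e-12)
    return float(mean), float(math.sqrt(var))


# ---------------------------------------------------------------------------
# augmentation


def draw_augment_params(config: AugmentConfig, rng: np.random.Generator) -> dict:
    """Sample one augmentation; every parameter stays inside its range."""
    config.validate()
    return dict(
        hflip=bool(rng.random() < config.hflip_prob),
        vflip=bool(rng.random() < config.vflip_prob),
        angle_deg=float(rng.uniform(-config.rotation_deg, config.rotation_deg)),
        translate=(
            float(rng.uniform(-config.translate_frac, config.translate_frac)),
            float(rng.uniform(-config.translate_frac, config.translate_frac)),
        ),
        scale=float(rng.uniform(*config.scale_range)),
        shear_deg=float(rng.uniform(-config.shear_deg, config.shear_deg)),
    )


def _is_identity(p: dict) -> bool:
    return (
        not p["hflip"]
        and not p["vflip"]
        and p["angle_deg"] == 0.0
        and p["translate"] == (0.0, 0.0)
        and p["scale"] == 1.0
        and p["shear_deg"] == 0.0
    )


def apply_augment(image: np.ndarray, params: dict) -> np.ndarray:
    """Apply a sampled affine augmentation to a 2-D image (bilinear, zero fill)."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"apply_augment expects a 2-D image, got {img.shape}")
    if _is_identity(params):
        return img.copy()
    h, w = img.shape
    theta = math.radians(params["angle_deg"])
    sh = math.tan(math.radians(params["shear_deg"]))
    s = params["scale"]
    # forward map in (row, col): flip, then scale+shear, then rotation,
    # all about the image center; translation in pixels afterwards
    flip = np.diag([
        -1.0 if params["vflip"] else 1.0,
        -1.0 if params["hflip"] else 1.0,
    ])
    shear = np.array([[1.0, sh], [0.0, 1.0]])
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    fwd = rot @ shear @ (s * flip)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    trans = np.array([params["translate"][0] * h, params["translate"][1] * w])
    inv = np.linalg.inv(fwd)
    offset = center - inv @ (center + trans)
    return ndimage.affine_transform(
        img, inv, offset=offset, order=1, mode="constant", cval=0.0
    )


def augment(image: np.ndarray, config: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw parameters and apply them; deterministic under a fixed rng."""
    return apply_augment(image, draw_augment_params(config, rng))


# ---------------------------------------------------------------------------
# hyperparameter search


def sample_hyperparams(
    space: SearchSpace, rng: np.random.Generator, epochs: int = 12, seed: int = 0
) -> TrainConfig:
    """One random-search draw: log-uniform rates, uniform pooling fraction."""
    return TrainConfig(
        lr=float(10.0 ** rng.uniform(*space.lr_log10)),
        beta=float(10.0 ** rng.uniform(*space.beta_log10)),
        weight_decay=float(10.0 ** rng.uniform(*space.weight_decay_log10)),
        pool_frac=float(rng.uniform(*space.pool_frac_range)),
        epochs=epochs,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# training


def _label_pair(exam) -> tuple[int, int]:
    return int(exam.label_benign), int(exam.label_malignant)


def _val_auroc(model: MILModel, val_pre: list[tuple[list[np.ndarray], int]]) -> float:
    scores = [model.forward(images).y_malignant for images, _ in val_pre]
    labels = [y for _, y in val_pre]
    return auroc(np.array(scores), np.array(labels))


def train_model(
    train_set: Sequence,
    val_set: Sequence,
    config: TrainConfig,
    model_config: ModelConfig | None = None,
    augment_config: AugmentConfig | None = None,
) -> tuple[MILModel, pd.DataFrame]:
    """Optimize the MIL loss with Adam; keep the best-validation checkpoint.

    ``train_set`` / ``val_set`` are sequences of objects exposing ``images``
    (raw grayscale arrays) and the breast-level labels — e.g.
    :class:`~sonomil.phantom.TrainingView`. Returns the selected model and a
    per-epoch history frame (epoch, train_loss, val_auroc).
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train_set and val_set must be nonempty")
    val_labels = {_label_pair(e)[1] for e in val_set}
    if val_labels != {0, 1}:
        raise ValueError("val_set must contain both malignant and non-malignant breasts")
    model_config = model_config or ModelConfig.tiny()
    model_config = replace(model_config, pool_frac=config.pool_frac)
    augment_config = augment_config if augment_config is not None else TINY_AUGMENT

    rng = np.random.default_rng(config.seed)
    model = MILModel(model_config, rng=rng)
    mean, std = norm_stats([e.images for e in train_set])
    model.norm_mean, model.norm_std = mean, std
    size = model_config.input_size

    val_pre = [
        (
            [preprocess(img, size, mean, std) for img in e.images],
            _label_pair(e)[1],
        )
        for e in val_set
    ]

    history_rows: list[dict] = []
    if config.epochs == 0:
        return model, pd.DataFrame(history_rows, columns=["epoch", "train_loss", "val_auroc"])

    opt = AdamW(model.params, lr=config.lr, weight_decay=config.weight_decay)
    best_auroc = -np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_set))
        losses = []
        acc: dict[str, np.ndarray] | None = None
        n_acc = 0
        for i in order:
            exam = train_set[i]
            y_b, y_m = _label_pair(exam)
            images = [
                preprocess(augment(img, augment_config, rng), size, mean, std)
                for img in exam.images
            ]
            loss, grads, _ = model.loss_and_grads(images, y_b, y_m, config.beta)
            if acc is None:
                acc = grads
            else:
                for k in acc:
                    acc[k] += grads[k]
            n_acc += 1
            if n_acc == config.grad_accum:
                for k in acc:
                    acc[k] /= n_acc
                opt.step(acc)
                acc, n_acc = None, 0
            losses.append(loss)
        if acc is not None:
            for k in acc:
                acc[k] /= n_acc
            opt.step(acc)
        va = _val_auroc(model, val_pre)
        history_rows.append(
            dict(epoch=epoch, train_loss=float(np.mean(losses)), val_auroc=va)
        )
        if va > best_auroc:
            best_auroc = va
            best_params = {k: v.copy() for k, v in model.params.items()}
    model.params = best_params
    history = pd.DataFrame(history_rows, columns=["epoch", "train_loss", "val_auroc"])
    return model, history


@dataclass
class Ensemble:
    """Mean of member breast-level predictions (and their attachments)."""

    members: list[MILModel]

    def forward(self, images: list[np.ndarray]) -> BreastPrediction:
        preds = [m.forward(images) for m in self.members]
        return BreastPrediction(
            y_benign=float(np.mean([p.y_benign for p in preds])),
            y_malignant=float(np.mean([p.y_malignant for p in preds])),
            image_preds=np.mean([p.image_preds for p in preds], axis=0),
            attention=np.mean([p.attention for p in preds], axis=0),
            saliency=[
                np.mean([p.saliency[k] for p in preds], axis=0)
                for k in range(preds[0].k)
            ],
        )

    @property
    def norm_mean(self) -> float:
        return self.members[0].norm_mean

    @property
    def norm_std(self) -> float:
        return self.members[0].norm_std

    @property
    def config(self) -> ModelConfig:
        return self.members[0].config


def select_ensemble(trained: Sequence[tuple[MILModel, float]], k: int = 3) -> Ensemble:
    """Keep the k models with the highest validation AUROC."""
    if len(trained) < k:
        raise ValueError(f"need at least {k} trained models, got {len(trained)}")
    ranked = sorted(trained, key=lambda mv: mv[1], reverse=True)
    return Ensemble(members=[m for m, _ in ranked[:k]])


def random_search(
    train_set: Sequence,
    val_set: Sequence,
    space: SearchSpace,
    n_trials: int,
    epochs: int,
    rng: np.random.Generator,
    model_config: ModelConfig | None = None,
) -> list[tuple[MILModel, float, TrainConfig]]:
    """Train ``n_trials`` models with randomly sampled hyperparameters."""
    results = []
    for trial in range(n_trials):
        cfg = sample_hyperparams(
            space, rng, epochs=epochs, seed=int(rng.integers(0, 2**31 - 1))
        )
        model, history = train_model(train_set, val_set, cfg, model_config)
        va = float(history["val_auroc"].max()) if len(history) else float("nan")
        results.append((model, va, cfg))
    return results
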