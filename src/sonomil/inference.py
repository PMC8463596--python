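"""Breast-level inference: plain prediction, test-time augmentation, saliency export.

All entry points accept *raw* grayscale image sets (as generated or as read
from an exam bundle); preprocessing (resize + the normalization stored in
the checkpoint) happens inside, so a saved model carries everything needed
to reproduce its predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .mil import BreastPrediction, MILModel
from .train import Ensemble, preprocess, _to_float01

Predictor = MILModel | Ensemble


@dataclass(frozen=True)
class TTAConfig:
    """Test-time augmentation: flips plus mild photometric jitter."""

    n_reps: int = 20
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    factor_range: tuple[float, float] = (0.9, 1.1)

    def validate(self) -> None:
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if self.factor_range[0] <= 0 or self.factor_range[1] < self.factor_range[0]:
            raise ValueError(f"bad factor_range {self.factor_range}")


def _prep_set(predictor: Predictor, images: list[np.ndarray]) -> list[np.ndarray]:
    size = predictor.config.input_size
    return [
        preprocess(img, size, predictor.norm_mean, predictor.norm_std) for img in images
    ]


def predict_breast(predictor: Predictor, images: list[np.ndarray]) -> BreastPrediction:
    """Deterministic breast-level prediction from a model or ensemble."""
    if len(images) == 0:
        raise ValueError("image set is empty")
    return predictor.forward(_prep_set(predictor, images))


def _tta_augment_one(
    img: np.ndarray, config: TTAConfig, rng: np.random.Generator
) -> np.ndarray:
    out = _to_float01(img)
    if rng.random() < config.hflip_prob:
        out = out[:, ::-1]
    if rng.random() < config.vflip_prob:
        out = out[::-1, :]
    contrast = rng.uniform(*config.factor_range)
    brightness = rng.uniform(*config.factor_range)
    m = out.mean()
    out = m + contrast * (out - m)
    return brightness * out


def tta_predict(
    predictor: Predictor,
    images: list[np.ndarray],
    config: TTAConfig,
    rng: np.random.Generator,
) -> BreastPrediction:
    """Average the breast-level prediction over augmented replicas of the set."""
    config.validate()
    if len(images) == 0:
        raise ValueError("image set is empty")
    size = predictor.config.input_size
    preds = []
    for _ in range(config.n_reps):
        aug = [
            preprocess(
                _tta_augment_one(img, config, rng),
                size,
                predictor.norm_mean,
                predictor.norm_std,
            )
            for img in images
        ]
        preds.append(predictor.forward(aug))
    return BreastPrediction(
        y_benign=float(np.mean([p.y_benign for p in preds])),
        y_malignant=float(np.mean([p.y_malignant for p in preds])),
        image_preds=np.mean([p.image_preds for p in preds], axis=0),
        attention=np.mean([p.attention for p in preds], axis=0),
        saliency=[
            np.mean([p.saliency[k] for p in preds], axis=0) for k in range(preds[0].k)
        ],
    )


def upsample_map(
    saliency_map: np.ndarray, size: int, method: str = "bilinear"
) -> np.ndarray:
    """Upsample an (h, w) saliency map to (size, size).

    Cell (i, j) of the map is placed at input pixel (s*i, s*j) where s is
    the feature stride (size / h): with stride-2 convolutions and symmetric
    padding that pixel is the center of the cell's receptive field, so the
    upsampled heatmap is spatially registered to the image rather than
    shifted by half a cell.
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"method must be 'bilinear' or 'nearest', got {method!r}")
    sal = np.asarray(saliency_map, dtype=float)
    h, w = sal.shape
    sy, sx = size / h, size / w
    ii = np.arange(size)[:, None] / sy * np.ones((1, size))
    jj = np.ones((size, 1)) * (np.arange(size)[None, :] / sx)
    order = 1 if method == "bilinear" else 0
    return ndimage.map_coordinates(sal, [ii, jj], order=order, mode="nearest")


def export_saliency(
    predictor: Predictor,
    images: list[np.ndarray],
    out_dir: str | Path,
    method: str = "bilinear",
) -> list[Path]:
    """Write per-image benign/malignant heatmaps and an attention sidecar.

    Produces ``img{k}_benign.png`` and ``img{k}_malignant.png`` (8-bit, the
    [0, 1] saliency scaled to [0, 255]) for every image plus one
    ``attention.json`` with attention weights and breast-level probabilities.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pred = predict_breast(predictor, images)
    size = predictor.config.input_size
    paths: list[Path] = []
    for k, sal in enumerate(pred.saliency):
        for c, name in enumerate(("benign", "malignant")):
            up = upsample_map(sal[:, :, c], size, method)
            img8 = np.clip(np.round(up * 255.0), 0, 255).astype(np.uint8)
            path = out_dir / f"img{k:03d}_{name}.png"
            Image.fromarray(img8, mode="L").save(path)
            paths.append(path)
    sidecar = out_dir / "attention.json"
    sidecar.write_text(
        json.dumps(
            dict(
                y_benign=pred.y_benign,
                y_malignant=pred.y_malignant,
                attention_benign=pred.attention[:, 0].tolist(),
                attention_malignant=pred.attention[:, 1].tolist(),
                image_preds_benign=pred.image_preds[:, 0].tolist(),
                image_preds_malignant=pred.image_preds[:, 1].tolist(),
                upsample=method,
            ),
            indent=2,
        )
    )
    paths.append(sidecar)
    return paths


def pointing_game(
    predictor: Predictor,
    exams,
    upsample_method: str = "bilinear",
) -> tuple[float, int]:
    """Weakly supervised localization check on phantoms with truth masks.

    For every malignant-labeled image in every exam, upsample the malignant
    saliency map to input resolution and test whether its argmax pixel lies
    inside the planted lesion mask. Returns (hit fraction, n images).
    """
    hits = 0
    total = 0
    for exam in exams:
        if not exam.label_malignant:
            continue
        pred = predict_breast(predictor, exam.images)
        for k, mask in enumerate(exam.truth_masks):
            if not mask.any():
                continue
            size = mask.shape[0]
            up = upsample_map(pred.saliency[k][:, :, 1], size, upsample_method)
            i, j = np.unravel_index(int(up.argmax()), up.shape)
            hits += int(mask[i, j])
            total += 1
    return (hits / total if total else float("nan")), total
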