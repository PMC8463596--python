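"""Synthetic breast-ultrasound phantom generator.

Emulates the structure of a B-mode breast exam at desk scale: each *breast*
contributes a variable-length set of speckle-textured grayscale images, and a
positive breast contains a hypoechoic (darker-than-background) lesion that is
visible in only a subset of the images — benign lesions are smooth-margin
ovals, malignant lesions are irregular spiculated shapes. Only breast-level
labels are exposed to training code; pixel-level truth masks are carried
separately for evaluation (pointing-game localization) and never appear in
the training view of an exam.

The generator makes no attempt at acoustic realism (no posterior shadowing,
no Doppler); its job is to reproduce the *learning problem*: weak labels,
instance-level ambiguity, and morphology-driven class differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

ClassLabel = Literal["negative", "benign", "malignant"]
CLASSES: tuple[ClassLabel, ...] = ("negative", "benign", "malignant")


@dataclass(frozen=True)
class BenignMorphology:
    """Smooth oval: axis ratio below 1 and a gently blurred margin."""

    axis_ratio: tuple[float, float] = (0.55, 0.85)
    margin_blur: float = 1.0  # pixels of Gaussian blur on the mask edge


@dataclass(frozen=True)
class MalignantMorphology:
    """Irregular, spiculated contour with an indistinct margin."""

    spiculations: tuple[int, int] = (6, 12)
    irregularity: tuple[float, float] = (0.25, 0.5)  # radial modulation depth
    margin_blur: float = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic cohort.

    ``lesion_frac_visible`` is the fraction of a positive breast's images in
    which the lesion is rendered (at least 2 images always show it, mimicking
    orthogonal sonographic views); the remaining images are lesion-free
    speckle, which is what makes per-image relevance — attention — matter.
    """

    image_size: int = 64
    k_range: tuple[int, int] = (4, 12)
    lesion_frac_visible: float = 0.4
    speckle_scale: float = 0.35
    lesion_contrast: float = 0.45  # interior intensity multiplier (< 1: hypoechoic)
    lesion_radius_frac: tuple[float, float] = (0.14, 0.22)  # of image size
    benign_morphology: BenignMorphology = field(default_factory=BenignMorphology)
    malignant_morphology: MalignantMorphology = field(default_factory=MalignantMorphology)
    class_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # negative, benign, malignant
    dual_label_prob: float = 0.05  # malignant breast also carries a benign lesion
    seed: int | None = None

    def validate(self) -> None:
        if self.image_size < 16:
            raise ValueError(f"image_size must be >= 16, got {self.image_size}")
        lo, hi = self.k_range
        if lo < 1 or hi < lo:
            raise ValueError(f"k_range must satisfy 1 <= lo <= hi, got {self.k_range}")
        if not 0.0 < self.lesion_frac_visible <= 1.0:
            raise ValueError(
                f"lesion_frac_visible must be in (0, 1], got {self.lesion_frac_visible}"
            )
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {self.class_mix}")
        if any(p < 0 for p in self.class_mix):
            raise ValueError(f"class_mix entries must be >= 0, got {self.class_mix}")
        if not 0.0 < self.lesion_contrast < 1.0:
            raise ValueError(
                f"lesion_contrast must be in (0, 1) to keep lesions hypoechoic, "
                f"got {self.lesion_contrast}"
            )


@dataclass
class TrainingView:
    """What the learner is allowed to see: images and breast-level labels only."""

    images: list[np.ndarray]
    label_benign: int
    label_malignant: int
    breast_id: str


@dataclass
class PhantomExam:
    """One synthetic breast: image set, weak labels and held-back truth.

    ``truth_masks`` exist for evaluation only; training code must consume
    :meth:`training_view`, which does not carry them.
    """

    images: list[np.ndarray]  # (H, W) float32 in [0, 1]
    label_benign: int
    label_malignant: int
    truth_masks: list[np.ndarray]  # (H, W) bool, malignant-lesion pixels
    benign_masks: list[np.ndarray]  # (H, W) bool, benign-lesion pixels
    exam_id: str
    breast_id: str
    laterality: str = "L"
    class_label: str = "negative"

    @property
    def k(self) -> int:
        return len(self.images)

    def training_view(self) -> TrainingView:
        return TrainingView(
            images=self.images,
            label_benign=self.label_benign,
            label_malignant=self.label_malignant,
            breast_id=self.breast_id,
        )


# ---------------------------------------------------------------------------
# texture and lesion rendering


def _tissue_background(size: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency tissue field around mid-gray."""
    coarse = rng.normal(0.0, 1.0, size=(8, 8))
    field_ = gaussian_filter(coarse, sigma=1.2, mode="reflect")
    # bilinear-ish upsample by nearest zoom through np.kron then blur
    rep = size // 8 + 1
    up = np.kron(field_, np.ones((rep, rep)))[:size, :size]
    up = gaussian_filter(up, sigma=size / 16.0, mode="reflect")
    up = up / (np.abs(up).max() + 1e-9)
    return 0.55 + 0.08 * up


def _speckle(size: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Rayleigh-magnitude speckle, unit mean, light spatial blur."""
    r = rng.rayleigh(scale=1.0, size=(size, size))
    r = gaussian_filter(r, sigma=0.6, mode="reflect")
    r = r / r.mean()
    return 1.0 + scale * (r - 1.0)


def _radial_mask(
    size: int,
    center: tuple[float, float],
    radius: float,
    radius_fn,
) -> np.ndarray:
    """Binary mask of the region r(theta) <= radius_fn(theta)."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - center[0]
    dx = xx - center[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    return r <= radius_fn(theta)


def _benign_lesion_shape(
    size: int, radius: float, morph: BenignMorphology, rng: np.random.Generator
) -> tuple[np.ndarray, tuple[float, float]]:
    ratio = rng.uniform(*morph.axis_ratio)
    phi = rng.uniform(0.0, math.pi)
    margin = max(radius, size * 0.08)
    cy = rng.uniform(margin + 2, size - margin - 2)
    cx = rng.uniform(margin + 2, size - margin - 2)

    def radius_fn(theta: np.ndarray) -> np.ndarray:
        # ellipse radius in polar form, semi-axes (radius, radius*ratio)
        a, b = radius, radius * ratio
        c, s = np.cos(theta - phi), np.sin(theta - phi)
        return (a * b) / np.sqrt((b * c) ** 2 + (a * s) ** 2)

    return _radial_mask(size, (cy, cx), radius, radius_fn), (cy, cx)


def _malignant_lesion_shape(
    size: int, radius: float, morph: MalignantMorphology, rng: np.random.Generator
) -> tuple[np.ndarray, tuple[float, float]]:
    n_spic = int(rng.integers(morph.spiculations[0], morph.spiculations[1] + 1))
    amp = rng.uniform(*morph.irregularity)
    phases = rng.uniform(0.0, 2 * math.pi, size=3)
    margin = max(radius * (1 + amp), size * 0.08)
    cy = rng.uniform(margin + 2, size - margin - 2)
    cx = rng.uniform(margin + 2, size - margin - 2)

    def radius_fn(theta: np.ndarray) -> np.ndarray:
        mod = (
            amp * np.sin(n_spic * theta + phases[0])
            + 0.5 * amp * np.sin((n_spic // 2 + 1) * theta + phases[1])
            + 0.25 * amp * np.sin(3 * theta + phases[2])
        )
        return radius * np.clip(1.0 + mod, 0.3, 2.0)

    return _radial_mask(size, (cy, cx), radius, radius_fn), (cy, cx)


def _render_lesion(
    image: np.ndarray,
    mask: np.ndarray,
    contrast: float,
    margin_blur: float,
) -> np.ndarray:
    """Darken the lesion interior with a soft margin (hypoechoic interior)."""
    soft = gaussian_filter(mask.astype(np.float64), sigma=margin_blur, mode="constant")
    soft = np.clip(soft, 0.0, 1.0)
    factor = 1.0 - (1.0 - contrast) * soft
    return image * factor


# ---------------------------------------------------------------------------
# public generation API


def gen_exam(
    spec: PhantomSpec,
    class_label: ClassLabel,
    rng: np.random.Generator,
    exam_id: str = "exam-000",
    breast_id: str | None = None,
) -> PhantomExam:
    """Generate one synthetic breast exam of the requested class.

    Positive classes plant the lesion in ``max(2, round(frac * K))`` of the K
    images (two orthogonal views at minimum); lesion geometry is re-jittered
    per image, emulating different probe placements on the same finding.
    """
    spec.validate()
    if class_label not in CLASSES:
        raise ValueError(f"class_label must be one of {CLASSES}, got {class_label!r}")
    size = spec.image_size
    k = int(rng.integers(spec.k_range[0], spec.k_range[1] + 1))

    has_malignant = class_label == "malignant"
    has_benign = class_label == "benign"
    if has_malignant and rng.random() < spec.dual_label_prob:
        has_benign = True

    def visible_indices(k: int) -> np.ndarray:
        n_vis = max(2, int(round(spec.lesion_frac_visible * k)))
        n_vis = min(n_vis, k)
        return rng.choice(k, size=n_vis, replace=False)

    mal_idx = set(visible_indices(k).tolist()) if has_malignant else set()
    ben_idx = set(visible_indices(k).tolist()) if has_benign else set()

    base_radius = rng.uniform(*spec.lesion_radius_frac) * size

    images: list[np.ndarray] = []
    truth_masks: list[np.ndarray] = []
    benign_masks: list[np.ndarray] = []
    for i in range(k):
        img = _tissue_background(size, rng)
        mal_mask = np.zeros((size, size), dtype=bool)
        ben_mask = np.zeros((size, size), dtype=bool)
        if i in mal_idx:
            radius = base_radius * rng.uniform(0.85, 1.15)
            mal_mask, _ = _malignant_lesion_shape(
                size, radius, spec.malignant_morphology, rng
            )
            img = _render_lesion(
                img, mal_mask, spec.lesion_contrast, spec.malignant_morphology.margin_blur
            )
        if i in ben_idx:
            radius = base_radius * rng.uniform(0.85, 1.15)
            ben_mask, _ = _benign_lesion_shape(size, radius, spec.benign_morphology, rng)
            img = _render_lesion(
                img, ben_mask, spec.lesion_contrast, spec.benign_morphology.margin_blur
            )
        img = img * _speckle(size, spec.speckle_scale, rng)
        images.append(np.clip(img, 0.0, 1.0).astype(np.float32))
        truth_masks.append(mal_mask)
        benign_masks.append(ben_mask)

    breast_id = breast_id or f"{exam_id}-L"
    return PhantomExam(
        images=images,
        label_benign=int(has_benign),
        label_malignant=int(has_malignant),
        truth_masks=truth_masks,
        benign_masks=benign_masks,
        exam_id=exam_id,
        breast_id=breast_id,
        laterality="L",
        class_label=class_label,
    )


def _bounding_boxes(masks: Sequence[np.ndarray]) -> list[list[int] | None]:
    boxes: list[list[int] | None] = []
    for m in masks:
        if not m.any():
            boxes.append(None)
            continue
        ys, xs = np.nonzero(m)
        boxes.append([int(ys.min()), int(xs.min()), int(ys.max()), int(xs.max())])
    return boxes


def gen_cohort(
    spec: PhantomSpec,
    n_exams: int,
    rng: np.random.Generator,
) -> tuple[list[PhantomExam], "pd.DataFrame"]:
    """Generate a cohort; class counts follow ``class_mix`` multinomially.

    Returns the exams together with a truth table (one row per breast) holding
    labels and per-image malignant-lesion bounding boxes as a JSON column.
    """
    import json

    import pandas as pd

    if n_exams < 1:
        raise ValueError(f"n_exams must be >= 1, got {n_exams}")
    spec.validate()
    labels = rng.choice(len(CLASSES), size=n_exams, p=np.asarray(spec.class_mix))
    exams = []
    rows = []
    for i, lab in enumerate(labels):
        exam = gen_exam(spec, CLASSES[lab], rng, exam_id=f"exam-{i:04d}")
        exams.append(exam)
        rows.append(
            {
                "exam_id": exam.exam_id,
                "breast_id": exam.breast_id,
                "class_label": exam.class_label,
                "label_benign": exam.label_benign,
                "label_malignant": exam.label_malignant,
                "k_images": exam.k,
                "malignant_boxes": json.dumps(_bounding_boxes(exam.truth_masks)),
            }
        )
    return exams, pd.DataFrame(rows)


def boundary_irregularity(mask: np.ndarray) -> float:
    """Isoperimetric roughness perimeter^2 / (4*pi*area); 1 for a disk."""
    from scipy.ndimage import binary_erosion

    area = float(mask.sum())
    if area == 0:
        return float("nan")
    boundary = mask & ~binary_erosion(mask)
    perimeter = float(boundary.sum())
    return perimeter**2 / (4.0 * math.pi * area)


def split_cohort(
    exams: Sequence[PhantomExam],
    fractions: tuple[float, float, float],
    rng: np.random.Generator,
) -> tuple[list[PhantomExam], list[PhantomExam], list[PhantomExam]]:
    """Shuffle and split into train/validation/test by breast."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    order = rng.permutation(len(exams))
    n_train = int(round(fractions[0] * len(exams)))
    n_val = int(round(fractions[1] * len(exams)))
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]
    pick = lambda idx: [exams[i] for i in idx]  # noqa: E731
    return pick(idx_train), pick(idx_val), pick(idx_test)
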