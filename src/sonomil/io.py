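"""Exam-bundle and table I/O plus the end-to-end reproducible pipeline.

An exam bundle is one directory per breast::

    <breast_id>/
        manifest.json    exam_id, breast_id, laterality, k, labels, images
        images/NNN.png   8-bit grayscale images, in manifest order
        truth/NNN.png    lesion masks (evaluation only; not listed in the
                         manifest and never read by the training loader)

``run_pipeline`` chains simulate -> train -> predict -> evaluate with named
seeds and writes a run-summary JSON whose contents are bit-reproducible for
identical seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import phantom, stats
from .inference import predict_breast
from .mil import MILModel, ModelConfig
from .train import TrainConfig, train_model


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    ``profile`` chooses the architecture scale: ``tiny`` is the desk-scale
    configuration (64x64 input, 4x4x32 features, L=16), ``paper`` the
    full-scale one (256x256 input, 8x8x512 features, L=128, 50 epochs,
    30 search trials, ensemble of 3) documented for completeness.
    """

    out_dir: str = "runs/out"
    profile: str = "tiny"
    n_exams: int = 48
    epochs: int = 4
    data_seed: int = 1
    train_seed: int = 2
    eval_seed: int = 3
    class_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)

    def model_config(self) -> ModelConfig:
        if self.profile == "tiny":
            return ModelConfig.tiny()
        if self.profile == "paper":
            return ModelConfig.deep()
        raise ValueError(f"profile must be 'tiny' or 'paper', got {self.profile!r}")


# ---------------------------------------------------------------------------
# bundles


def write_exam_bundle(exam: phantom.PhantomExam, root: str | Path) -> Path:
    """Write one breast's bundle; returns the bundle directory."""
    bundle = Path(root) / exam.breast_id
    img_dir = bundle / "images"
    truth_dir = bundle / "truth"
    img_dir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, img in enumerate(exam.images):
        name = f"{i:03d}.png"
        arr = np.clip(np.round(np.asarray(img, dtype=float) * 255.0), 0, 255)
        Image.fromarray(arr.astype(np.uint8), mode="L").save(img_dir / name)
        Image.fromarray(
            (exam.truth_masks[i].astype(np.uint8) * 255), mode="L"
        ).save(truth_dir / name)
        names.append(name)
    manifest = dict(
        exam_id=exam.exam_id,
        breast_id=exam.breast_id,
        laterality=exam.laterality,
        k=exam.k,
        label_benign=exam.label_benign,
        label_malignant=exam.label_malignant,
        images=names,
    )
    (bundle / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle


def read_exam_bundle(bundle: str | Path) -> tuple[list[np.ndarray], dict]:
    """Load a bundle's images (uint8 -> float in [0, 1]) in manifest order."""
    bundle = Path(bundle)
    manifest_path = bundle / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest.json in {bundle}")
    manifest = json.loads(manifest_path.read_text())
    img_dir = bundle / "images"
    missing = [n for n in manifest["images"] if not (img_dir / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"manifest lists {len(manifest['images'])} images but "
            f"{len(missing)} are missing from {img_dir}: {missing[:3]}"
        )
    if len(manifest["images"]) != manifest.get("k", len(manifest["images"])):
        raise ValueError(
            f"manifest k={manifest.get('k')} does not match "
            f"{len(manifest['images'])} listed images"
        )
    images = [
        np.asarray(Image.open(img_dir / n), dtype=np.float64) / 255.0
        for n in manifest["images"]
    ]
    if not images:
        raise ValueError(f"bundle {bundle} contains no images")
    return images, manifest


def write_cohort(
    exams: list[phantom.PhantomExam], truth: pd.DataFrame, root: str | Path
) -> Path:
    root = Path(root)
    for exam in exams:
        write_exam_bundle(exam, root)
    truth.to_csv(root / "truth.csv", index=False)
    return root


def read_cohort(root: str | Path) -> list[tuple[list[np.ndarray], dict]]:
    root = Path(root)
    bundles = sorted(p for p in root.iterdir() if (p / "manifest.json").exists())
    return [read_exam_bundle(b) for b in bundles]


# ---------------------------------------------------------------------------
# pipeline


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> train -> predict -> evaluate, with a run-summary JSON."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # annotate with the failing stage
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    # simulate
    spec = phantom.PhantomSpec(class_mix=config.class_mix)
    rng_data = np.random.default_rng(config.data_seed)
    exams, truth = stage(
        "simulate", lambda: phantom.gen_cohort(spec, config.n_exams, rng_data)
    )
    data_dir = out / "data"
    stage("simulate", lambda: write_cohort(exams, truth, data_dir))

    train_ex, val_ex, test_ex = phantom.split_cohort(exams, (0.6, 0.2, 0.2), rng_data)

    # train
    tcfg = TrainConfig(epochs=config.epochs, seed=config.train_seed)
    model, history = stage(
        "train",
        lambda: train_model(
            [e.training_view() for e in train_ex],
            [e.training_view() for e in val_ex],
            tcfg,
            config.model_config(),
        ),
    )
    ckpt = out / "model.npz"
    model.save(ckpt)
    history.to_csv(out / "history.csv", index=False)

    # predict
    def _predict() -> pd.DataFrame:
        rows = []
        for e in test_ex:
            pred = predict_breast(model, e.images)
            rows.append(
                dict(
                    breast_id=e.breast_id,
                    y_true_malignant=e.label_malignant,
                    y_hat_benign=repr(pred.y_benign),
                    y_hat_malignant=repr(pred.y_malignant),
                )
            )
        return pd.DataFrame(rows)

    preds = stage("predict", _predict)
    pred_csv = out / "predictions.csv"
    preds.to_csv(pred_csv, index=False)

    # evaluate
    def _evaluate() -> dict:
        labels = preds["y_true_malignant"].to_numpy().astype(int)
        scores = preds["y_hat_malignant"].astype(float).to_numpy()
        metrics: dict[str, float] = {"n_breasts": int(len(labels))}
        if 0 < labels.sum() < len(labels):
            metrics["auroc"] = stats.auroc(scores, labels)
            metrics["auprc"] = stats.auprc(scores, labels)
        return metrics

    metrics = stage("evaluate", _evaluate)
    summary = dict(
        config=asdict(config),
        train_history_tail=history.tail(1).to_dict("records"),
        metrics=metrics,
        file_hashes={
            "predictions.csv": _sha256(pred_csv),
            "history.csv": _sha256(out / "history.csv"),
        },
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
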