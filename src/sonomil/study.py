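"""End-to-end desk-scale study harness.

Bundles the whole weak-supervision experiment into one call: simulate a
phantom cohort, train a committee of MIL models on breast-level labels
only, and evaluate breast-level discrimination plus pointing-game
localization on held-out breasts. Both the acceptance machinery and the
CLI-level demos run through this module so the reported numbers always
come from the same procedure.

The committee deliberately mixes two member families (see
docs/methods.md): instance-normalized backbones, which are the stronger
classifiers at this scale, and unnormalized backbones with a milder
saliency penalty, whose purely local computation keeps the saliency maps
anchored to the lesion. Averaging breast-level scores and saliency maps
over the committee combines both strengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stats
from .inference import pointing_game, predict_breast
from .mil import ModelConfig
from .phantom import PhantomSpec, gen_cohort
from .train import Ensemble, TrainConfig, train_model


@dataclass(frozen=True)
class StudyConfig:
    """Desk-scale study conditions.

    300 breasts: 200 for training (160 optimize / 40 validate for model
    selection) and 100 held out. ``members`` lists the committee as
    (backbone normalization, saliency L1 weight) pairs; each member is an
    independently seeded training run capped at ``epochs`` epochs.
    """

    n_train: int = 160
    n_val: int = 40
    n_heldout: int = 100
    members: tuple[tuple[str, float], ...] = (
        ("instance", 1e-2),
        ("instance", 1e-2),
        ("instance", 1e-2),
        ("none", 1e-3),
        ("none", 1e-3),
        ("none", 1e-3),
    )
    epochs: int = 15


def run_weak_supervision_study(
    seed: int,
    config: StudyConfig = StudyConfig(),
    spec: PhantomSpec | None = None,
) -> dict:
    """Run the full study; returns metrics plus the trained committee.

    All randomness derives from ``seed``: the cohort draw, member
    initializations, augmentation and shuffling.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    n_total = config.n_train + config.n_val + config.n_heldout
    exams, _ = gen_cohort(spec, n_total, rng)
    train_ex = [e.training_view() for e in exams[: config.n_train]]
    val_ex = [
        e.training_view()
        for e in exams[config.n_train : config.n_train + config.n_val]
    ]
    heldout = exams[config.n_train + config.n_val :]

    members = []
    val_aurocs = []
    for norm, beta in config.members:
        tcfg = TrainConfig(
            epochs=config.epochs, beta=beta, seed=int(rng.integers(0, 2**31 - 1))
        )
        model, history = train_model(
            train_ex, val_ex, tcfg, ModelConfig.tiny(norm=norm)
        )
        members.append(model)
        val_aurocs.append(float(history["val_auroc"].max()))
    ensemble = Ensemble(members=members)

    labels = np.array([e.label_malignant for e in heldout])
    scores = np.array(
        [predict_breast(ensemble, e.images).y_malignant for e in heldout]
    )
    pointing, n_images = pointing_game(ensemble, heldout)
    out = dict(
        heldout_auroc=stats.auroc(scores, labels),
        heldout_auprc=stats.auprc(scores, labels),
        pointing_accuracy=pointing,
        n_heldout=len(heldout),
        n_pointing_images=n_images,
        member_val_aurocs=val_aurocs,
        scores=scores,
        labels=labels,
        ensemble=ensemble,
        heldout=heldout,
    )
    op = stats.operating_point_at(scores, labels, 0.9, match="sensitivity")
    out["specificity_at_sens90"] = op.specificity
    out["biopsy_rate_at_sens90"] = op.biopsy_rate
    out["ppv_at_sens90"] = op.ppv
    return out
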