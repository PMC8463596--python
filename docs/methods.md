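# Methods

## The problem

A breast-ultrasound exam yields a variable-length set of B-mode images per
breast; ground truth (pathology) exists only at breast level. `sonomil`
implements a weakly supervised multiple-instance learning (MIL) system that
(i) predicts breast-level probabilities of benign and malignant findings
from the whole image set and (ii) localizes the suspicious region in each
image via saliency maps, despite never seeing pixel- or image-level labels.
Around the model sit the pieces a study of such a system needs: a synthetic
phantom generator that reproduces the learning problem at desk scale, the
cohort rules that assign labels and build a clinically realistic test set
from exam metadata, and the reader-study statistics used to compare an AI
score against radiologists' BI-RADS assessments.

## Model

For one breast, the input is an image set X = {x_1, ..., x_K}, each image
resized to S x S x 3 and standardized. The forward pass is:

1. **Backbone.** A stride-2 convolutional encoder maps each image to a
   spatial feature map h_k of shape (h, w, C). Two profiles are registered:
   `tiny` (S=64, four 3x3 blocks, C=32, h=w=4) used throughout the tests,
   and `deep` (S=256, five blocks, C=512, h=w=8, L=128) mirroring the
   full-scale parameterization. Blocks optionally apply per-channel
   instance normalization (spatial mean/variance, learnable gain and bias)
   before the ReLU; see "Committee" below for why both normalized and
   unnormalized variants are kept.
2. **Saliency head.** A 1x1 convolution with 2 output channels followed by
   a sigmoid yields maps A_k^b, A_k^m in [0,1]^{h x w} — per-location
   evidence for benign and malignant findings. One shared head with two
   filters is used rather than two separate heads; with a linear head the
   two parameterizations are equivalent in capacity.
3. **Gated attention.** Global max pooling turns h_k into v_k in R^C and
   alpha_k = softmax_k( W^T ( tanh(V v_k) ⊙ sigm(U v_k) ) ) gives each
   image a benign and a malignant weight; the two columns are normalized
   independently across the K images (max-subtracted softmax).
4. **Top-t pooling.** Each saliency map aggregates to an image-level
   probability as the mean of its n = ceil(t·h·w) largest entries, with n
   floored at 1. t is a fraction in (0, 1] (the search range is
   [0.1, 0.5]). Ties at the cutoff do not affect the mean of the top-n
   values, so the tie-break is arbitrary by construction.
5. **Breast-level prediction.** y-hat^c = sum_k alpha_k^c y-hat_k^c for
   c in {b, m}: a convex combination, so the breast-level probability lies
   within the range of the image-level ones, and the whole pipeline is
   invariant to permuting or duplicating images in the set.

**Loss.** Per breast, L = sum_{c in {b,m}} [ BCE(y^c, y-hat^c) +
beta · sum_k L1(A_k^c) ], with probabilities clipped at 1e-7 for
finiteness. The L1 term penalizes saliency mass on irrelevant tissue; it is
summed (not averaged) over the K images, with beta compensating for scale.
The benign label participates only through this training loss as multi-task
regularization; model selection and evaluation use the malignant head.

**Gradients.** The package computes all gradients analytically with its own
reverse-mode backward pass (im2col convolutions, instance-norm and softmax
Jacobians, subgradients routed through max pooling and top-t index sets).
Correctness is enforced by a finite-difference check in the test suite
(relative tolerance 1e-4 on a float64 model; coordinates where both
analytic and numeric gradients are below 1e-8 are treated as dead
directions, since central differences are pure round-off there).

## Training

One optimizer step covers `grad_accum` breasts (default 4; gradients are
averaged), using Adam (library-default moments 0.9/0.999) with decoupled
weight decay. Augmentation draws horizontal flips, rotations, translations,
scalings and shears per image. Two policies are registered: the full-scale
policy (flip 0.5, ±45°, ±10% translation, scale 0.7–1.5, shear ±25°),
appropriate for 256-px inputs and long schedules, and the desk-scale
default (flip 0.5, ±10°, ±5%, scale 0.95–1.05, no shear) — at 64 px and 15
epochs the full-scale policy leaves the model underfit, so the scaled-down
study uses the gentler profile. Augmentation alters images only, never the
label pairing.

Normalization of inputs uses the training split's global pixel mean and
standard deviation, computed once and stored in the checkpoint header so
that validation, test and later inference apply the identical transform
(per-image min-max scaling is available behind a flag).

Hyperparameter search samples learning rate, saliency weight beta and
weight decay log10-uniformly (ranges 10^[-5.5,-4], 10^[-3,0.5],
10^[-6,-3.5]) and the pooling fraction t uniformly in [0.1, 0.5]; the
full-scale profile trains 30 trials of 50 epochs and ensembles the top 3 by
validation AUROC. Model selection within a run keeps the epoch with the
highest validation AUROC of the malignant head (the open question of
whether selection should average both heads is resolved in favor of the
malignant head, matching the clinical target).

### Desk-scale committee

At desk scale (160 optimize / 40 validate / 100 held-out breasts, 15
epochs, 64-px phantoms) single runs are noisy, so the study procedure
trains several seeded members and averages their breast-level predictions
and saliency maps. Two backbone variants are deliberately mixed: instance-
normalized members, whose whole-image statistics make them markedly
stronger classifiers at this scale, and unnormalized members, whose purely
local computation keeps the saliency maps anchored to the lesion (the
normalized members' global coupling lets a displaced cell explain the
label, which costs localization, not discrimination). Averaging the
committee combines both strengths. The saliency penalty is set per family
(beta 1e-2 for normalized members, 1e-3 for unnormalized ones, where a
heavier penalty measurably degrades localization); the remaining
desk-scale optimization defaults (lr 6e-3, t 0.25, gradient accumulation
over 4 breasts, 15 epochs) were fixed during development on development
seeds. The full-scale search ranges above remain the documented reference
profile.

## Synthetic phantoms

The generator reproduces the *learning problem*, not ultrasound physics:

- background: a smooth low-frequency tissue field around mid-gray,
  multiplied by Rayleigh-magnitude speckle (unit mean, amplitude 0.35,
  light spatial correlation);
- lesions are hypoechoic: the interior is darkened by a contrast factor
  0.45 through a blurred (1 px) margin. Benign lesions are smooth ovals
  (axis ratio 0.55–0.85); malignant lesions are star-shaped with 6–12
  spicules and radial modulation 0.25–0.5 of the base radius (0.14–0.22 of
  the image side, chosen so spicules survive the 64-px rendering);
- each breast has K ~ U{4..12} images; in positive breasts the lesion is
  rendered in max(2, 0.4·K) of them with per-view jitter — the rest are
  lesion-free speckle, which is what makes attention necessary;
- class mix negative/benign/malignant = 0.4/0.3/0.3; with probability 0.05
  a malignant breast also carries a benign lesion (the dual-label case);
- binary truth masks and bounding boxes are stored for evaluation only.
  The training interface (`PhantomExam.training_view`) exposes images and
  breast-level labels, nothing else; a contract test enforces this.

What passing on phantoms does *not* show: robustness to acquisition
variability, posterior acoustic artifacts, Doppler overlays, burnt-in
annotations, or real lesion appearance. The phantoms establish that the
MIL machinery learns and localizes from weak labels under speckle and
instance ambiguity — nothing more.

## Cohort rules

Labels: a breast is malignant (benign) if any coded malignant (benign)
pathology finding is dated within [exam − 30 d, exam + 120 d], inclusive;
both labels can hold. Finding terms are validated against controlled
malignant/benign vocabularies and unknown terms raise.

Eligibility for the clinically realistic test set:

- non-biopsied BI-RADS 1–2: include iff no malignancy in 0–15 months and a
  BI-RADS 1–2 follow-up exists in 6–24 months;
- non-biopsied BI-RADS 3: include iff no malignancy in 0–15 months and
  either all follow-ups in 4–36 months are BI-RADS 1–2 (at least one
  required — the vacuous reading is rejected) or some follow-up in 24–36
  months is BI-RADS 1–3;
- discordant benign biopsy: include iff a non-discordant biopsy or surgery
  follows the initial discordant biopsy within 6 months;
- malignant breasts: BI-RADS 1–2 or no US-guided sampling excludes;
  BI-RADS 0/3/6 or mixed US+stereotactic/MRI guidance routes to
  `manual_review` (a first-class verdict here, since no images can be
  re-read); BI-RADS 4A–5 with purely US-guided sampling includes. Surgery
  events carry no imaging guidance and do not trigger review.

Months are fixed 30.44-day multiples rounded to whole days (4/6/15/24/36
months = 122/183/457/731/1096 days); all window endpoints are inclusive.
The router is total: every record gets exactly one audited verdict, with
`unroutable` exclusions for anything outside the rule branches (unknown
BI-RADS, biopsied without in-window findings). The synthetic record
generator builds one record per behavioral branch — including every exact
boundary day — and stamps the intended verdict on it, so the rules engine
is validated against construction-time intent, not against itself.

## Reader-study statistics

- BI-RADS ordinalization: {1,2}→0, 3→1, 4A→2, 4B→3, 4C→4, 5→5 (0 and 6
  rejected); dichotomization at ≥4A = biopsy recommendation.
- AUROC via the rank statistic (ties counted half), equal to pairwise
  enumeration; AUPRC as average precision (no interpolation, which avoids
  the optimism of trapezoidal PR integration).
- Operating points match a comparator's sensitivity or specificity as the
  smallest achievable rate ≥ target, no interpolation; ties prefer the
  threshold maximizing the complementary rate. Reported rates: sensitivity,
  specificity, PPV₂ = TP/(TP+FP), NPV, biopsy rate = (TP+FP)/N.
- Hybrid fusion: reader and AI scores are standardized to zero mean and
  unit variance over the table, then combined as λ·reader + (1−λ)·AI with
  λ = 0.5; zero-variance inputs standardize to zeros with a warning.
- Bootstrap: percentile 2.5/97.5 interval over breast-level resamples
  (1000 draws); single-class resamples are redrawn, and the metric is
  declared undefined if more than half of draws fail. The resampling unit
  is the breast; patient clustering is ignored (flagged limitation).
- Permutation test: one-sided, paired; each trial swaps the two models'
  scores per case with probability 1/2; p = (1 + #{null ≥ observed}) /
  (1 + trials), so p ∈ (0, 1].
- Triage: dismiss-mode returns the highest threshold with NPV ≥ target,
  escalate-mode the lowest threshold with PPV ≥ target.
- Readers are ordinalized before entering score-based comparisons; this is
  metric-irrelevant for AUROC and stated for AUPRC.

## Saliency registration and the pointing game

With stride-2 convolutions and symmetric padding, feature cell (i, j) is
centered on input pixel (s·i, s·j), where s is the total stride. Upsampled
heatmaps therefore place cell (i, j) at (s·i, s·j) (bilinear or nearest,
flagged), rather than at the (s·i + s/2) convention of generic image
resizing — the half-cell difference is a systematic registration error at
coarse grids. Localization is scored by the pointing game: the argmax pixel
of the upsampled malignant map must fall inside the planted lesion mask;
chance level is the lesion area fraction (~11% here).

## Numerical choices

- BCE clip 1e-7; attention normalization asserted to 1e-6; permutation/
  duplication invariance tolerated to 1e-5 (float32 forward).
- Softmax with max subtraction; sigmoid computed branch-wise to avoid
  overflow.
- top-t uses argpartition; the index set is cached for the backward pass.
- Max-pool backward routes to the first argmax on exact ties (measure-zero
  for continuous inputs).
- Checkpoints are single `.npz` files with a JSON header (config +
  normalization stats); loading reconstructs the exact model.

## Known limitations

- Phantom realism as listed above; in particular the benign/malignant
  distinction rests entirely on planted morphology.
- Weak supervision does not pin the saliency peak to the lesion center:
  a constant detector offset changes neither the loss nor the AUROC, so
  localization quality varies across seeds more than discrimination does.
  The committee averaging above mitigates but does not eliminate this.
- The full-scale profile (256 px, C=512, 50 epochs, 30 trials) is defined
  and serializable but not exercised by the test suite; all quantitative
  statements in this repository are desk-scale.
- Bootstrap ignores within-patient correlation between breasts.
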