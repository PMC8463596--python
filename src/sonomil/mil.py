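"""Weakly supervised multiple-instance breast-ultrasound classifier.

One *example* is a breast: an ordered set X = {x_1, ..., x_K} of K
preprocessed images. The model:

1. encodes each image with a stride-2 convolutional backbone into a spatial
   feature map h_k of shape (h, w, C);
2. projects h_k through a 1x1 convolution + sigmoid into two saliency maps
   A_k^b, A_k^m in [0,1]^{h x w} (approximate benign / malignant lesion
   locations);
3. global-max-pools h_k into a vector v_k and computes gated-attention
   scores alpha_k = softmax_k( W^T ( tanh(V v_k) * sigm(U v_k) ) ),
   normalized independently per class column across the K images;
4. aggregates each saliency map into an image-level probability via top-t
   pooling (mean of the largest ceil(t*h*w) entries, t a fraction in (0,1]);
5. forms breast-level probabilities y_hat^c = sum_k alpha_k^c y_hat_k^c.

Training minimizes, per breast, the sum over classes c in {benign,
malignant} of BCE(y^c, y_hat^c) + beta * sum_k L1(A_k^c), where the L1 term
discourages the saliency maps from lighting up irrelevant tissue. All
gradients are computed analytically by the module's own backward pass.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn

BCE_EPS = 1e-7
ATTN_NORM_TOL = 1e-6


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``block_channels`` lists the output width of each conv block (stride 2
    each unless ``block_strides`` overrides); the saliency grid is
    ``input_size / total_stride`` on a side and ``C = block_channels[-1]``
    channels feed the attention gates (M = C). ``pool_frac`` is the top-t
    pooling fraction t.
    """

    input_size: int = 64
    block_channels: tuple[int, ...] = (16, 32, 32, 32)
    block_strides: tuple[int, ...] | None = None  # None: all 2
    kernel_size: int = 3
    norm: str = "instance"  # per-channel spatial normalization, or "none"
    attn_dim: int = 16  # L
    pool_frac: float = 0.25  # t
    dtype: str = "float32"

    def __post_init__(self):
        if not 0.0 < self.pool_frac <= 1.0:
            raise ValueError(f"pool_frac must be in (0, 1], got {self.pool_frac}")
        if self.block_strides is not None and len(self.block_strides) != len(
            self.block_channels
        ):
            raise ValueError("block_strides must match block_channels in length")
        if self.norm not in ("instance", "first", "none"):
            raise ValueError(
                f"norm must be 'instance', 'first' or 'none', got {self.norm!r}"
            )
        if self.input_size % self.total_stride != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by the total "
                f"backbone stride {self.total_stride}"
            )

    @property
    def strides(self) -> tuple[int, ...]:
        if self.block_strides is not None:
            return self.block_strides
        return (2,) * len(self.block_channels)

    @property
    def total_stride(self) -> int:
        return int(np.prod(self.strides))

    @property
    def feature_hw(self) -> int:
        return self.input_size // self.total_stride

    @property
    def n_channels(self) -> int:
        return self.block_channels[-1]

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Desk-scale profile: 64x64 input, 4x4x32 features, L=16."""
        return cls(**overrides)

    @classmethod
    def deep(cls, **overrides) -> "ModelConfig":
        """Full-scale profile: 256x256 input, 8x8x512 features, L=128."""
        defaults = dict(
            input_size=256,
            block_channels=(64, 64, 128, 256, 512),
            block_strides=None,
            attn_dim=128,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class BreastPrediction:
    """Breast-level probabilities with per-image attachments."""

    y_benign: float
    y_malignant: float
    image_preds: np.ndarray  # (K, 2) columns [benign, malignant]
    attention: np.ndarray  # (K, 2), each column sums to 1
    saliency: list[np.ndarray]  # per image (h, w, 2)

    @property
    def k(self) -> int:
        return len(self.saliency)


# ---------------------------------------------------------------------------
# pure aggregation operations


def top_t_pool(saliency_map: np.ndarray, t: float) -> float:
    """Mean of the largest ceil(t * h * w) entries of a 2-D map."""
    value, _ = _top_t_pool_cached(np.asarray(saliency_map, dtype=float), t)
    return value


def _top_t_pool_cached(saliency_map: np.ndarray, t: float):
    if not 0.0 < t <= 1.0:
        raise ValueError(f"t must be in (0, 1], got {t}")
    flat = saliency_map.reshape(-1)
    if flat.size == 0:
        raise ValueError("saliency map is empty")
    n = max(1, math.ceil(t * flat.size))
    if n >= flat.size:
        idx = np.arange(flat.size)
    else:
        idx = np.argpartition(flat, flat.size - n)[flat.size - n :]
    return float(flat[idx].mean()), (idx, n, saliency_map.shape)


def image_level_pred(saliency: np.ndarray, t: float) -> tuple[float, float]:
    """Apply top-t pooling independently to the benign and malignant maps.

    ``saliency``: (h, w, 2) with columns [benign, malignant].
    """
    return top_t_pool(saliency[:, :, 0], t), top_t_pool(saliency[:, :, 1], t)


def gated_attention(
    vectors: list[np.ndarray] | np.ndarray,
    attn_w: np.ndarray,
    attn_v: np.ndarray,
    attn_u: np.ndarray,
) -> np.ndarray:
    """Gated-attention weights over an image set.

    Returns alpha of shape (K, 2); each column is a softmax over the K
    images of W^T(tanh(V v_k) * sigm(U v_k)), benign and malignant
    normalized independently.
    """
    vs = np.asarray(vectors, dtype=float)
    if vs.ndim == 1:
        vs = vs[None, :]
    if vs.shape[0] == 0:
        raise ValueError("gated_attention requires at least one vector")
    m = attn_v.shape[1]
    if vs.shape[1] != m:
        raise ValueError(f"vector length {vs.shape[1]} != attention width M={m}")
    gates = np.tanh(vs @ attn_v.T) * nn.sigmoid(vs @ attn_u.T)  # (K, L)
    e = gates @ attn_w  # (K, 2)
    return nn.softmax_columns(e)


def breast_pred(image_preds: np.ndarray, attention: np.ndarray) -> tuple[float, float]:
    """Attention-weighted breast-level probabilities.

    ``image_preds`` and ``attention`` are (K, 2); each attention column must
    already sum to 1 (checked to 1e-6).
    """
    p = np.asarray(image_preds, dtype=float)
    a = np.asarray(attention, dtype=float)
    if p.shape != a.shape:
        raise ValueError(f"shape mismatch: image_preds {p.shape} vs attention {a.shape}")
    if p.shape[0] < 1:
        raise ValueError("need at least one image prediction")
    colsums = a.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > ATTN_NORM_TOL):
        raise ValueError(f"attention columns must sum to 1, got {colsums}")
    y = (a * p).sum(axis=0)
    return float(y[0]), float(y[1])


def saliency_reg(saliency: np.ndarray) -> float:
    """L1 mass of a saliency pair: sum of |A[i, j]| over both maps."""
    return float(np.abs(saliency).sum())


def binary_cross_entropy(y: float, p: float, eps: float = BCE_EPS) -> float:
    if y not in (0, 1):
        raise ValueError(f"label must be binary, got {y}")
    p = min(max(p, eps), 1.0 - eps)
    return -(y * math.log(p) + (1 - y) * math.log(1.0 - p))


def total_loss(
    y: tuple[int, int],
    pred: BreastPrediction,
    saliencies: list[np.ndarray],
    beta: float,
) -> float:
    """Per-breast training loss: class-wise BCE plus beta-weighted L1 saliency mass."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    y_b, y_m = y
    loss = binary_cross_entropy(y_b, pred.y_benign) + binary_cross_entropy(
        y_m, pred.y_malignant
    )
    if beta:
        loss += beta * sum(saliency_reg(s) for s in saliencies)
    return loss


# ---------------------------------------------------------------------------
# the model


class MILModel:
    """Backbone + saliency head + gated attention, with analytic gradients."""

    def __init__(
        self,
        config: ModelConfig,
        rng: np.random.Generator | None = None,
        params: dict[str, np.ndarray] | None = None,
        norm_mean: float = 0.0,
        norm_std: float = 1.0,
    ):
        self.config = config
        self.norm_mean = float(norm_mean)
        self.norm_std = float(norm_std)
        if params is not None:
            self.params = params
        else:
            if rng is None:
                rng = np.random.default_rng(0)
            self.params = self._init_params(rng)

    # -- initialization ----------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        cfg = self.config
        dt = np.dtype(cfg.dtype)
        k = cfg.kernel_size
        params: dict[str, np.ndarray] = {}
        cin = 3
        for i, cout in enumerate(cfg.block_channels):
            fan_in = k * k * cin
            params[f"block{i}_w"] = nn.he_init((cout, k, k, cin), fan_in, rng, dt)
            params[f"block{i}_b"] = np.zeros(cout, dtype=dt)
            if cfg.norm == "instance" or (cfg.norm == "first" and i == 0):
                params[f"block{i}_g"] = np.ones(cout, dtype=dt)
                params[f"block{i}_nb"] = np.zeros(cout, dtype=dt)
            cin = cout
        c = cfg.n_channels
        params["head_w"] = (rng.standard_normal((2, 1, 1, c)) * 0.01).astype(dt)
        params["head_b"] = np.zeros(2, dtype=dt)
        ll, m = cfg.attn_dim, c
        params["attn_V"] = (rng.standard_normal((ll, m)) / np.sqrt(m)).astype(dt)
        params["attn_U"] = (rng.standard_normal((ll, m)) / np.sqrt(m)).astype(dt)
        params["attn_W"] = (rng.standard_normal((ll, 2)) / np.sqrt(ll)).astype(dt)
        return params

    def copy(self) -> "MILModel":
        return MILModel(
            self.config,
            params={k: v.copy() for k, v in self.params.items()},
            norm_mean=self.norm_mean,
            norm_std=self.norm_std,
        )

    # -- forward pieces ----------------------------------------------------

    def _backbone_forward(self, x: np.ndarray, want_cache: bool):
        cfg = self.config
        if x.shape != (cfg.input_size, cfg.input_size, 3):
            raise ValueError(
                f"image shape mismatch: expected "
                f"({cfg.input_size}, {cfg.input_size}, 3), got {x.shape}"
            )
        pad = cfg.kernel_size // 2
        a = np.asarray(x, dtype=cfg.dtype)
        caches = []
        strides = cfg.strides
        for i in range(len(cfg.block_channels)):
            z, ccache = nn.conv2d_forward(
                a,
                self.params[f"block{i}_w"],
                self.params[f"block{i}_b"],
                stride=strides[i],
                pad=pad,
            )
            ncache = None
            if f"block{i}_g" in self.params:
                z, ncache = nn.instance_norm_forward(
                    z, self.params[f"block{i}_g"], self.params[f"block{i}_nb"]
                )
            a, rmask = nn.relu_forward(z)
            if want_cache:
                caches.append((ccache, ncache, rmask))
        return a, caches

    def extract_features(self, image: np.ndarray) -> np.ndarray:
        """Feature map h_k of shape (h, w, C) for one preprocessed image."""
        feats, _ = self._backbone_forward(image, want_cache=False)
        return feats

    def compute_saliency(self, features: np.ndarray) -> np.ndarray:
        """Saliency pair (h, w, 2) = sigmoid of a 1x1 convolution of h_k."""
        if not np.all(np.isfinite(features)):
            raise ValueError("features contain non-finite values")
        pre, _ = nn.conv2d_forward(features, self.params["head_w"], self.params["head_b"])
        return nn.sigmoid(pre)

    # -- full forward ------------------------------------------------------

    def forward(self, images: list[np.ndarray]) -> BreastPrediction:
        """Breast-level prediction for an image set (no gradient caches)."""
        pred, _ = self._forward_full(images, want_cache=False)
        return pred

    def _forward_full(self, images: list[np.ndarray], want_cache: bool):
        if len(images) == 0:
            raise ValueError("image set is empty")
        cfg = self.config
        feats_caches = []
        saliencies = []
        sal_caches = []
        vectors = []
        gmp_caches = []
        pool_caches = []
        image_preds = np.zeros((len(images), 2), dtype=float)
        for k, x in enumerate(images):
            h, bcache = self._backbone_forward(x, want_cache)
            pre, hcache = nn.conv2d_forward(h, self.params["head_w"], self.params["head_b"])
            sal = nn.sigmoid(pre)
            v, gcache = nn.global_max_pool_forward(h)
            yb, cb = _top_t_pool_cached(sal[:, :, 0].astype(float), cfg.pool_frac)
            ym, cm = _top_t_pool_cached(sal[:, :, 1].astype(float), cfg.pool_frac)
            image_preds[k] = (yb, ym)
            saliencies.append(sal)
            vectors.append(v)
            if want_cache:
                feats_caches.append(bcache)
                sal_caches.append(hcache)
                gmp_caches.append(gcache)
                pool_caches.append((cb, cm))
        vs = np.stack(vectors).astype(float)
        gates_t = np.tanh(vs @ self.params["attn_V"].T.astype(float))
        gates_s = nn.sigmoid(vs @ self.params["attn_U"].T.astype(float))
        gates = gates_t * gates_s  # (K, L)
        e = gates @ self.params["attn_W"].astype(float)  # (K, 2)
        alpha = nn.softmax_columns(e)
        y_b, y_m = breast_pred(image_preds, alpha)
        pred = BreastPrediction(
            y_benign=y_b,
            y_malignant=y_m,
            image_preds=image_preds,
            attention=alpha,
            saliency=saliencies,
        )
        cache = None
        if want_cache:
            cache = dict(
                feats_caches=feats_caches,
                sal_caches=sal_caches,
                gmp_caches=gmp_caches,
                pool_caches=pool_caches,
                vs=vs,
                gates_t=gates_t,
                gates_s=gates_s,
                gates=gates,
                alpha=alpha,
            )
        return pred, cache

    # -- loss and gradients ------------------------------------------------

    def loss(self, images: list[np.ndarray], y_b: int, y_m: int, beta: float) -> float:
        pred = self.forward(images)
        return total_loss((y_b, y_m), pred, pred.saliency, beta)

    def loss_and_grads(
        self, images: list[np.ndarray], y_b: int, y_m: int, beta: float
    ):
        """Returns (loss, grads, prediction); grads keyed like ``params``."""
        if beta < 0:
            raise ValueError(f"beta must be >= 0, got {beta}")
        if y_b not in (0, 1) or y_m not in (0, 1):
            raise ValueError(f"labels must be binary, got ({y_b}, {y_m})")
        cfg = self.config
        pred, cache = self._forward_full(images, want_cache=True)
        loss = total_loss((y_b, y_m), pred, pred.saliency, beta)

        grads = {k: np.zeros_like(v, dtype=float) for k, v in self.params.items()}

        # d loss / d breast-level probabilities (clip-aware BCE gradient)
        dy = np.zeros(2)
        for c, (yc, pc) in enumerate(((y_b, pred.y_benign), (y_m, pred.y_malignant))):
            if BCE_EPS < pc < 1.0 - BCE_EPS:
                dy[c] = (pc - yc) / (pc * (1.0 - pc))
        alpha = cache["alpha"]
        dalpha = dy[None, :] * pred.image_preds  # (K, 2)
        dimg = dy[None, :] * alpha  # (K, 2)

        # attention branch
        de = nn.softmax_columns_backward(dalpha, alpha)  # (K, 2)
        w_attn = self.params["attn_W"].astype(float)
        gates_t, gates_s = cache["gates_t"], cache["gates_s"]
        dgates = de @ w_attn.T  # (K, L)
        grads["attn_W"] += cache["gates"].T @ de
        dt_ = dgates * gates_s * (1.0 - gates_t**2)
        ds_ = dgates * gates_t * gates_s * (1.0 - gates_s)
        vs = cache["vs"]
        grads["attn_V"] += dt_.T @ vs
        grads["attn_U"] += ds_.T @ vs
        dvs = dt_ @ self.params["attn_V"].astype(float) + ds_ @ self.params[
            "attn_U"
        ].astype(float)  # (K, M)

        # per-image branches
        for k in range(len(images)):
            sal = pred.saliency[k].astype(float)
            dsal = np.full(sal.shape, beta, dtype=float)  # L1 term, A in (0,1)
            cb, cm = cache["pool_caches"][k]
            for c, cc in enumerate((cb, cm)):
                idx, n, shape = cc
                dflat = np.zeros(shape[0] * shape[1])
                dflat[idx] = dimg[k, c] / n
                dsal[:, :, c] += dflat.reshape(shape)
            dpre = dsal * sal * (1.0 - sal)
            dh_head, dw_head, db_head = nn.conv2d_backward(
                dpre.astype(cfg.dtype), cache["sal_caches"][k], self.params["head_w"]
            )
            grads["head_w"] += dw_head
            grads["head_b"] += db_head
            dh = dh_head.astype(float) + nn.global_max_pool_backward(
                dvs[k], cache["gmp_caches"][k]
            )
            da = dh.astype(cfg.dtype)
            for i in reversed(range(len(cfg.block_channels))):
                ccache, ncache, rmask = cache["feats_caches"][k][i]
                dz = nn.relu_backward(da, rmask)
                if ncache is not None:
                    dz, dg, dnb = nn.instance_norm_backward(dz, ncache)
                    grads[f"block{i}_g"] += dg
                    grads[f"block{i}_nb"] += dnb
                da, dw, db = nn.conv2d_backward(dz, ccache, self.params[f"block{i}_w"])
                grads[f"block{i}_w"] += dw
                grads[f"block{i}_b"] += db

        dt = np.dtype(cfg.dtype)
        grads = {k: v.astype(dt) for k, v in grads.items()}
        return loss, grads, pred

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: arrays plus an embedded JSON config header."""
        header = dict(
            config=asdict(self.config),
            norm_mean=self.norm_mean,
            norm_std=self.norm_std,
        )
        arrays = {f"param/{k}": v for k, v in self.params.items()}
        np.savez(path, __header__=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8
        ), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "MILModel":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            params = {
                k.removeprefix("param/"): data[k]
                for k in data.files
                if k.startswith("param/")
            }
        cfg_dict = header["config"]
        cfg_dict["block_channels"] = tuple(cfg_dict["block_channels"])
        return cls(
            ModelConfig(**cfg_dict),
            params=params,
            norm_mean=header["norm_mean"],
            norm_std=header["norm_std"],
        )
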