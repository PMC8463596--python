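"""Model operations against direct-formula oracles, plus architecture invariants."""

import math

import numpy as np
import pytest

from sonomil import nn
from sonomil.mil import (
    MILModel,
    ModelConfig,
    BreastPrediction,
    binary_cross_entropy,
    breast_pred,
    gated_attention,
    image_level_pred,
    saliency_reg,
    top_t_pool,
    total_loss,
)


@pytest.fixture
def tiny_model(rng):
    cfg = ModelConfig(
        input_size=16, block_channels=(4, 6), attn_dim=5, pool_frac=0.3, dtype="float64"
    )
    return MILModel(cfg, rng=rng)


def random_images(rng, n, size=16):
    return [rng.standard_normal((size, size, 3)) for _ in range(n)]


# -- primitive layers --------------------------------------------------------


def test_conv2d_matches_explicit_loops(rng):
    x = rng.standard_normal((6, 7, 2))
    w = rng.standard_normal((3, 3, 3, 2))
    b = rng.standard_normal(3)
    out, _ = nn.conv2d_forward(x, w, b, stride=1, pad=1)
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            for c in range(3):
                expected = (xp[i : i + 3, j : j + 3, :] * w[c]).sum() + b[c]
                assert out[i, j, c] == pytest.approx(expected, rel=1e-10)


def test_global_max_pool_matches_loop_oracle(rng):
    h = rng.standard_normal((5, 4, 7))
    v, _ = nn.global_max_pool_forward(h)
    for c in range(7):
        assert v[c] == max(h[i, j, c] for i in range(5) for j in range(4))


def test_global_max_pool_constant_and_spike():
    const = np.full((3, 3, 2), 1.7)
    v, _ = nn.global_max_pool_forward(const)
    assert np.allclose(v, 1.7)
    spike = np.zeros((3, 3, 2))
    spike[1, 2, 0] = 5.0
    spike[0, 0, 1] = -1.0
    v, _ = nn.global_max_pool_forward(spike)
    assert v[0] == 5.0 and v[1] == 0.0


# -- top-t pooling -----------------------------------------------------------


def sort_oracle(grid, t):
    flat = sorted(np.asarray(grid).ravel(), reverse=True)
    n = max(1, math.ceil(t * len(flat)))
    return sum(flat[:n]) / n


def test_top_t_examples():
    grid = [[0.1, 0.9], [0.3, 0.5]]
    assert top_t_pool(grid, 0.25) == 0.9  # n=1: the max
    assert top_t_pool(grid, 1.0) == pytest.approx(0.45)  # plain mean
    assert top_t_pool(np.full((4, 4), 0.37), 0.2) == pytest.approx(0.37)


def test_top_t_matches_sort_oracle_all_small_grids(rng):
    for h in range(1, 9):
        for w in range(1, 9):
            grid = rng.random((h, w))
            for t in (1.0 / (h * w), 0.1, 0.25, 0.5, 1.0):
                assert top_t_pool(grid, t) == pytest.approx(
                    sort_oracle(grid, t), abs=1e-15
                )


def test_top_t_nonincreasing_in_n(rng):
    grid = rng.random((6, 6))
    values = [top_t_pool(grid, t) for t in np.linspace(0.03, 1.0, 15)]
    ns = [max(1, math.ceil(t * 36)) for t in np.linspace(0.03, 1.0, 15)]
    for (v1, n1), (v2, n2) in zip(zip(values, ns), zip(values[1:], ns[1:])):
        if n2 > n1:
            assert v2 <= v1 + 1e-12


def test_top_t_invalid_fraction():
    with pytest.raises(ValueError):
        top_t_pool(np.ones((2, 2)), 0.0)
    with pytest.raises(ValueError):
        top_t_pool(np.ones((2, 2)), 1.2)


def test_image_level_pred_per_class(rng):
    sal = rng.random((4, 4, 2))
    yb, ym = image_level_pred(sal, 0.25)
    assert yb == pytest.approx(sort_oracle(sal[:, :, 0], 0.25))
    assert ym == pytest.approx(sort_oracle(sal[:, :, 1], 0.25))
    same = np.dstack([sal[:, :, 0], sal[:, :, 0]])
    yb2, ym2 = image_level_pred(same, 0.4)
    assert yb2 == ym2


# -- gated attention ---------------------------------------------------------


def attention_oracle(vectors, w, v, u):
    """Direct per-image evaluation with explicit log-sum-exp."""
    es = []
    for vec in vectors:
        gate = np.tanh(v @ vec) * (1.0 / (1.0 + np.exp(-(u @ vec))))
        es.append(w.T @ gate)
    es = np.array(es)  # (K, 2)
    out = np.zeros_like(es)
    for c in range(2):
        m = es[:, c].max()
        z = np.exp(es[:, c] - m)
        out[:, c] = z / z.sum()
    return out


def test_attention_singleton_is_one(rng):
    w = rng.standard_normal((5, 2))
    v = rng.standard_normal((5, 8))
    u = rng.standard_normal((5, 8))
    alpha = gated_attention([rng.standard_normal(8)], w, v, u)
    assert np.allclose(alpha, 1.0)


def test_attention_identical_vectors_uniform(rng):
    w = rng.standard_normal((5, 2))
    v = rng.standard_normal((5, 8))
    u = rng.standard_normal((5, 8))
    vec = rng.standard_normal(8)
    alpha = gated_attention([vec] * 4, w, v, u)
    assert np.allclose(alpha, 0.25)


def test_attention_matches_formula_oracle(rng):
    w = rng.standard_normal((5, 2))
    v = rng.standard_normal((5, 8))
    u = rng.standard_normal((5, 8))
    vectors = [rng.standard_normal(8) * 3 for _ in range(3)]
    alpha = gated_attention(vectors, w, v, u)
    assert np.allclose(alpha, attention_oracle(vectors, w, v, u), atol=1e-12)
    assert np.allclose(alpha.sum(axis=0), 1.0, atol=1e-12)


def test_attention_errors():
    w = np.zeros((5, 2))
    v = np.zeros((5, 8))
    u = np.zeros((5, 8))
    with pytest.raises(ValueError):
        gated_attention(np.zeros((0, 8)), w, v, u)
    with pytest.raises(ValueError):
        gated_attention([np.zeros(7)], w, v, u)


# -- breast-level aggregation ------------------------------------------------


def test_breast_pred_direct_expansion():
    preds = np.array([[0.0, 0.0], [0.0, 1.0]])
    alpha = np.array([[0.5, 0.25], [0.5, 0.75]])
    yb, ym = breast_pred(preds, alpha)
    assert yb == 0.0 and ym == 0.75


def test_breast_pred_convexity(rng):
    preds = rng.random((5, 2))
    e = rng.standard_normal((5, 2))
    alpha = np.exp(e) / np.exp(e).sum(axis=0)
    yb, ym = breast_pred(preds, alpha)
    for c, y in enumerate((yb, ym)):
        assert preds[:, c].min() - 1e-12 <= y <= preds[:, c].max() + 1e-12


def test_breast_pred_rejects_unnormalized_attention():
    preds = np.ones((2, 2)) * 0.5
    with pytest.raises(ValueError, match="sum to 1"):
        breast_pred(preds, np.array([[0.6, 0.5], [0.6, 0.5]]))


# -- saliency head and regularizer -------------------------------------------


def test_saliency_zero_head_gives_half(rng):
    cfg = ModelConfig(
        input_size=16, block_channels=(4, 6), attn_dim=5, dtype="float64"
    )
    model = MILModel(cfg, rng=rng)
    model.params["head_w"][:] = 0.0
    model.params["head_b"][:] = 0.0
    feats = model.extract_features(rng.standard_normal((16, 16, 3)))
    sal = model.compute_saliency(feats)
    assert np.allclose(sal, 0.5)
    assert sal.shape == (cfg.feature_hw, cfg.feature_hw, 2)


def test_saliency_bounded_and_monotone(tiny_model, rng):
    feats = tiny_model.extract_features(rng.standard_normal((16, 16, 3)))
    sal = tiny_model.compute_saliency(feats)
    assert np.all((sal > 0) & (sal < 1))
    # raising the malignant head bias raises every malignant map entry
    tiny_model.params["head_b"][1] += 1.0
    sal2 = tiny_model.compute_saliency(feats)
    assert np.all(sal2[:, :, 1] > sal[:, :, 1])
    assert np.allclose(sal2[:, :, 0], sal[:, :, 0])


def test_saliency_rejects_nonfinite(tiny_model):
    feats = np.full((4, 4, 6), np.nan)
    with pytest.raises(ValueError):
        tiny_model.compute_saliency(feats)


def test_saliency_reg_values():
    assert saliency_reg(np.zeros((4, 4, 2))) == 0.0
    single = np.zeros((4, 4, 2))
    single[1, 2, 0] = 0.5
    assert saliency_reg(single) == 0.5
    pos = np.random.default_rng(0).random((3, 3, 2))
    assert saliency_reg(pos) == pytest.approx(pos.sum())


# -- loss --------------------------------------------------------------------


def test_loss_zero_at_perfect_prediction():
    pred = BreastPrediction(1.0, 0.0, np.zeros((1, 2)), np.ones((1, 2)), [])
    loss = total_loss((1, 0), pred, [], beta=0.0)
    assert loss == pytest.approx(0.0, abs=1e-5)


def test_loss_linear_in_beta(rng):
    sal = [rng.random((4, 4, 2)) for _ in range(3)]
    pred = BreastPrediction(0.3, 0.6, np.zeros((3, 2)), np.full((3, 2), 1 / 3), sal)
    l0 = total_loss((0, 1), pred, sal, beta=0.0)
    l1 = total_loss((0, 1), pred, sal, beta=1.0)
    assert l1 - l0 == pytest.approx(sum(s.sum() for s in sal))


def test_loss_rejects_nonbinary_labels():
    with pytest.raises(ValueError):
        binary_cross_entropy(0.5, 0.5)


# -- end-to-end forward invariants -------------------------------------------


def test_feature_shape_contract(rng):
    cfg = ModelConfig()
    model = MILModel(cfg, rng=rng)
    feats = model.extract_features(rng.standard_normal((64, 64, 3)).astype(np.float32))
    assert feats.shape == (4, 4, 32)
    with pytest.raises(ValueError, match="expected"):
        model.extract_features(rng.standard_normal((32, 32, 3)))


def test_forward_deterministic(tiny_model, rng):
    images = random_images(rng, 3)
    p1 = tiny_model.forward(images)
    p2 = tiny_model.forward(images)
    assert p1.y_malignant == p2.y_malignant
    assert p1.y_benign == p2.y_benign


def test_forward_attention_normalized(tiny_model, rng):
    pred = tiny_model.forward(random_images(rng, 5))
    assert np.allclose(pred.attention.sum(axis=0), 1.0, atol=1e-6)


def test_forward_permutation_invariant(tiny_model, rng):
    images = random_images(rng, 5)
    p = tiny_model.forward(images)
    perm = [images[i] for i in (3, 1, 4, 0, 2)]
    q = tiny_model.forward(perm)
    assert q.y_benign == pytest.approx(p.y_benign, abs=1e-5)
    assert q.y_malignant == pytest.approx(p.y_malignant, abs=1e-5)


def test_forward_duplication_invariant(tiny_model, rng):
    images = random_images(rng, 3)
    p = tiny_model.forward(images)
    q = tiny_model.forward(images + images)
    assert q.y_benign == pytest.approx(p.y_benign, abs=1e-5)
    assert q.y_malignant == pytest.approx(p.y_malignant, abs=1e-5)
    # each duplicated image carries half its original attention
    assert np.allclose(q.attention, np.vstack([p.attention, p.attention]) / 2, atol=1e-6)


def test_forward_k1_reduces_to_image_prediction(tiny_model, rng):
    images = random_images(rng, 1)
    p = tiny_model.forward(images)
    assert np.allclose(p.attention, 1.0)
    assert p.y_malignant == pytest.approx(p.image_preds[0, 1])


def test_forward_empty_set_raises(tiny_model):
    with pytest.raises(ValueError):
        tiny_model.forward([])


# -- gradients ---------------------------------------------------------------


def test_analytic_gradient_matches_finite_differences(rng):
    cfg = ModelConfig(
        input_size=16, block_channels=(4, 6), attn_dim=5, pool_frac=0.3, dtype="float64"
    )
    model = MILModel(cfg, rng=rng)
    images = random_images(rng, 3)
    beta = 0.05
    _, grads, _ = model.loss_and_grads(images, 1, 0, beta)
    h = 1e-5
    for name, p in model.params.items():
        flat = p.reshape(-1)
        for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + h
            lp = model.loss(images, 1, 0, beta)
            flat[i] = orig - h
            lm = model.loss(images, 1, 0, beta)
            flat[i] = orig
            num = (lp - lm) / (2 * h)
            ana = grads[name].reshape(-1)[i]
            if max(abs(num), abs(ana)) < 1e-8:
                continue  # dead direction: both gradients are FD noise
            assert abs(num - ana) / max(abs(num), abs(ana), 1e-7) < 1e-4, name


# -- serialization -----------------------------------------------------------


def test_checkpoint_round_trip(tmp_path, tiny_model, rng):
    images = random_images(rng, 2)
    before = tiny_model.forward(images)
    path = tmp_path / "model.npz"
    tiny_model.norm_mean, tiny_model.norm_std = 0.4, 0.2
    tiny_model.save(path)
    loaded = MILModel.load(path)
    after = loaded.forward(images)
    assert after.y_malignant == pytest.approx(before.y_malignant, abs=1e-12)
    assert loaded.config == tiny_model.config
    assert loaded.norm_mean == 0.4 and loaded.norm_std == 0.2
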