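"""Reader-study statistics against brute-force oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from sonomil import stats
from sonomil.stats import (
    CIResult,
    HybridConfig,
    auprc,
    auroc,
    birads_to_ordinal,
    bootstrap_ci,
    dichotomize_birads,
    hybrid_scores,
    operating_point_at,
    permutation_test,
    subgroup_eval,
    triage_points,
)


# -- independent oracles -----------------------------------------------------


def auroc_pairs(scores, labels):
    """Exhaustive positive-negative pair enumeration."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def sweep_points(scores, labels):
    """All distinct confusion matrices for 'score >= thr positive'."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    out = []
    for thr in list(np.unique(scores)) + [np.max(scores) + 1.0]:
        pos = scores >= thr
        tp = int((pos & (labels == 1)).sum())
        fp = int((pos & (labels == 0)).sum())
        fn = int((~pos & (labels == 1)).sum())
        tn = int((~pos & (labels == 0)).sum())
        out.append((thr, tp, fp, fn, tn))
    return out


def random_table(rng, n=15):
    labels = np.zeros(n, dtype=int)
    labels[: max(1, n // 3)] = 1
    rng.shuffle(labels)
    scores = np.round(rng.random(n), 3)  # rounding forces occasional ties
    return scores, labels


# -- BI-RADS coding ----------------------------------------------------------


@pytest.mark.parametrize(
    "score,expected",
    [("1", 0), ("2", 0), ("3", 1), ("4A", 2), ("4B", 3), ("4C", 4), ("5", 5)],
)
def test_suspicion_index_mapping(score, expected):
    assert birads_to_ordinal(score) == expected


@pytest.mark.parametrize("bad", ["0", "6", "7", "unknown"])
def test_disallowed_birads_raise(bad):
    with pytest.raises(ValueError):
        birads_to_ordinal(bad)
    with pytest.raises(ValueError):
        dichotomize_birads(bad)


@pytest.mark.parametrize(
    "score,expected",
    [("1", 0), ("2", 0), ("3", 0), ("4A", 1), ("4B", 1), ("4C", 1), ("5", 1)],
)
def test_biopsy_recommendation_threshold(score, expected):
    assert dichotomize_birads(score) == expected


# -- ranking metrics ---------------------------------------------------------


def test_auroc_separated_and_ties():
    assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert auroc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5


def test_auroc_single_class_raises():
    with pytest.raises(ValueError):
        auroc([0.1, 0.9], [1, 1])


def test_auroc_matches_pair_oracle_and_sklearn(small_table_rng):
    for _ in range(100):
        scores, labels = random_table(small_table_rng)
        ours = auroc(scores, labels)
        assert ours == pytest.approx(auroc_pairs(scores, labels), abs=1e-12)
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_auroc_invariant_under_monotone_recoding(small_table_rng):
    scores, labels = random_table(small_table_rng)
    ref = auroc(scores, labels)
    assert auroc(np.exp(4 * scores), labels) == pytest.approx(ref, abs=1e-12)
    # ordinal recoding of ranks, as with BI-RADS suspicion indices
    order = {s: i for i, s in enumerate(sorted(set(scores)))}
    assert auroc([order[s] for s in scores], labels) == pytest.approx(ref, abs=1e-12)


def test_auprc_perfect_and_constant():
    assert auprc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    # all ties: precision equals prevalence at every recall
    assert auprc([0.5] * 10, [1, 0, 0, 0, 0, 1, 0, 0, 0, 0]) == pytest.approx(0.2)


def test_auprc_requires_positives():
    with pytest.raises(ValueError):
        auprc([0.3, 0.6], [0, 0])


def test_auprc_matches_threshold_enumeration(small_table_rng):
    # average precision = sum over positive-prediction thresholds of
    # precision * recall increment, walking down the distinct scores
    for _ in range(50):
        scores, labels = random_table(small_table_rng, n=10)
        expected = 0.0
        prev_recall = 0.0
        n_pos = labels.sum()
        for thr in sorted(set(scores), reverse=True):
            pos = scores >= thr
            tp = int((pos & (labels == 1)).sum())
            precision = tp / int(pos.sum())
            recall = tp / n_pos
            expected += precision * (recall - prev_recall)
            prev_recall = recall
        assert auprc(scores, labels) == pytest.approx(expected, abs=1e-12)


# -- operating points --------------------------------------------------------


def test_operating_point_identities(small_table_rng):
    scores, labels = random_table(small_table_rng, n=20)
    op = operating_point_at(scores, labels, 0.8, match="sensitivity")
    n = len(scores)
    tp = round(op.sensitivity * labels.sum())
    assert op.biopsy_rate == pytest.approx((tp + round((1 - op.specificity) * (n - labels.sum()))) / n)
    assert op.ppv * op.biopsy_rate * n == pytest.approx(tp)


def test_operating_point_matches_sweep_oracle(small_table_rng):
    for _ in range(100):
        scores, labels = random_table(small_table_rng, n=12)
        target = float(small_table_rng.random())
        for match in ("sensitivity", "specificity"):
            pts = sweep_points(scores, labels)
            cands = []
            for thr, tp, fp, fn, tn in pts:
                sens = tp / (tp + fn)
                spec = tn / (tn + fp)
                matched = sens if match == "sensitivity" else spec
                other = spec if match == "sensitivity" else sens
                if matched >= target - 1e-12:
                    cands.append((matched, -other, thr))
            if not cands:
                with pytest.raises(ValueError):
                    operating_point_at(scores, labels, target, match=match)
                continue
            best_rate = min(cands)[0]
            best_other = -min(c[1] for c in cands if c[0] == best_rate)
            op = operating_point_at(scores, labels, target, match=match)
            assert getattr(op, match) == pytest.approx(best_rate, abs=1e-12)
            other_name = "specificity" if match == "sensitivity" else "sensitivity"
            assert getattr(op, other_name) == pytest.approx(best_other, abs=1e-12)


def test_operating_point_extreme_targets():
    scores = [0.1, 0.2, 0.3, 0.8, 0.9]
    labels = [0, 0, 0, 1, 1]
    op0 = operating_point_at(scores, labels, 0.0, match="sensitivity")
    assert op0.specificity == 1.0 and op0.biopsy_rate == 0.0
    op1 = operating_point_at(scores, labels, 1.0, match="sensitivity")
    assert op1.sensitivity == 1.0 and op1.specificity == 1.0  # separable scores


# -- hybrid fusion -----------------------------------------------------------


def test_hybrid_endpoints_preserve_rankings(small_table_rng):
    scores, labels = random_table(small_table_rng, n=12)
    reader = small_table_rng.integers(0, 6, size=12).astype(float)
    # guarantee both classes rankable
    fused_reader = hybrid_scores(reader, scores, HybridConfig(fusion_weight=1.0))
    fused_ai = hybrid_scores(reader, scores, HybridConfig(fusion_weight=0.0))
    assert auroc(fused_reader, labels) == pytest.approx(auroc(reader, labels), abs=1e-12)
    assert auroc(fused_ai, labels) == pytest.approx(auroc(scores, labels), abs=1e-12)


def test_hybrid_matches_hand_computation():
    reader = [0.0, 0.0, 1.0, 2.0, 4.0, 5.0]
    ai = [0.10, 0.20, 0.15, 0.50, 0.80, 0.90]
    # hand oracle: standardize each list with population std, then average
    def standardized(xs):
        m = sum(xs) / len(xs)
        sd = (sum((x - m) ** 2 for x in xs) / len(xs)) ** 0.5
        return [(x - m) / sd for x in xs]

    expected = [
        0.5 * r + 0.5 * a for r, a in zip(standardized(reader), standardized(ai))
    ]
    fused = hybrid_scores(reader, ai, HybridConfig(fusion_weight=0.5))
    assert fused == pytest.approx(expected, abs=1e-12)


def test_hybrid_zero_variance_warns():
    with pytest.warns(UserWarning):
        fused = hybrid_scores([1.0, 1.0, 1.0], [0.1, 0.5, 0.9])
    assert fused == pytest.approx([0.5 * z for z in
                                   [(x - 0.5) / np.std([0.1, 0.5, 0.9]) for x in [0.1, 0.5, 0.9]]])


# -- bootstrap ---------------------------------------------------------------


def _auroc_on(table):
    return auroc(table["score"].to_numpy(), table["label"].to_numpy())


def test_bootstrap_constant_metric_zero_width(rng):
    table = pd.DataFrame({"score": [0.9] * 8, "label": [1, 0] * 4})
    ci = bootstrap_ci(lambda t: float((t["score"] >= 0.5).mean()), table, n_boot=100, rng=rng)
    assert ci.point == ci.lower95 == ci.upper95 == 1.0


def test_bootstrap_seeded_determinism():
    table = pd.DataFrame(
        {"score": np.linspace(0, 1, 30), "label": ([0, 1] * 15)}
    )
    a = bootstrap_ci(_auroc_on, table, n_boot=200, rng=np.random.default_rng(5))
    b = bootstrap_ci(_auroc_on, table, n_boot=200, rng=np.random.default_rng(5))
    assert (a.lower95, a.upper95) == (b.lower95, b.upper95)
    assert a.lower95 <= a.point <= a.upper95


# -- permutation test --------------------------------------------------------


def _auroc_metric(scores, labels):
    return auroc(scores, labels)


def test_permutation_identical_scores_p_one(rng):
    labels = np.array([0, 1] * 10)
    s = np.linspace(0, 1, 20)
    p = permutation_test(_auroc_metric, labels, s, s.copy(), n_trials=200, rng=rng)
    assert p == 1.0


def test_permutation_p_in_unit_interval(rng):
    labels = np.array([0, 1] * 10)
    a = np.linspace(0, 1, 20)
    b = rng.random(20)
    p = permutation_test(_auroc_metric, labels, a, b, n_trials=99, rng=rng)
    assert 0.0 < p <= 1.0


def test_permutation_detects_dominant_model(rng):
    # model a perfectly separates; model b is noise: p should be small
    labels = np.array([0] * 15 + [1] * 15)
    a = np.concatenate([np.linspace(0, 0.4, 15), np.linspace(0.6, 1.0, 15)])
    b = rng.random(30)
    p = permutation_test(_auroc_metric, labels, a, b, n_trials=500, rng=rng)
    assert p < 0.05


# -- triage ------------------------------------------------------------------


def test_triage_separable_dismiss():
    scores = [0.05, 0.1, 0.2, 0.8, 0.9]
    labels = [0, 0, 0, 1, 1]
    op = triage_points(scores, labels, mode="dismiss", target=1.0)
    assert op.specificity == 1.0 and op.npv == 1.0


def test_triage_escalate_at_prevalence():
    scores = [0.3, 0.6, 0.2, 0.9]
    labels = [0, 1, 0, 1]
    op = triage_points(scores, labels, mode="escalate", target=0.5)
    assert op.sensitivity == 1.0


def test_triage_matches_sweep_oracle(small_table_rng):
    for _ in range(50):
        scores, labels = random_table(small_table_rng, n=12)
        target = 0.5 + 0.5 * float(small_table_rng.random())
        pts = sweep_points(scores, labels)
        feas = []
        for thr, tp, fp, fn, tn in pts:
            if tn + fn > 0 and tn / (tn + fn) >= target - 1e-12:
                feas.append(thr)
        if feas:
            op = triage_points(scores, labels, mode="dismiss", target=target)
            assert op.threshold == pytest.approx(max(feas))
        else:
            with pytest.raises(ValueError):
                triage_points(scores, labels, mode="dismiss", target=target)


def test_triage_unreachable_reports_best():
    scores = [0.4, 0.6, 0.5, 0.7]
    labels = [1, 0, 1, 0]  # inverted scores: high NPV unreachable
    with pytest.raises(ValueError, match="best achievable"):
        triage_points(scores, labels, mode="dismiss", target=0.999)


# -- subgroups ---------------------------------------------------------------


def test_subgroup_single_group_equals_overall(rng):
    table = pd.DataFrame(
        {"score": np.linspace(0, 1, 20), "label": [0, 1] * 10, "site": ["a"] * 20}
    )
    res = subgroup_eval(table, "site", _auroc_on, n_boot=50, rng=rng)
    assert set(res) == {"a"}
    assert res["a"].point == pytest.approx(_auroc_on(table))


def test_subgroup_single_class_group_is_undefined(rng):
    table = pd.DataFrame(
        {
            "score": [0.2, 0.8, 0.3, 0.7],
            "label": [0, 1, 0, 0],
            "site": ["a", "a", "b", "b"],
        }
    )
    res = subgroup_eval(table, "site", _auroc_on, n_boot=20, rng=rng)
    assert isinstance(res["a"], CIResult)
    assert res["b"] is None


def test_subgroup_unknown_column_raises(rng):
    with pytest.raises(ValueError):
        subgroup_eval(pd.DataFrame({"x": [1]}), "site", _auroc_on, rng=rng)
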