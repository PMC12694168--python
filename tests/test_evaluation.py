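"""Metrics, confusion normalization, bootstrap aggregation, macro AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protoshot.evaluation import (
    aggregate,
    episode_metrics,
    macro_auc_ovr,
    multi_seed_summary,
    normalize_confusion,
)


# --- episode metrics -----------------------------------------------------


def test_perfect_predictions():
    m = episode_metrics([0, 1, 2, 3], [0, 1, 2, 3], 4)
    assert m.accuracy == 1.0
    assert np.all(m.f1 == 1.0)
    assert np.array_equal(m.confusion, np.eye(4, dtype=int))


def test_all_predicted_class_zero_closed_form():
    true = [0, 1, 2, 3] * 5
    m = episode_metrics(true, [0] * 20, 4)
    assert m.accuracy == 0.25
    assert m.recall[0] == 1.0
    assert m.precision[0] == 0.25
    assert np.all(m.precision[1:] == 0)  # zero denominators reported as 0
    assert m.zero_division_flags[1:].all()


def test_metrics_match_hand_tally_oracle():
    rng = np.random.default_rng(0)
    true = rng.integers(0, 4, 40)
    pred = rng.integers(0, 4, 40)
    m = episode_metrics(true, pred, 4)
    conf = np.zeros((4, 4), dtype=int)
    for t, p in zip(true, pred):
        conf[t, p] += 1
    assert np.array_equal(m.confusion, conf)
    for c in range(4):
        tp = conf[c, c]
        prec = tp / conf[:, c].sum() if conf[:, c].sum() else 0.0
        rec = tp / conf[c].sum() if conf[c].sum() else 0.0
        assert m.precision[c] == pytest.approx(prec)
        assert m.recall[c] == pytest.approx(rec)
        if prec + rec:
            assert m.f1[c] == pytest.approx(2 * prec * rec / (prec + rec))
    assert m.accuracy == pytest.approx(np.trace(conf) / conf.sum())


def test_out_of_range_label_rejected():
    with pytest.raises(ValueError):
        episode_metrics([0, 4], [0, 0], 4)


# --- confusion normalization ---------------------------------------------


def test_identity_counts_normalize_to_identity():
    out, zero = normalize_confusion(np.eye(4) * 7)
    assert np.array_equal(out, np.eye(4))
    assert not zero.any()


def test_row_normalization_closed_form():
    out, _ = normalize_confusion(np.array([[2.0, 2.0, 0.0, 0.0]]))
    assert np.array_equal(out, [[0.5, 0.5, 0.0, 0.0]])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_random_counts_rows_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 20, (4, 4))
    out, zero = normalize_confusion(counts)
    sums = out.sum(axis=1)
    for r in range(4):
        if zero[r]:
            assert sums[r] == 0
        else:
            assert abs(sums[r] - 1) < 1e-12


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        normalize_confusion(np.array([[-1.0, 2.0]]))


# --- aggregation ---------------------------------------------------------


def _mets(accs):
    out = []
    for a in accs:
        n_correct = int(round(a * 20))
        true = [0, 1, 2, 3] * 5
        pred = list(true)
        for i in range(20 - n_correct):
            pred[i] = (pred[i] + 1) % 4
        out.append(episode_metrics(true, pred, 4))
    return out


def test_degenerate_equal_accuracies():
    rep = aggregate(_mets([0.8] * 10), seed=0)
    assert rep.mean_accuracy == pytest.approx(0.8)
    assert rep.sd_accuracy == 0.0
    assert rep.ci_low == pytest.approx(0.8) and rep.ci_high == pytest.approx(0.8)


def test_two_point_sd_closed_form():
    rep = aggregate(_mets([0.8, 0.9]), seed=0)
    assert rep.mean_accuracy == pytest.approx(0.85)
    assert rep.sd_accuracy == pytest.approx(np.std([0.8, 0.9], ddof=1))
    assert rep.sd_accuracy == pytest.approx(0.0707, abs=2e-4)


def test_single_episode_sd_undefined():
    rep = aggregate(_mets([0.75]), seed=0)
    assert rep.sd_accuracy is None and rep.ci_low is None


def test_ci_bracket_contains_mean():
    rng = np.random.default_rng(1)
    rep = aggregate(_mets(rng.uniform(0.5, 1.0, 50)), seed=3)
    assert rep.ci_low <= rep.mean_accuracy <= rep.ci_high


def test_bootstrap_seeded_reproducible():
    mets = _mets(np.random.default_rng(2).uniform(0.4, 0.9, 30))
    a = aggregate(mets, seed=5)
    b = aggregate(mets, seed=5)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


def test_pooled_accuracy_conservation():
    """Pooled accuracy equals trace over total of the pooled counts."""
    rng = np.random.default_rng(3)
    mets = []
    for _ in range(25):
        true = rng.integers(0, 4, 20)
        pred = rng.integers(0, 4, 20)
        mets.append(episode_metrics(true, pred, 4))
    pooled = np.sum([m.confusion for m in mets], axis=0)
    mean_acc = np.mean([m.accuracy for m in mets])
    assert mean_acc == pytest.approx(np.trace(pooled) / pooled.sum())


# --- macro AUC -----------------------------------------------------------


def test_perfectly_separating_scores_auc_one():
    true = [0, 1, 2, 3] * 3
    scores = np.eye(4)[true] * 5.0
    auc, skipped = macro_auc_ovr(scores, true)
    assert auc == 1.0 and not skipped.any()


def test_constant_scores_auc_half():
    true = [0, 1, 2, 3] * 3
    auc, _ = macro_auc_ovr(np.ones((12, 4)), true)
    assert auc == pytest.approx(0.5)


def test_auc_matches_all_pairs_oracle():
    rng = np.random.default_rng(4)
    true = rng.integers(0, 4, 30)
    scores = rng.standard_normal((30, 4))
    auc, _ = macro_auc_ovr(scores, true)
    per_class = []
    for c in range(4):
        pos = scores[true == c, c]
        neg = scores[true != c, c]
        if len(pos) == 0 or len(neg) == 0:
            continue
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        per_class.append(wins / (len(pos) * len(neg)))
    assert abs(auc - np.mean(per_class)) < 1e-12


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(5)
    true = rng.integers(0, 4, 60)
    scores = rng.standard_normal((60, 4))
    e = np.exp(scores)
    probs = e / e.sum(axis=1, keepdims=True)  # sklearn ovr wants probabilities
    auc, _ = macro_auc_ovr(probs, true)
    ref = roc_auc_score(true, probs, multi_class="ovr", average="macro")
    assert auc == pytest.approx(ref, abs=1e-10)


def test_auc_invariant_to_monotone_transform():
    rng = np.random.default_rng(6)
    true = rng.integers(0, 4, 40)
    scores = rng.standard_normal((40, 4))
    a, _ = macro_auc_ovr(scores, true)
    b, _ = macro_auc_ovr(np.exp(3 * scores) + 7, true)
    assert a == pytest.approx(b, abs=1e-12)


def test_absent_class_skipped_with_flag():
    true = [0, 0, 1, 1]
    auc, skipped = macro_auc_ovr(np.random.default_rng(7).standard_normal((4, 4)), true)
    assert skipped[2] and skipped[3]
    assert auc is not None


def test_single_class_truth_undefined():
    auc, skipped = macro_auc_ovr(np.ones((3, 2)), [0, 0, 0])
    assert auc is None and skipped.all()


# --- multi-seed ----------------------------------------------------------


def test_identical_seeds_consistent():
    reps = {s: aggregate(_mets([0.8, 0.85, 0.9]), seed=0) for s in (1, 2, 3)}
    s = multi_seed_summary(reps)
    assert s["sd_accuracy"] == 0.0 and s["consistent"]


def test_divergent_seeds_flagged():
    reps = {1: aggregate(_mets([0.8] * 5), seed=0),
            2: aggregate(_mets([0.9] * 5), seed=0)}
    s = multi_seed_summary(reps)
    assert s["max_deviation"] == pytest.approx(0.05)
    assert not s["consistent"]


def test_multi_seed_matches_independent_recomputation():
    rng = np.random.default_rng(8)
    accs = {s: rng.uniform(0.6, 0.9, 10) for s in range(5)}
    reps = {s: aggregate(_mets(a), seed=0) for s, a in accs.items()}
    summ = multi_seed_summary(reps)
    means = np.array([reps[s].mean_accuracy for s in range(5)])
    assert summ["mean_accuracy"] == pytest.approx(means.mean())
    assert summ["sd_accuracy"] == pytest.approx(means.std(ddof=1))
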