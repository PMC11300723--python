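"""The statistical battery against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enterogram.metrics import (
    delong_test,
    dice,
    dice_on_slices,
    icc_two_way_agreement,
    joint_confusion,
    roc_auroc,
    select_evaluation_slices,
    unpaired_t_test,
)

# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------


def test_dice_identities():
    a = np.zeros((4, 4), dtype=bool)
    a[:2] = True
    assert dice(a, a) == 1.0
    assert dice(a, ~a) == 0.0
    assert dice(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0


def test_dice_closed_form():
    a = np.zeros(12, dtype=bool)
    b = np.zeros(12, dtype=bool)
    a[:8] = True  # |A| = 8
    b[6:10] = True  # |B| = 4, overlap = 2
    assert dice(a, b) == pytest.approx(2 * 2 / 12)


def test_dice_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        dice(np.zeros((2, 2)), np.zeros((3, 3)))


def test_dice_symmetry():
    rng = np.random.default_rng(0)
    a = rng.random((6, 6)) < 0.4
    b = rng.random((6, 6)) < 0.4
    assert dice(a, b) == dice(b, a)


# ---------------------------------------------------------------------------
# ICC (two-way, absolute agreement, single measurement)
# ---------------------------------------------------------------------------


def test_icc_perfect_agreement():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    icc, f, p = icc_two_way_agreement(x, x)
    assert icc == pytest.approx(1.0)
    assert p < 1e-6


def test_icc_penalizes_constant_offset():
    rng = np.random.default_rng(1)
    x = rng.normal(size=20)
    y = x + 5.0
    icc, _, _ = icc_two_way_agreement(x, y)
    r = stats.pearsonr(x, y).statistic
    assert icc < r
    assert icc < 0.5  # the offset is large relative to the spread


def test_icc_matches_mean_squares_arithmetic():
    """Six-pair worked example against the explicit variance-components
    formula (MSR - MSE) / (MSR + MSE + 2/n (MSC - MSE))."""
    x = np.array([9.0, 10.0, 6.0, 11.0, 12.0, 4.0])
    y = np.array([10.0, 12.0, 7.0, 13.0, 11.0, 6.0])
    data = np.stack([x, y], axis=1)
    n, k = data.shape
    grand = data.mean()
    msr = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
    mse = (
        np.sum((data - data.mean(1, keepdims=True) - data.mean(0) + grand) ** 2)
        / ((n - 1) * (k - 1))
    )
    expected = (msr - mse) / (msr + mse + k / n * (msc - mse))
    icc, f, _ = icc_two_way_agreement(x, y)
    assert icc == pytest.approx(expected)
    assert f == pytest.approx(msr / mse)


def test_icc_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(7)
    x = rng.normal(10, 3, size=30)
    y = 0.8 * x + rng.normal(0, 1.5, size=30) + 1.0
    icc, _, p = icc_two_way_agreement(x, y)
    df = pd.DataFrame(
        {
            "targets": np.tile(np.arange(30), 2),
            "raters": np.repeat(["a", "b"], 30),
            "scores": np.concatenate([x, y]),
        }
    )
    ref = pingouin.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
    row = ref[ref.Type == "ICC(A,1)"].iloc[0]
    assert icc == pytest.approx(row.ICC, abs=1e-9)
    assert p == pytest.approx(row.pval, rel=1e-6)


def test_icc_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        icc_two_way_agreement(np.ones(5), np.ones(5))
    with pytest.raises(ValueError):
        icc_two_way_agreement(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


def test_icc_invariant_under_joint_affine():
    rng = np.random.default_rng(11)
    x = rng.normal(size=25)
    y = x + rng.normal(0, 0.3, size=25)
    icc1, _, _ = icc_two_way_agreement(x, y)
    icc2, _, _ = icc_two_way_agreement(3.0 * x - 7.0, 3.0 * y - 7.0)
    assert icc2 == pytest.approx(icc1)


# ---------------------------------------------------------------------------
# ROC / AUROC / DeLong
# ---------------------------------------------------------------------------


def test_auroc_identities():
    labels = np.array([0, 0, 0, 1, 1], dtype=bool)
    _, auc = roc_auroc(np.array([0.1, 0.2, 0.3, 0.8, 0.9]), labels)
    assert auc == 1.0
    _, auc = roc_auroc(np.full(5, 0.5), labels)
    assert auc == 0.5


def test_auroc_matches_pair_counting():
    rng = np.random.default_rng(3)
    scores = rng.normal(size=25)
    labels = rng.random(25) < 0.4
    labels[:2] = [True, False]  # both classes present
    _, auc = roc_auroc(scores, labels)
    pos, neg = scores[labels], scores[~labels]
    pairs = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    assert auc == pytest.approx(pairs / (len(pos) * len(neg)))


def test_auroc_orientation_identity():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=40)
    labels = rng.random(40) < 0.5
    labels[:2] = [True, False]
    _, a1 = roc_auroc(scores, labels)
    _, a2 = roc_auroc(-scores, labels)
    assert a1 + a2 == pytest.approx(1.0)


def test_auroc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auroc(np.arange(4.0), np.ones(4, dtype=bool))


def test_delong_identical_paired_scores():
    rng = np.random.default_rng(9)
    scores = rng.normal(size=30)
    labels = rng.random(30) < 0.5
    labels[:2] = [True, False]
    z, p = delong_test(scores, scores, labels)
    assert z == 0.0
    assert p == 1.0


def test_delong_detects_separation_difference():
    """Good vs. chance-level scores at n = 200: p < 0.05 in >= 95% of
    seeded replicates (unpaired variant)."""
    hits = 0
    n_rep = 40
    for rep in range(n_rep):
        rng = np.random.default_rng(1000 + rep)
        labels = rng.random(200) < 0.5
        labels[:2] = [True, False]
        good = labels.astype(float) * 2.0 + rng.normal(size=200)
        noise = rng.normal(size=200)
        _, p = delong_test(good, noise, labels, labels_b=labels)
        hits += p < 0.05
    assert hits >= int(0.95 * n_rep)


def test_delong_variance_close_to_bootstrap():
    rng = np.random.default_rng(17)
    n = 500
    labels = rng.random(n) < 0.4
    labels[:2] = [True, False]
    scores = labels * 1.0 + rng.normal(size=n)
    from enterogram.metrics import _delong_variance

    _, var = _delong_variance(scores, labels)
    boots = []
    for _ in range(200):
        idx = rng.integers(0, n, n)
        lb, sb = labels[idx], scores[idx]
        if lb.all() or not lb.any():
            continue
        pos, neg = sb[lb], sb[~lb]
        r = stats.rankdata(np.concatenate([pos, neg]))
        boots.append((r[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))
    assert var == pytest.approx(np.var(boots, ddof=1), rel=0.20)


# ---------------------------------------------------------------------------
# joint confusion / t-test
# ---------------------------------------------------------------------------


def test_joint_confusion_perfect():
    y = np.array([True, False, True, False])
    sens, spec, p = joint_confusion(y, y)
    assert sens == 1.0 and spec == 1.0
    assert p == 1.0  # no discordant pairs


def test_joint_confusion_closed_form():
    meas = np.concatenate([np.ones(10, bool), np.zeros(90, bool)])
    pred = meas.copy()
    pred[9] = False  # one FN
    pred[10:15] = True  # five FP
    sens, spec, p = joint_confusion(pred, meas)
    assert sens == pytest.approx(0.9)
    assert spec == pytest.approx(85 / 90)
    assert 0 < p < 1


def test_joint_confusion_no_positives_flagged_undefined():
    meas = np.zeros(10, dtype=bool)
    pred = np.zeros(10, dtype=bool)
    sens, spec, p = joint_confusion(pred, meas)
    assert sens is None
    assert spec == 1.0


def test_unpaired_t_test_identities():
    a = np.array([1.0, 2.0, 3.0])
    assert unpaired_t_test(a, a) == 1.0
    b0 = np.random.default_rng(0).normal(0, 1, 20)
    b1 = b0 + 10.0
    assert unpaired_t_test(b0, b1) < 1e-6
    assert unpaired_t_test(b0, b1) == unpaired_t_test(b1, b0)


# ---------------------------------------------------------------------------
# evaluation-slice protocol
# ---------------------------------------------------------------------------


def test_evaluation_slices_hit_required_organ_groups(obstructed_phantom):
    truth = obstructed_phantom.truth
    s_stomach, s_sb, s_colon = select_evaluation_slices(truth, seed=3)
    lon = truth.longitude
    assert np.any((lon[:, :, s_stomach] >= 20) & (lon[:, :, s_stomach] < 30))
    assert np.any((lon[:, :, s_sb] >= 40) & (lon[:, :, s_sb] < 80))
    assert np.any(lon[:, :, s_colon] >= 90)


def test_dice_on_slices_of_identical_masks(obstructed_phantom):
    truth = obstructed_phantom.truth
    slices = select_evaluation_slices(truth, seed=1)
    assert dice_on_slices(truth, truth, slices) == 1.0
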