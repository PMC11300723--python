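"""The evaluation battery: Dice, ICC, ROC/AUROC, DeLong, McNemar, t-test.

Agreement between predicted and reference values is quantified with the
two-way absolute-agreement single-measurement intraclass correlation
ICC(A,1), with an F-test against zero correlation; threshold tasks
(diameter > 30 mm, longitude < 40 or > 80) use ROC curves and AUROC, with
DeLong's variance estimate for comparing AUROCs; the joint dilated /
nondilated small-bowel classifications are summarized by sensitivity and
specificity with McNemar's test on the discordant pairs; per-scan Dice
scores between groups are compared with Welch's unpaired t-test.

Per-scan Dice is evaluated on three designated axial slices (one
containing stomach, one small bowel, one colon, chosen at random under
those constraints), mirroring a protocol where exhaustive manual
segmentation is time-prohibitive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .embed import LabelVolumes
from .profile import ILEOCECAL_LONGITUDE, TREITZ_LONGITUDE

__all__ = [
    "dice",
    "icc_two_way_agreement",
    "roc_auroc",
    "delong_test",
    "joint_confusion",
    "unpaired_t_test",
    "select_evaluation_slices",
    "EvalReport",
]

_STOMACH_RANGE = (20.0, 30.0)
_SMALL_BOWEL_RANGE = (TREITZ_LONGITUDE, ILEOCECAL_LONGITUDE)
_COLON_RANGE = (90.0, 151.0)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def icc_two_way_agreement(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """ICC(A,1): two-way, single measurement, absolute agreement.

    *x* and *y* are the two raters' paired measurements (e.g. manual and
    predicted values over query points).  Returns (icc, F, p) where the F
    statistic MSR/MSE tests the hypothesis of zero correlation.  Absolute
    agreement penalizes systematic bias, so a constant offset lowers the
    ICC below the Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    data = np.stack([x, y], axis=1)  # n subjects x k=2 raters
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
    if mse == 0:  # perfect agreement
        return float(icc), float("inf"), 0.0
    f_stat = msr / mse
    p = float(stats.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
    return float(icc), float(f_stat), p


def roc_auroc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], float]:
    """ROC curve over all thresholds and its area.

    AUROC equals the Mann-Whitney probability that a random positive
    outscores a random negative, ties counted one half.  Rejects label
    vectors containing a single class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = _mann_whitney_auc(scores, labels)
    return (fpr, tpr, thr), auc


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels]
    neg = scores[~labels]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n1, n0 = len(pos), len(neg)
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUROC plus DeLong's structural components V10 (positives) and V01."""
    pos = scores[labels]
    neg = scores[~labels]
    n1, n0 = len(pos), len(neg)
    # midrank formulation: V10_i = P(X_i > Y) + 0.5 P(X_i = Y)
    v10 = np.empty(n1)
    v01 = np.empty(n0)
    for i, s in enumerate(pos):
        v10[i] = (np.sum(s > neg) + 0.5 * np.sum(s == neg)) / n0
    for j, s in enumerate(neg):
        v01[j] = (np.sum(pos > s) + 0.5 * np.sum(pos == s)) / n1
    auc = float(v10.mean())
    return auc, v10, v01


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    auc, v10, v01 = _delong_components(scores, labels)
    n1, n0 = len(v10), len(v01)
    var = np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n0
    return auc, float(var)


def delong_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    labels_b: np.ndarray | None = None,
) -> tuple[float, float]:
    """DeLong z-test comparing two AUROCs; returns (z, p).

    With ``labels_b`` omitted the scores are paired on the same cases and
    the covariance of the structural components enters the variance; with
    ``labels_b`` given the two score sets are independent (e.g. training
    vs. test cohorts) and the variances simply add.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    if labels_b is None:
        if not (scores_a.shape == scores_b.shape == labels.shape):
            raise ValueError("paired variant needs equal-length scores and labels")
        auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
        auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
        n1, n0 = len(v10_a), len(v01_a)
        s10 = np.cov(v10_a, v10_b, ddof=1)
        s01 = np.cov(v01_a, v01_b, ddof=1)
        var = (
            s10[0, 0] / n1
            + s10[1, 1] / n1
            - 2 * s10[0, 1] / n1
            + s01[0, 0] / n0
            + s01[1, 1] / n0
            - 2 * s01[0, 1] / n0
        )
    else:
        labels_b = np.asarray(labels_b).astype(bool)
        if labels_b.all() or not labels_b.any():
            raise ValueError("labels must contain both classes")
        auc_a, var_a = _delong_variance(scores_a, labels)
        auc_b, var_b = _delong_variance(scores_b, labels_b)
        var = var_a + var_b
    if var <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p


def joint_confusion(
    predicted: np.ndarray, measured: np.ndarray
) -> tuple[float | None, float | None, float]:
    """Sensitivity, specificity and McNemar's p for paired binary calls.

    Sensitivity (or specificity) is None when no positives (negatives)
    exist.  McNemar uses the continuity-corrected chi-square on the
    discordant cells, falling back to the exact binomial test when fewer
    than 25 pairs are discordant.
    """
    pred = np.asarray(predicted).astype(bool)
    meas = np.asarray(measured).astype(bool)
    if pred.shape != meas.shape:
        raise ValueError("predicted and measured must have equal length")
    tp = int(np.sum(pred & meas))
    fn = int(np.sum(~pred & meas))
    tn = int(np.sum(~pred & ~meas))
    fp = int(np.sum(pred & ~meas))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    b, c = fp, fn  # discordant cells
    if b + c == 0:
        p = 1.0
    else:
        table = np.array([[tp, fn], [fp, tn]])
        exact = (b + c) < 25
        res = _sm_mcnemar(table, exact=exact, correction=True)
        p = float(res.pvalue)
    return sens, spec, p


def unpaired_t_test(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Welch's two-sample t-test p-value; 1.0 for identical degenerate samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def select_evaluation_slices(
    truth: LabelVolumes, seed: int = 0
) -> tuple[int, int, int]:
    """Pick three random axial slices: stomach, small bowel, colon.

    Slices are drawn (without replacement where possible) from those whose
    truth longitudes intersect each organ-group range; when a group is
    absent, a random slice containing any bowel is substituted, and an
    empty scan draws fully at random.
    """
    rng = np.random.default_rng(seed)
    nz = truth.grid.shape[2]
    lon = truth.longitude
    chosen = []
    any_mask = [int(z) for z in range(nz) if truth.mask[:, :, z].any()]
    for lo, hi in (_STOMACH_RANGE, _SMALL_BOWEL_RANGE, _COLON_RANGE):
        cands = [
            z
            for z in range(nz)
            if np.any((lon[:, :, z] >= lo) & (lon[:, :, z] < hi) & truth.mask[:, :, z])
        ]
        pool = [z for z in (cands or any_mask or list(range(nz))) if z not in chosen]
        if not pool:
            pool = cands or any_mask or list(range(nz))
        chosen.append(int(rng.choice(pool)))
    return tuple(chosen)


def dice_on_slices(
    truth: LabelVolumes, pred: LabelVolumes, slices: tuple[int, ...]
) -> float:
    """Dice between the masks restricted to the designated axial slices."""
    t = np.stack([truth.mask[:, :, z] for z in slices])
    p = np.stack([pred.mask[:, :, z] for z in slices])
    return dice(t, p)


def evaluate_scans(
    scans: list[tuple[LabelVolumes, LabelVolumes, list]],
    seed: int = 0,
) -> tuple["EvalReport", "pd.DataFrame"]:
    """Full statistical evaluation of predicted against reference volumes.

    *scans* is a list of (truth, prediction, query points) triples.  Per
    scan, Dice is computed on the three designated evaluation slices; over
    all query points pooled across scans, predictions are sampled at the
    nearest voxel and the ICC, ROC and joint dilated/nondilated statistics
    are computed.  Returns the report plus the per-point table.
    """
    from .profile import DIAMETER_THRESHOLD_MM, classify_query_point

    rng = np.random.default_rng(seed)
    dices = []
    rows = []
    for truth, pred, qpoints in scans:
        slices = select_evaluation_slices(truth, seed=int(rng.integers(2**31)))
        dices.append(dice_on_slices(truth, pred, slices))
        for q in qpoints:
            cls = classify_query_point(pred, q)
            meas_sb = TREITZ_LONGITUDE < q.presumed_longitude < ILEOCECAL_LONGITUDE
            rows.append(
                {
                    "organ": q.organ,
                    "measured_diameter_mm": q.measured_diameter_mm,
                    "presumed_longitude": q.presumed_longitude,
                    "in_mask": cls["in_mask"],
                    "predicted_diameter_mm": cls["predicted_diameter_mm"],
                    "predicted_longitude": cls["predicted_longitude"],
                    "pred_dilated": cls["dilated_small_bowel"],
                    "pred_nondilated": cls["nondilated_small_bowel"],
                    "meas_dilated": meas_sb
                    and q.measured_diameter_mm > DIAMETER_THRESHOLD_MM,
                    "meas_nondilated": meas_sb
                    and q.measured_diameter_mm < DIAMETER_THRESHOLD_MM,
                }
            )
    table = pd.DataFrame(rows)

    def _safe_auroc(scores, labels):
        try:
            _, auc = roc_auroc(scores, labels)
            return auc
        except ValueError:
            return float("nan")

    icc_d = icc_two_way_agreement(
        table.measured_diameter_mm.to_numpy(), table.predicted_diameter_mm.to_numpy()
    )
    icc_l = icc_two_way_agreement(
        table.presumed_longitude.to_numpy(), table.predicted_longitude.to_numpy()
    )
    auc_d = _safe_auroc(
        table.predicted_diameter_mm.to_numpy(),
        table.measured_diameter_mm.to_numpy() > DIAMETER_THRESHOLD_MM,
    )
    # higher score must mean "positive": negate predictions for the < 40 task
    auc_l40 = _safe_auroc(
        -table.predicted_longitude.to_numpy(),
        table.presumed_longitude.to_numpy() < TREITZ_LONGITUDE,
    )
    auc_l80 = _safe_auroc(
        table.predicted_longitude.to_numpy(),
        table.presumed_longitude.to_numpy() > ILEOCECAL_LONGITUDE,
    )
    sens_d, spec_d, p_d = joint_confusion(
        table.pred_dilated.to_numpy(), table.meas_dilated.to_numpy()
    )
    sens_n, spec_n, p_n = joint_confusion(
        table.pred_nondilated.to_numpy(), table.meas_nondilated.to_numpy()
    )
    report = EvalReport(
        dice_per_scan=[float(d) for d in dices],
        dice_mean=float(np.mean(dices)),
        dice_sd=float(np.std(dices, ddof=1)) if len(dices) > 1 else 0.0,
        icc_diameter=icc_d,
        icc_longitude=icc_l,
        auroc_diameter=auc_d,
        auroc_longitude_below_40=auc_l40,
        auroc_longitude_above_80=auc_l80,
        dilated={"sensitivity": sens_d, "specificity": spec_d, "mcnemar_p": p_d},
        nondilated={"sensitivity": sens_n, "specificity": spec_n, "mcnemar_p": p_n},
        n_query_points=len(table),
    )
    return report, table


@dataclass
class EvalReport:
    """All statistics for one data set, JSON-serializable."""

    dice_per_scan: list[float]
    dice_mean: float
    dice_sd: float
    icc_diameter: tuple[float, float, float]  # (icc, F, p)
    icc_longitude: tuple[float, float, float]
    auroc_diameter: float
    auroc_longitude_below_40: float
    auroc_longitude_above_80: float
    dilated: dict  # sensitivity, specificity, mcnemar_p
    nondilated: dict
    n_query_points: int

    def to_dict(self) -> dict:
        return {
            "dice": {
                "per_scan": self.dice_per_scan,
                "mean": self.dice_mean,
                "sd": self.dice_sd,
            },
            "icc": {
                "diameter": dict(zip(("icc", "F", "p"), self.icc_diameter)),
                "longitude": dict(zip(("icc", "F", "p"), self.icc_longitude)),
            },
            "auroc": {
                "diameter_gt_30mm": self.auroc_diameter,
                "longitude_lt_40": self.auroc_longitude_below_40,
                "longitude_gt_80": self.auroc_longitude_above_80,
            },
            "joint": {"dilated": self.dilated, "nondilated": self.nondilated},
            "n_query_points": self.n_query_points,
        }
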