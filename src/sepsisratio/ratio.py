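"""Up/down expression-ratio score and its discrimination of ICU mortality.

The score is the linear-scale ratio of an up-regulated marker to a
down-regulated marker, 2^(log2_up - log2_down) on array data or the ratio
of calibrated relative quantities on qPCR data. Because any per-sample
offset common to both genes cancels, the ratio needs no normalization
genes. Discrimination is summarized by the AUROC (non-survivors expected
to score higher), a stratified-bootstrap percentile CI, the Youden optimal
threshold and its operating characteristics, and the DeLong test for
comparing correlated AUROCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import NONSURVIVOR


class ClassError(ValueError):
    """Both outcome classes must be present."""


def _binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        y = (arr == NONSURVIVOR).astype(int)
        if y.sum() == 0 and np.isin(arr, ("0", "1")).all():
            y = arr.astype(int)
    else:
        y = arr.astype(int)
    if y.min() == y.max():
        raise ClassError("need both survivors and non-survivors")
    return y


def ratio_score(log2_up, log2_down) -> np.ndarray:
    """Linear expression ratio 2^(log2_up - log2_down)."""
    return np.asarray(2.0 ** (np.asarray(log2_up, float) - np.asarray(log2_down, float)))


def auroc(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formula.

    Equals the probability that a random non-survivor outscores a random
    survivor, ties counted half.
    """
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(s)
    n1 = int(y.sum())
    n0 = len(y) - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def bootstrap_ci(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUROC, resampling within each class."""
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos, neg = s[y == 1], s[y == 0]
    n1, n0 = len(pos), len(neg)
    aucs = np.empty(n_boot)
    lab = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
    for i in range(n_boot):
        sample = np.concatenate(
            [pos[rng.integers(0, n1, n1)], neg[rng.integers(0, n0, n0)]]
        )
        aucs[i] = auroc(sample, lab)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _delong_structural(scores: np.ndarray, y: np.ndarray):
    """Placement values (structural components) of the AUROC estimator."""
    pos, neg = scores[y == 1], scores[y == 0]
    n1, n0 = len(pos), len(neg)
    # V10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i), likewise V01 per negative
    v10 = np.empty(n1)
    for i, x in enumerate(pos):
        v10[i] = ((neg < x).sum() + 0.5 * (neg == x).sum()) / n0
    v01 = np.empty(n0)
    for j, x in enumerate(neg):
        v01[j] = ((pos > x).sum() + 0.5 * (pos == x).sum()) / n1
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong z-test comparing two correlated AUROCs on the same samples.

    Returns (z, two-sided p) for AUROC(a) - AUROC(b). Identical score
    vectors give z = 0, p = 1.
    """
    y = _binary_labels(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or len(a) != len(y):
        raise ValueError("scores_a, scores_b and labels must be equal length")
    v10a, v01a = _delong_structural(a, y)
    v10b, v01b = _delong_structural(b, y)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    n1, n0 = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    )
    if var <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def youden_threshold(scores, labels) -> tuple[float, float, float]:
    """Operating threshold maximizing J = sensitivity + specificity - 1.

    Candidate cuts are midpoints between consecutive sorted unique scores
    plus outer sentinels; the rule is score >= threshold => non-survivor;
    ties in J resolve to the smallest threshold. Returns
    (threshold, sensitivity, specificity).
    """
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cuts = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best = (-np.inf, np.nan, np.nan, np.nan)
    n1 = y.sum()
    n0 = len(y) - n1
    for c in cuts:
        pred = s >= c
        sens = (pred & (y == 1)).sum() / n1
        spec = (~pred & (y == 0)).sum() / n0
        j = sens + spec - 1.0
        if j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    _, thr, sens, spec = best
    return float(thr), float(sens), float(spec)


def operating_characteristics(
    scores, labels, threshold: float
) -> dict[str, float]:
    """Sensitivity, specificity, PPV and NPV of the score >= threshold rule."""
    y = _binary_labels(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "ppv": tp / (tp + fp) if tp + fp else np.nan,
        "npv": tn / (tn + fn) if tn + fn else np.nan,
    }


@dataclass
class RatioScoreResult:
    """Ratio-score evaluation at one timepoint."""

    up_gene: str
    down_gene: str
    timepoint: str
    scores: pd.Series  # per-sample linear ratio
    labels: pd.Series
    auroc: float
    ci_lo: float
    ci_hi: float
    n_bootstrap: int
    youden_threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def evaluate_ratio(
    log2_up: pd.Series,
    log2_down: pd.Series,
    labels: pd.Series,
    up_gene: str = "",
    down_gene: str = "",
    timepoint: str = "",
    n_boot: int = 2000,
    seed: int = 0,
    threshold: float | None = None,
) -> RatioScoreResult:
    """Score samples with the up/down ratio and evaluate discrimination.

    With ``threshold=None`` the Youden optimum is computed from these data
    (discovery / platform-transfer behaviour); passing a frozen threshold
    evaluates an externally fixed operating point (validation behaviour).
    """
    scores = pd.Series(
        ratio_score(log2_up.to_numpy(), log2_down.to_numpy()), index=log2_up.index
    )
    auc = auroc(scores.to_numpy(), labels.to_numpy())
    lo, hi = bootstrap_ci(scores.to_numpy(), labels.to_numpy(), n_boot=n_boot, seed=seed)
    if threshold is None:
        thr, _, _ = youden_threshold(scores.to_numpy(), labels.to_numpy())
    else:
        thr = float(threshold)
    oc = operating_characteristics(scores.to_numpy(), labels.to_numpy(), thr)
    return RatioScoreResult(
        up_gene=up_gene,
        down_gene=down_gene,
        timepoint=timepoint,
        scores=scores,
        labels=pd.Series(labels, index=log2_up.index),
        auroc=auc,
        ci_lo=lo,
        ci_hi=hi,
        n_bootstrap=n_boot,
        youden_threshold=thr,
        sensitivity=oc["sensitivity"],
        specificity=oc["specificity"],
        ppv=oc["ppv"],
        npv=oc["npv"],
    )
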