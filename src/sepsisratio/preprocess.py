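"""Gene-level normalization and cross-batch adjustment.

Two steps stand between raw log2 expression and differential testing:
quantile normalization (forcing every sample to a common empirical
distribution) and a location/scale empirical-Bayes batch adjustment of the
ComBat family, which standardizes each gene, estimates per-batch additive
(gamma) and multiplicative (delta) effects, shrinks them toward priors
fitted across genes, and removes the shrunken effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class InputError(ValueError):
    pass


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean empirical distribution.

    After normalization every column holds the same multiset of values: the
    per-rank means across columns. Tied values within a column receive the
    mean of the reference values at their tied ranks, and within-column rank
    order is preserved.
    """
    if matrix.size == 0:
        raise InputError("cannot quantile-normalize an empty matrix")
    if matrix.isna().any().any():
        raise InputError("matrix contains missing values")
    x = matrix.to_numpy(dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, x.shape[0] + 1), ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class BatchModel:
    """Fitted batch-adjustment parameters (one row per batch, column per gene)."""

    batches: list[str]
    gamma_star: pd.DataFrame  # shrunken additive effects, standardized units
    delta_star: pd.DataFrame  # shrunken scale effects (variance ratios), > 0
    grand_mean: pd.Series
    pooled_var: pd.Series
    gamma_prior_mean: pd.Series  # per-batch normal-prior mean for gamma
    gamma_prior_var: pd.Series  # per-batch normal-prior variance
    delta_prior_shape: pd.Series  # per-batch inverse-gamma shape (lambda)
    delta_prior_scale: pd.Series  # per-batch inverse-gamma scale (theta)


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(ssq, n, a, b):
    return (0.5 * ssq + b) / (n / 2.0 + a - 1.0)


def _it_sol(z_batch, g_hat, d_hat, g_bar, t2, a, b, conv=1e-8):
    """Iterate the coupled posterior equations for (gamma*, delta*²)."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        ssq = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(ssq, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
            np.abs(d_new - d_old).max() / max(np.abs(d_old).max(), 1e-12),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_adjust(
    matrix: pd.DataFrame,
    batch_labels: pd.Series | list,
    covariates: pd.DataFrame | pd.Series | None = None,
    shrink: bool = True,
) -> tuple[pd.DataFrame, BatchModel]:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per gene: standardize against the sample-size-weighted grand mean and the
    pooled residual variance; estimate each batch's mean (gamma_hat) and
    variance (delta_hat) on the standardized scale; shrink gamma toward a
    normal prior and delta toward an inverse-gamma prior, both fitted across
    genes by method of moments; subtract/divide the shrunken effects and
    restore the grand location and scale.

    Parameters
    ----------
    covariates : optional design columns (e.g. outcome) whose effects are
        estimated jointly with batch, removed before standardization and
        restored afterwards, protecting them from the adjustment.
    shrink : with ``False`` the raw per-batch estimates are used (plain
        location/scale adjustment, no empirical-Bayes pooling); this mode
        removes a pure per-gene location shift exactly and is idempotent.
    """
    batch = pd.Series(
        np.asarray(batch_labels, dtype=object), index=matrix.columns, name="batch"
    )
    levels = list(pd.unique(batch))
    counts = batch.value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise InputError(f"each batch needs >= 2 samples; too small: {small}")
    if len(levels) == 1:
        warnings.warn("single batch: adjustment is the identity", stacklevel=2)
        model = BatchModel(
            batches=levels,
            gamma_star=pd.DataFrame(0.0, index=levels, columns=matrix.index),
            delta_star=pd.DataFrame(1.0, index=levels, columns=matrix.index),
            grand_mean=matrix.mean(axis=1),
            pooled_var=matrix.var(axis=1, ddof=0),
            gamma_prior_mean=pd.Series(0.0, index=levels),
            gamma_prior_var=pd.Series(1.0, index=levels),
            delta_prior_shape=pd.Series(np.nan, index=levels),
            delta_prior_scale=pd.Series(np.nan, index=levels),
        )
        return matrix.copy(), model

    y = matrix.to_numpy(dtype=float)
    n_genes, n_samples = y.shape
    design_cols = [(batch == b).to_numpy(float) for b in levels]
    n_batch_cols = len(design_cols)
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        cov = cov.loc[matrix.columns]
        cov_num = pd.get_dummies(cov, drop_first=True).to_numpy(float)
        design = np.column_stack(design_cols + [cov_num])
    else:
        design = np.column_stack(design_cols)

    beta_hat, *_ = np.linalg.lstsq(design, y.T, rcond=None)  # (p, genes)
    sizes = np.array([counts[b] for b in levels], dtype=float)
    grand = (sizes / n_samples) @ beta_hat[:n_batch_cols]  # (genes,)
    fitted = design @ beta_hat
    pooled = ((y.T - fitted) ** 2).mean(axis=0)  # per gene, ddof=0
    pooled = np.maximum(pooled, 1e-18)

    stand_mean = np.tile(grand[:, None], (1, n_samples))
    if covariates is not None:
        cov_design = design.copy()
        cov_design[:, :n_batch_cols] = 0.0
        stand_mean += (cov_design @ beta_hat).T
    z = (y - stand_mean) / np.sqrt(pooled)[:, None]

    gamma_star = np.empty((len(levels), n_genes))
    delta_star = np.empty((len(levels), n_genes))
    g_bar = np.empty(len(levels))
    t2 = np.empty(len(levels))
    a_pr = np.empty(len(levels))
    b_pr = np.empty(len(levels))
    for i, b in enumerate(levels):
        cols = (batch == b).to_numpy()
        zb = z[:, cols]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar[i], t2[i] = g_hat.mean(), g_hat.var(ddof=0)
        a_pr[i], b_pr[i] = _aprior(d_hat), _bprior(d_hat)
        if shrink:
            gamma_star[i], delta_star[i] = _it_sol(
                zb, g_hat, d_hat, g_bar[i], t2[i], a_pr[i], b_pr[i]
            )
        else:
            # raw estimates; ddof=0 scale makes this mode exactly idempotent
            gamma_star[i], delta_star[i] = g_hat, zb.var(axis=1, ddof=0)

    adjusted = z.copy()
    for i, b in enumerate(levels):
        cols = (batch == b).to_numpy()
        adjusted[:, cols] = (
            (z[:, cols] - gamma_star[i][:, None]) / np.sqrt(delta_star[i])[:, None]
        )
    adjusted = adjusted * np.sqrt(pooled)[:, None] + stand_mean

    model = BatchModel(
        batches=[str(b) for b in levels],
        gamma_star=pd.DataFrame(gamma_star, index=levels, columns=matrix.index),
        delta_star=pd.DataFrame(delta_star, index=levels, columns=matrix.index),
        grand_mean=pd.Series(grand, index=matrix.index),
        pooled_var=pd.Series(pooled, index=matrix.index),
        gamma_prior_mean=pd.Series(g_bar, index=levels),
        gamma_prior_var=pd.Series(t2, index=levels),
        delta_prior_shape=pd.Series(a_pr, index=levels),
        delta_prior_scale=pd.Series(b_pr, index=levels),
    )
    return pd.DataFrame(adjusted, index=matrix.index, columns=matrix.columns), model


def batch_f_statistics(matrix: pd.DataFrame, batch_labels: pd.Series | list) -> pd.Series:
    """Per-gene one-way ANOVA F statistic across batches (batch-signal gauge)."""
    batch = np.asarray(batch_labels, dtype=object)
    levels = pd.unique(batch)
    x = matrix.to_numpy(dtype=float)
    n = x.shape[1]
    grand = x.mean(axis=1, keepdims=True)
    ss_between = np.zeros(x.shape[0])
    ss_within = np.zeros(x.shape[0])
    for b in levels:
        cols = batch == b
        xb = x[:, cols]
        mb = xb.mean(axis=1, keepdims=True)
        ss_between += cols.sum() * (mb[:, 0] - grand[:, 0]) ** 2
        ss_within += ((xb - mb) ** 2).sum(axis=1)
    df_b, df_w = len(levels) - 1, n - len(levels)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    return pd.Series(f, index=matrix.index)
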