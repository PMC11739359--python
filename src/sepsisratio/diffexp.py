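"""Moderated two-group differential expression, per timepoint.

Implements the empirical-Bayes moderated t workflow for a survivor vs
non-survivor comparison on a log2 expression matrix: gene-wise pooled
variances are shrunk toward a common prior fitted across genes (scaled
inverse-chi-square, hyperparameters d0 and s0² estimated by method of
moments on log sample variances), the t statistic uses the posterior
variance on d0 + d_g degrees of freedom, and the B statistic is the log
posterior odds of differential expression at a prior DE proportion p_DE.

log2 fold change is always the raw difference of group means
(non-survivors minus survivors); only the variance is moderated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .synthetic import NONSURVIVOR, SURVIVOR, ExpressionCohort

#: variance floor for degenerate (constant) genes
VAR_FLOOR = 1e-12


class GroupSizeError(ValueError):
    pass


@dataclass
class DEGTable:
    """Per-gene differential-expression statistics for one timepoint."""

    table: pd.DataFrame  # log2_fc, t, p, q, b, posterior_prob, s2_gene, s2_post
    timepoint: str
    df_residual: float
    df_prior: float
    s2_prior: float
    var_prior: float  # prior variance of the (standardized) effect for DE genes
    p_de: float

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the log scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0²) to sample variances on the log scale.

    Models s²_g ~ s0² · F(df, d0). Returns (d0, s0²); d0 = inf when the
    observed spread of log s² is no larger than the sampling spread alone.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), VAR_FLOOR)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = (np.square(e - e_mean)).sum() / (len(e) - 1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        # spread of log s² no larger than pure sampling noise: variances are
        # effectively common, prior df infinite, scale the arithmetic mean
        return np.inf, float(s2.mean())
    d0 = 2.0 * trigamma_inverse(excess)
    s0_2 = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_2)


def _tmixture(
    t: np.ndarray,
    v_unscaled: float,
    df: float,
    proportion: float,
    v0_lim: tuple[float, float] = (0.01, 16.0),
) -> float:
    """Estimate the prior variance of the effect for DE genes.

    Top-proportion method: take the ceil(p/2·m) largest |t| values, convert
    each rank's expected null tail probability into a target t quantile, and
    back out the implied effect variance; the estimate is the mean of the
    per-gene values (floored at zero).
    """
    m = len(t)
    ntarget = int(np.ceil(proportion / 2.0 * m))
    if ntarget < 1:
        return np.nan
    p = max(ntarget / m, proportion)
    tstat = np.sort(np.abs(t))[::-1][:ntarget]
    r = np.arange(1, ntarget + 1)
    p0 = 2.0 * stats.t.sf(tstat, df)
    ptarget = ((r - 0.5) / m - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.isf(ptarget[pos] / 2.0, df)
        v0[pos] = v_unscaled * ((tstat[pos] / qtarget) ** 2 - 1.0)
    v0 = np.clip(v0, *v0_lim)  # effect-variance limits keep the prior proper
    return float(v0.mean())


def b_statistic(
    t: np.ndarray,
    df_total: float,
    v_unscaled: float,
    var_prior: float,
    p_de: float,
) -> np.ndarray:
    """Log posterior odds of differential expression for moderated t values."""
    r = (v_unscaled + var_prior) / v_unscaled
    t2 = np.square(t)
    if np.isfinite(df_total):
        kernel = (1.0 + df_total) / 2.0 * np.log((t2 + df_total) / (t2 / r + df_total))
    else:
        kernel = t2 * (1.0 - 1.0 / r) / 2.0
    return np.log(p_de / (1.0 - p_de)) - 0.5 * np.log(r) + kernel


def fit_group_comparison(
    cohort: ExpressionCohort,
    timepoint: str,
    p_de: float = 0.01,
) -> DEGTable:
    """Survivor vs non-survivor moderated comparison at one timepoint.

    Requires at least two samples per outcome group at the timepoint. With
    the prior df forced to zero the statistic reduces to the ordinary
    pooled-variance two-sample t.
    """
    sub = cohort.subset_timepoint(timepoint)
    outcome = sub.meta["outcome"]
    dead = (outcome == NONSURVIVOR).to_numpy()
    alive = (outcome == SURVIVOR).to_numpy()
    n1, n0 = int(dead.sum()), int(alive.sum())
    if n1 < 2 or n0 < 2:
        raise GroupSizeError(
            f"need >= 2 samples per outcome group at {timepoint}; "
            f"got {n1} non-survivors, {n0} survivors"
        )
    x = sub.matrix.to_numpy(dtype=float)
    m_dead = x[:, dead].mean(axis=1)
    m_alive = x[:, alive].mean(axis=1)
    log2_fc = m_dead - m_alive

    ss = ((x[:, dead] - m_dead[:, None]) ** 2).sum(axis=1) + (
        (x[:, alive] - m_alive[:, None]) ** 2
    ).sum(axis=1)
    df_g = n1 + n0 - 2
    s2_g = ss / df_g
    if (s2_g < VAR_FLOOR).any():
        warnings.warn(
            f"{int((s2_g < VAR_FLOOR).sum())} zero-variance genes floored at {VAR_FLOOR}",
            stacklevel=2,
        )
        s2_g = np.maximum(s2_g, VAR_FLOOR)

    d0, s0_2 = fit_f_dist(s2_g, df_g)
    if np.isfinite(d0):
        s2_post = (d0 * s0_2 + df_g * s2_g) / (d0 + df_g)
        df_total = min(d0 + df_g, len(s2_g) * df_g)
    else:
        s2_post = np.full_like(s2_g, s0_2)
        df_total = len(s2_g) * df_g

    v_unscaled = 1.0 / n1 + 1.0 / n0
    t = log2_fc / np.sqrt(s2_post * v_unscaled)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    # effect-variance search limits on the standardized scale (0.1..4 sd of
    # coefficient, relative to the prior residual variance)
    v0_lim = (0.01 / s0_2, 16.0 / s0_2)
    var_prior = _tmixture(t, v_unscaled, df_total, p_de, v0_lim=v0_lim)
    # with an (effectively) infinite prior df the moderated t is a z-statistic
    # and the log-odds kernel takes its normal-limit form
    b_df = np.inf if d0 > 1e6 else df_total
    b = b_statistic(t, b_df, v_unscaled, var_prior, p_de)
    posterior = special.expit(b)

    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "t": t,
            "p": p,
            "q": q,
            "b": b,
            "posterior_prob": posterior,
            "s2_gene": s2_g,
            "s2_post": s2_post,
        },
        index=sub.matrix.index,
    )
    return DEGTable(
        table=table,
        timepoint=timepoint,
        df_residual=float(df_g),
        df_prior=float(d0),
        s2_prior=float(s0_2),
        var_prior=float(var_prior),
        p_de=p_de,
    )


def ordinary_t_table(cohort: ExpressionCohort, timepoint: str) -> pd.DataFrame:
    """Unmoderated pooled two-sample t per gene (the d0 -> 0 limit)."""
    fit = fit_group_comparison(cohort, timepoint)
    sub = cohort.subset_timepoint(timepoint)
    dead = (sub.meta["outcome"] == NONSURVIVOR).sum()
    alive = (sub.meta["outcome"] == SURVIVOR).sum()
    v = 1.0 / dead + 1.0 / alive
    t = fit["log2_fc"] / np.sqrt(fit["s2_gene"] * v)
    p = 2.0 * stats.t.sf(np.abs(t), fit.df_residual)
    return pd.DataFrame({"log2_fc": fit["log2_fc"], "t": t, "p": p})


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
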