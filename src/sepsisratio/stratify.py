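"""Lactate x ratio risk stratification, group mortality, KM and log-rank.

Patients are classified by two inclusive cutoffs — admission lactate
>= 2 mmol/L and expression ratio >= 0.47: both above gives high risk, both
below low risk, discordant combinations the intermediate group. Group
mortality is tabulated with a chi-square association test, and ICU
survival (censored at day 30) is compared with Kaplan-Meier curves and
log-rank tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

LOW, INTERMEDIATE, HIGH = "low", "intermediate", "high"
GROUP_ORDER = [LOW, INTERMEDIATE, HIGH]


@dataclass(frozen=True)
class RiskRule:
    """Inclusive decision cutoffs for the two biomarkers."""

    lactate_cutoff: float = 2.0  # mmol/L
    ratio_cutoff: float = 0.47

    def __post_init__(self) -> None:
        if self.lactate_cutoff <= 0 or self.ratio_cutoff <= 0:
            raise ValueError("cutoffs must be > 0")


def classify(lactate: float, ratio: float, rule: RiskRule = RiskRule()) -> str | None:
    """Assign one patient to low/intermediate/high risk; None if lactate missing."""
    if lactate is None or (isinstance(lactate, float) and math.isnan(lactate)):
        return None
    hi_l = lactate >= rule.lactate_cutoff
    hi_r = ratio >= rule.ratio_cutoff
    if hi_l and hi_r:
        return HIGH
    if not hi_l and not hi_r:
        return LOW
    return INTERMEDIATE


def classify_patients(
    lactate: pd.Series, ratio: pd.Series, rule: RiskRule = RiskRule()
) -> pd.Series:
    """Vectorized ``classify`` over aligned patient series; NaN lactate dropped."""
    common = lactate.index.intersection(ratio.index)
    out = {}
    for pid in common:
        g = classify(float(lactate[pid]), float(ratio[pid]), rule)
        if g is not None:
            out[pid] = g
    return pd.Series(out, name="risk_group")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def group_mortality(
    groups: pd.Series, outcomes: pd.Series
) -> pd.DataFrame:
    """Per-group n, deaths and mortality percent, plus an association test.

    ``outcomes`` is boolean (True = ICU death) or the survivor/nonsurvivor
    labels, aligned with ``groups``. Percentages are rounded half away from
    zero. The headline p-value is the Pearson chi-square on the group x
    outcome table; when any expected count is below 5 an exact p is also
    computed (Fisher for 2x2, Monte-Carlo chi-square otherwise) and flagged.
    Attributes ``chi2``, ``chi2_p``, ``exact_p`` and ``small_expected`` are
    attached to the returned frame's ``attrs``.
    """
    if groups.empty:
        raise ValueError("no classified patients")
    y = outcomes.loc[groups.index]
    if y.dtype == object:
        y = y == "nonsurvivor"
    y = y.astype(bool)

    present = [g for g in GROUP_ORDER if (groups == g).any()]
    rows = []
    for g in GROUP_ORDER:
        mask = groups == g
        n = int(mask.sum())
        deaths = int(y[mask].sum())
        rows.append(
            {
                "group": g,
                "n": n,
                "deaths": deaths,
                "mortality_percent": _round_half_away(100.0 * deaths / n) if n else None,
            }
        )
    table = pd.DataFrame(rows).set_index("group")

    cont = np.array(
        [
            [int(y[groups == g].sum()), int((~y[groups == g]).sum())]
            for g in present
        ]
    )
    chi2, chi2_p, dof, expected = stats.chi2_contingency(cont, correction=False)
    small = bool((expected < 5).any())
    exact_p = None
    if small:
        if cont.shape == (2, 2):
            exact_p = float(stats.fisher_exact(cont)[1])
        else:
            # Monte-Carlo chi-square: permute outcomes, seeded for determinism
            rng = np.random.default_rng(0)
            obs = chi2
            yv = y.loc[groups.index].to_numpy()
            gv = groups.to_numpy()
            count = 0
            n_mc = 10000
            for _ in range(n_mc):
                perm = rng.permutation(yv)
                c = np.array(
                    [
                        [int(perm[gv == g].sum()), int((~perm[gv == g]).sum())]
                        for g in present
                    ]
                )
                stat = stats.chi2_contingency(c, correction=False)[0]
                if stat >= obs - 1e-12:
                    count += 1
            exact_p = (count + 1) / (n_mc + 1)
    table.attrs.update(
        chi2=float(chi2), chi2_p=float(chi2_p), df=int(dof),
        small_expected=small, exact_p=exact_p,
    )
    return table


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve.

    Returns a frame indexed by event time with columns ``at_risk``,
    ``deaths``, ``censored`` and ``survival`` (right-continuous step values
    after each time).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise ValueError("empty survival input")
    if (t <= 0).any():
        raise ValueError("survival times must be > 0")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    s = 1.0
    rows = []
    for ti in np.unique(t):
        at_risk = int((t >= ti).sum())
        deaths = int(e[t == ti].sum())
        censored = int((~e[t == ti]).sum())
        if deaths > 0:
            s *= 1.0 - deaths / at_risk
        rows.append(
            {"time": ti, "at_risk": at_risk, "deaths": deaths,
             "censored": censored, "survival": s}
        )
    return pd.DataFrame(rows).set_index("time")


def logrank_test(group_times: dict, group_events: dict) -> tuple[float, int, float]:
    """K-sample log-rank chi-square test.

    ``group_times`` / ``group_events`` map group label -> arrays. Returns
    (chi2, df, p) with df = groups - 1, using the standard observed-minus-
    expected statistic with the hypergeometric variance.
    """
    labels = list(group_times)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    t = np.concatenate([np.asarray(group_times[g], float) for g in labels])
    e = np.concatenate([np.asarray(group_events[g], bool) for g in labels])
    gidx = np.concatenate(
        [np.full(len(group_times[g]), i) for i, g in enumerate(labels)]
    )
    if not e.any():
        raise ValueError("log-rank test needs at least one event")
    k = len(labels)
    event_times = np.unique(t[e])
    o_minus_e = np.zeros(k)
    var = np.zeros((k, k))
    for ti in event_times:
        at_risk = t >= ti
        n_i = at_risk.sum()
        d_i = (e & (t == ti)).sum()
        n_ig = np.array([(at_risk & (gidx == g)).sum() for g in range(k)])
        d_ig = np.array([((e) & (t == ti) & (gidx == g)).sum() for g in range(k)])
        exp_g = d_i * n_ig / n_i
        o_minus_e += d_ig - exp_g
        if n_i > 1:
            frac = n_ig / n_i
            v = (
                d_i
                * (n_i - d_i)
                / (n_i - 1)
                * (np.diag(frac) - np.outer(frac, frac))
            )
            var += v
    u = o_minus_e[:-1]
    v_sub = var[:-1, :-1]
    chi2 = float(u @ np.linalg.pinv(v_sub) @ u)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def pairwise_logrank(group_times: dict, group_events: dict) -> pd.DataFrame:
    """Unadjusted pairwise log-rank p-values for every group pair."""
    rows = []
    for a, b in combinations(group_times, 2):
        chi2, _, p = logrank_test(
            {a: group_times[a], b: group_times[b]},
            {a: group_events[a], b: group_events[b]},
        )
        rows.append({"group_a": a, "group_b": b, "chi2": chi2, "p": p})
    return pd.DataFrame(rows)


@dataclass
class RiskGroupResult:
    """Full risk-stratification output for one timepoint."""

    assignments: pd.Series  # patient -> low/intermediate/high
    mortality: pd.DataFrame  # group_mortality table (attrs carry the test)
    km_curves: dict[str, pd.DataFrame]
    overall_logrank: tuple[float, int, float]
    pairwise: pd.DataFrame
    rule: RiskRule = field(default_factory=RiskRule)
    timepoint: str = ""


def stratify_cohort(
    patients: pd.DataFrame,
    ratio: pd.Series,
    rule: RiskRule = RiskRule(),
    censor_day: float = 30.0,
    timepoint: str = "",
) -> RiskGroupResult:
    """Classify patients and run the mortality / survival comparisons.

    ``patients`` is a per-patient frame with columns ``lactate``,
    ``outcome``, ``survival_time`` and ``event``; ``ratio`` is the
    per-patient biomarker score. Patients without lactate or ratio are
    excluded. Follow-up is truncated at ``censor_day``.
    """
    groups = classify_patients(patients["lactate"], ratio, rule)
    sub = patients.loc[groups.index]
    times = np.minimum(sub["survival_time"].to_numpy(float), censor_day)
    events = sub["event"].to_numpy(bool) & (
        sub["survival_time"].to_numpy(float) <= censor_day
    )
    mortality = group_mortality(groups, sub["outcome"])
    gt = {
        g: times[(groups == g).to_numpy()]
        for g in GROUP_ORDER
        if (groups == g).any()
    }
    ge = {
        g: events[(groups == g).to_numpy()]
        for g in GROUP_ORDER
        if (groups == g).any()
    }
    km = {g: km_estimate(gt[g], ge[g]) for g in gt}
    overall = logrank_test(gt, ge)
    pw = pairwise_logrank(gt, ge)
    return RiskGroupResult(
        assignments=groups,
        mortality=mortality,
        km_curves=km,
        overall_logrank=overall,
        pairwise=pw,
        rule=rule,
        timepoint=timepoint,
    )
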