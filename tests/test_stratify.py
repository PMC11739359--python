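"""Risk classification, group mortality, KM estimator and log-rank tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sepsisratio.stratify import (
    GROUP_ORDER,
    RiskRule,
    classify,
    classify_patients,
    group_mortality,
    km_estimate,
    logrank_test,
    pairwise_logrank,
    stratify_cohort,
)

RULE = RiskRule(lactate_cutoff=2.0, ratio_cutoff=0.47)


class TestClassify:
    @pytest.mark.parametrize(
        "lactate, ratio, expected",
        [
            (3.0, 0.60, "high"),
            (1.0, 0.20, "low"),
            (3.0, 0.20, "intermediate"),
            (1.0, 0.60, "intermediate"),
            (2.0, 0.47, "high"),  # inclusive boundary on both cutoffs
            (2.0, 0.40, "intermediate"),
            (1.99, 0.47, "intermediate"),
        ],
    )
    def test_decision_table(self, lactate, ratio, expected):
        assert classify(lactate, ratio, RULE) == expected

    def test_missing_lactate_excluded_not_crash(self):
        assert classify(float("nan"), 0.6, RULE) is None
        lact = pd.Series({"P1": np.nan, "P2": 3.0})
        ratio = pd.Series({"P1": 0.6, "P2": 0.6})
        groups = classify_patients(lact, ratio, RULE)
        assert list(groups.index) == ["P2"]

    @given(
        st.floats(0.1, 10),
        st.floats(0.01, 5),
        st.floats(0, 5),
        st.floats(0, 2),
    )
    def test_monotone_in_both_biomarkers(self, lactate, ratio, dl, dr):
        order = {g: i for i, g in enumerate(GROUP_ORDER)}
        base = classify(lactate, ratio, RULE)
        worse = classify(lactate + dl, ratio + dr, RULE)
        assert order[worse] >= order[base]

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            RiskRule(lactate_cutoff=0.0)


class TestGroupMortality:
    def test_three_group_mortality_table(self):
        # three-tier classification: 59/22/12 patients with 11/6/8 deaths
        groups, outcomes = [], []
        for g, n, d in (("low", 59, 11), ("intermediate", 22, 6), ("high", 12, 8)):
            groups += [g] * n
            outcomes += [True] * d + [False] * (n - d)
        idx = [f"P{i}" for i in range(len(groups))]
        table = group_mortality(pd.Series(groups, idx), pd.Series(outcomes, idx))
        assert table.loc["low", "mortality_percent"] == 19
        assert table.loc["intermediate", "mortality_percent"] == 27
        assert table.loc["high", "mortality_percent"] == 67
        assert table.attrs["chi2_p"] == pytest.approx(0.003, abs=5e-4)
        # high-risk expected deaths < 5 triggers the exact companion p
        assert table.attrs["small_expected"]
        assert table.attrs["exact_p"] is not None

    def test_single_group_all_survivors(self):
        idx = ["a", "b", "c"]
        with pytest.raises(Exception):
            # chi-square needs >= 2 groups represented
            group_mortality(pd.Series(["low"] * 3, idx), pd.Series([False] * 3, idx))

    def test_identical_rates_give_p_near_one(self):
        groups = ["low"] * 40 + ["high"] * 40
        outcomes = ([True] * 10 + [False] * 30) * 2
        idx = [f"P{i}" for i in range(80)]
        table = group_mortality(pd.Series(groups, idx), pd.Series(outcomes, idx))
        assert table.attrs["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert table.attrs["chi2_p"] == pytest.approx(1.0, abs=1e-9)

    def test_group_sizes_partition_classified_patients(self):
        rng = np.random.default_rng(0)
        n = 100
        idx = [f"P{i}" for i in range(n)]
        groups = pd.Series(rng.choice(GROUP_ORDER, n), idx)
        outcomes = pd.Series(rng.uniform(size=n) < 0.3, idx)
        table = group_mortality(groups, outcomes)
        assert table["n"].sum() == n
        assert table["deaths"].sum() == outcomes.sum()


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survival(self):
        km = km_estimate([1, 2, 3], [True, True, True])
        np.testing.assert_allclose(km["survival"], [2 / 3, 1 / 3, 0.0])
        assert list(km["at_risk"]) == [3, 2, 1]

    def test_all_censored_flat_one(self):
        km = km_estimate([5, 10, 30], [False, False, False])
        np.testing.assert_allclose(km["survival"], 1.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        times = rng.exponential(10, 10).round(1) + 0.1
        events = rng.uniform(size=10) < 0.6
        km = km_estimate(times, events)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        ref = kmf.survival_function_["KM_estimate"]
        for t, row in km.iterrows():
            assert row["survival"] == pytest.approx(ref.loc[t], abs=1e-10)


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = [1, 2, 3, 4, 5]
        e = [True, True, False, True, False]
        chi2, df, p = logrank_test({"a": t, "b": t}, {"a": e, "b": e})
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_needs_two_groups_and_events(self):
        with pytest.raises(ValueError):
            logrank_test({"a": [1, 2]}, {"a": [True, True]})
        with pytest.raises(ValueError):
            logrank_test(
                {"a": [1, 2], "b": [3, 4]},
                {"a": [False, False], "b": [False, False]},
            )

    def test_matches_lifelines_on_random_three_group_instances(self):
        stats_ll = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(2)
        for trial in range(5):
            times, events, labels = [], [], []
            for g, scale in (("a", 8), ("b", 12), ("c", 20)):
                t = rng.exponential(scale, 20).round(2) + 0.01
                e = rng.uniform(size=20) < 0.7
                times += list(t)
                events += list(e)
                labels += [g] * 20
            chi2, df, p = logrank_test(
                {g: [t for t, l in zip(times, labels) if l == g] for g in "abc"},
                {g: [e for e, l in zip(events, labels) if l == g] for g in "abc"},
            )
            ref = stats_ll.multivariate_logrank_test(times, labels, events)
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-6)
            assert p == pytest.approx(ref.p_value, abs=1e-6)

    def test_permutation_type_I_error_calibrated(self):
        # permuting group labels under the null: rejection rate ~ alpha
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 60).round(2) + 0.01
        events = rng.uniform(size=60) < 0.7
        rejections = 0
        n_perm = 400
        for _ in range(n_perm):
            labels = rng.permutation([0] * 20 + [1] * 20 + [2] * 20)
            _, _, p = logrank_test(
                {g: times[labels == g] for g in range(3)},
                {g: events[labels == g] for g in range(3)},
            )
            rejections += p < 0.05
        assert rejections / n_perm == pytest.approx(0.05, abs=0.03)

    def test_pairwise_covers_all_pairs(self):
        rng = np.random.default_rng(4)
        gt = {g: rng.exponential(10, 15) + 0.01 for g in "abc"}
        ge = {g: rng.uniform(size=15) < 0.8 for g in "abc"}
        pw = pairwise_logrank(gt, ge)
        assert len(pw) == 3
        assert set(map(tuple, pw[["group_a", "group_b"]].values)) == {
            ("a", "b"), ("a", "c"), ("b", "c"),
        }


class TestStratifyCohort:
    def make_patients(self, n=90, seed=0):
        rng = np.random.default_rng(seed)
        lact = np.exp(rng.normal(0.7, 0.5, n))
        ratio = np.exp(rng.normal(-0.8, 0.6, n))
        # mortality probability increases with both biomarkers
        logit = -3.5 + 1.2 * np.log(lact) + 1.0 * np.log(ratio / 0.47)
        dead = rng.uniform(size=n) < 1 / (1 + np.exp(-logit))
        times = np.where(dead, rng.exponential(8, n), 30.0).clip(0.1, 30.0)
        patients = pd.DataFrame(
            {
                "lactate": lact,
                "outcome": np.where(dead, "nonsurvivor", "survivor"),
                "survival_time": times,
                "event": dead,
            },
            index=[f"P{i}" for i in range(n)],
        )
        return patients, pd.Series(ratio, patients.index)

    def test_partition_and_outputs(self):
        patients, ratio = self.make_patients()
        rg = stratify_cohort(patients, ratio, RULE)
        assert rg.assignments.isin(GROUP_ORDER).all()
        assert rg.mortality["n"].sum() == len(rg.assignments)
        assert set(rg.km_curves) <= set(GROUP_ORDER)
        assert 0 <= rg.overall_logrank[2] <= 1

    def test_mortality_ordering_across_seeds(self):
        # risk-linked outcomes: mean mortality must order low < int < high
        rates = {g: [] for g in GROUP_ORDER}
        for seed in range(10):
            patients, ratio = self.make_patients(seed=seed)
            rg = stratify_cohort(patients, ratio, RULE)
            for g in GROUP_ORDER:
                n = rg.mortality.loc[g, "n"]
                if n:
                    rates[g].append(rg.mortality.loc[g, "deaths"] / n)
        means = {g: np.mean(v) for g, v in rates.items()}
        assert means["low"] < means["intermediate"] < means["high"]
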