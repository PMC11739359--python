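"""Moderated t / B statistic engine and BH adjustment."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from conftest import toy_cohort
from sepsisratio.diffexp import (
    GroupSizeError,
    b_statistic,
    bh_adjust,
    fit_f_dist,
    fit_group_comparison,
    ordinary_t_table,
    trigamma_inverse,
)


class TestOrdinaryT:
    def test_pooled_t_on_two_triples(self):
        # {1,2,3} vs {4,5,6}: mean diff -3, pooled var 1, SE sqrt(2/3)
        rng = np.random.default_rng(0)
        mat = np.vstack(
            [[1, 2, 3, 4, 5, 6], rng.normal(8, 1, (30, 6))]
        )
        cohort = toy_cohort(mat, ["nonsurvivor"] * 3 + ["survivor"] * 3)
        tab = ordinary_t_table(cohort, "D1")
        assert tab["log2_fc"].iloc[0] == pytest.approx(-3.0)
        assert tab["t"].iloc[0] == pytest.approx(-3.674, abs=5e-4)

    def test_too_small_group_raises(self):
        mat = np.random.default_rng(1).normal(8, 1, (5, 4))
        cohort = toy_cohort(mat, ["nonsurvivor"] + ["survivor"] * 3)
        with pytest.raises(GroupSizeError):
            fit_group_comparison(cohort, "D1")


class TestModeratedFit:
    def test_log2fc_is_exact_mean_difference(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(8, 1, (50, 20))
        labels = ["nonsurvivor"] * 8 + ["survivor"] * 12
        cohort = toy_cohort(mat, labels)
        fit = fit_group_comparison(cohort, "D1")
        expected = mat[:, :8].mean(axis=1) - mat[:, 8:].mean(axis=1)
        np.testing.assert_allclose(fit["log2_fc"].to_numpy(), expected, atol=1e-12)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(8, 0.7, (5000, 40))
        labels = ["nonsurvivor"] * 15 + ["survivor"] * 25
        cohort = toy_cohort(mat, labels)
        fit = fit_group_comparison(cohort, "D1")
        ks = stats.kstest(fit["p"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_huge_separation_posterior_approaches_one(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(8, 0.5, (400, 20))
        mat[0, :10] += 30.0  # enormous effect in 'nonsurvivor' half
        labels = ["nonsurvivor"] * 10 + ["survivor"] * 10
        fit = fit_group_comparison(toy_cohort(mat, labels), "D1")
        assert fit["posterior_prob"].iloc[0] > 0.999

    def test_posterior_prob_monotone_in_b(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(8, 0.7, (1000, 30))
        mat[:50, :12] += rng.uniform(0.5, 2.5, (50, 1))
        fit = fit_group_comparison(
            toy_cohort(mat, ["nonsurvivor"] * 12 + ["survivor"] * 18), "D1"
        )
        order = fit["b"].sort_values().index
        assert fit["posterior_prob"].loc[order].is_monotonic_increasing

    def test_b_monotone_in_abs_t(self):
        t = np.array([-5.0, -2.0, -0.5, 0.0, 0.5, 2.0, 5.0])
        b = b_statistic(t, df_total=20.0, v_unscaled=0.2, var_prior=2.0, p_de=0.01)
        assert np.allclose(b, b[::-1])  # symmetric in t
        assert (np.diff(b[3:]) > 0).all()

    def test_moderated_t_between_ordinary_and_z(self):
        """As prior df grows the variance estimate approaches the global prior."""
        rng = np.random.default_rng(6)
        mat = rng.normal(8, 0.7, (2000, 16))
        cohort = toy_cohort(mat, ["nonsurvivor"] * 8 + ["survivor"] * 8)
        fit = fit_group_comparison(cohort, "D1")
        # posterior variance lies between the gene estimate and the prior
        s2g, s2p = fit["s2_gene"].to_numpy(), fit["s2_post"].to_numpy()
        lo = np.minimum(s2g, fit.s2_prior)
        hi = np.maximum(s2g, fit.s2_prior)
        assert ((s2p >= lo - 1e-12) & (s2p <= hi + 1e-12)).all()

    def test_zero_variance_gene_floored_with_warning(self):
        rng = np.random.default_rng(7)
        mat = rng.normal(8, 0.7, (100, 10))
        mat[0] = 5.0  # constant gene
        cohort = toy_cohort(mat, ["nonsurvivor"] * 5 + ["survivor"] * 5)
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_group_comparison(cohort, "D1")
        assert np.isfinite(fit["t"].iloc[0])


class TestTrigammaInverse:
    @pytest.mark.parametrize("y", [0.05, 0.5, 2.0, 10.0])
    def test_roundtrip(self, y):
        from scipy.special import polygamma

        assert trigamma_inverse(float(polygamma(1, y))) == pytest.approx(y, rel=1e-6)

    def test_fit_f_dist_recovers_hyperparameters(self):
        # simulate s2 ~ s0^2 * (chi2_df/df) / (chi2_d0/d0) with known d0, s0
        rng = np.random.default_rng(8)
        d0, s0_2, df = 8.0, 0.5, 10.0
        s2 = (
            s0_2
            * (rng.chisquare(df, 200000) / df)
            / (rng.chisquare(d0, 200000) / d0)
        )
        d0_hat, s0_hat = fit_f_dist(s2, df)
        assert d0_hat == pytest.approx(d0, rel=0.1)
        assert s0_hat == pytest.approx(s0_2, rel=0.05)


class TestAgainstLimma:
    def test_moderated_statistics_match_limma(self, tmp_path):
        """Independent oracle: Bioconductor limma lmFit/eBayes on a small matrix."""
        rng = np.random.default_rng(9)
        n1, n0 = 6, 8
        mat = rng.normal(8, 0.7, (300, n1 + n0))
        mat[:20, :n1] += rng.uniform(0.8, 2.0, (20, 1))
        labels = ["nonsurvivor"] * n1 + ["survivor"] * n0
        cohort = toy_cohort(mat, labels)
        fit = fit_group_comparison(cohort, "D1", p_de=0.01)

        data = tmp_path / "mat.tsv"
        pd.DataFrame(mat).to_csv(data, sep="\t", index=False, header=False)
        rscript = tmp_path / "oracle.R"
        rscript.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(limma))
                x <- as.matrix(read.delim("{data}", header=FALSE))
                group <- factor(c(rep("dead", {n1}), rep("alive", {n0})), levels=c("alive","dead"))
                design <- model.matrix(~group)
                f <- eBayes(lmFit(x, design), proportion=0.01)
                out <- data.frame(logfc=f$coefficients[,2], t=f$t[,2], p=f$p.value[,2], b=f$lods[,2],
                                  d0=f$df.prior, s02=f$s2.prior)
                write.table(out, "{tmp_path / 'limma.tsv'}", sep="\\t", row.names=FALSE)
                """
            )
        )
        subprocess.run(["Rscript", str(rscript)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        np.testing.assert_allclose(fit["log2_fc"].to_numpy(), ref["logfc"], atol=1e-8)
        assert fit.df_prior == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert fit.s2_prior == pytest.approx(ref["s02"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(fit["t"].to_numpy(), ref["t"], rtol=1e-5)
        np.testing.assert_allclose(fit["p"].to_numpy(), ref["p"], rtol=1e-4)
        np.testing.assert_allclose(fit["b"].to_numpy(), ref["b"], rtol=1e-3, atol=1e-3)


class TestBH:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_identity(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_direct_formula_and_statsmodels(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        # direct step-up formula: q_i = min_{j: p_j >= p_i} p_j * m / rank_j
        m = len(p)
        order = np.argsort(p)
        direct = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            running = min(running, p[order[rank - 1]] * m / rank)
            direct[order[rank - 1]] = min(running, 1.0)
        np.testing.assert_allclose(q, direct, atol=1e-12)
        sm = pytest.importorskip("statsmodels.stats.multitest")
        np.testing.assert_allclose(
            q, sm.multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=80))
    def test_bh_bounds_and_order_preservation(self, ps):
        q = bh_adjust(ps)
        p = np.asarray(ps)
        assert ((q >= p - 1e-12) & (q <= 1.0 + 1e-12)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()
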