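import numpy as np
import pytest
from scipy import stats

from conftest import make_instance
from oracles import dense_score_test
from scgxc.covariance import context_covariance, relatedness_context_covariance
from scgxc.inference import (
    association_lrt,
    interaction_score_test,
    interaction_test_no_relatedness,
    multi_env_lrt,
    single_env_lrt,
)
from scgxc.null_model import FixedDesign, fit_variance_components
from scgxc.preprocessing import (
    CellDonorMap,
    ContextMatrix,
    DegenerateInputError,
    standardize_contexts,
)


class TestInteractionScoreTest:
    def test_matches_dense_oracle(self):
        inst = make_instance(seed=21, n_donors=8, cells_per_donor=10, k=3)
        res = interaction_score_test(
            inst["y"], inst["g"], inst["X"], inst["Sigma"], inst["RSigma"]
        )
        fit = res.fit
        K0 = fit.K0.dense()
        F = inst["g"][:, None] * inst["Sigma"].factor
        Q_dense, lam_dense = dense_score_test(inst["y"], inst["X"], K0, F)
        np.testing.assert_allclose(res.statistic, Q_dense, rtol=1e-6)
        np.testing.assert_allclose(
            np.sort(res.eigen_weights), np.sort(lam_dense), rtol=1e-6
        )

    def test_single_context_closed_form(self):
        inst = make_instance(seed=22, n_donors=8, cells_per_donor=10, k=1)
        res = interaction_score_test(
            inst["y"], inst["g"], inst["X"], inst["Sigma"], inst["RSigma"]
        )
        assert len(res.eigen_weights) == 1
        lam = res.eigen_weights[0]
        np.testing.assert_allclose(
            res.pvalue, stats.chi2.sf(res.statistic / lam, 1), rtol=1e-6
        )

    def test_constant_genotype_rejected(self):
        inst = make_instance(seed=23)
        with pytest.raises(DegenerateInputError, match="unestimable"):
            interaction_score_test(
                inst["y"],
                np.ones(inst["n"]),
                np.ones((inst["n"], 1)),
                inst["Sigma"],
                inst["RSigma"],
            )

    def test_permutation_invariance(self):
        inst = make_instance(seed=24, n_donors=6, cells_per_donor=8, k=2)
        res1 = interaction_score_test(
            inst["y"], inst["g"], inst["X"], inst["Sigma"], inst["RSigma"]
        )
        rng = np.random.default_rng(0)
        perm = rng.permutation(inst["n"])
        from scgxc.covariance import LowRankCovariance

        Sigma_p = LowRankCovariance(inst["Sigma"].factor[perm], description="context")
        RSigma_p = LowRankCovariance(
            inst["RSigma"].factor[perm], description="relatedness_x_context"
        )
        res2 = interaction_score_test(
            inst["y"][perm], inst["g"][perm], inst["X"][perm], Sigma_p, RSigma_p
        )
        np.testing.assert_allclose(res1.pvalue, res2.pvalue, rtol=1e-5)

    def test_residualization_invariance(self):
        # adding a column-space vector of X to y leaves Q unchanged (same fit reused)
        inst = make_instance(seed=25, n_donors=6, cells_per_donor=8, k=2)
        fit = fit_variance_components(
            inst["y"], inst["X"], [inst["RSigma"], inst["Sigma"]]
        )
        res1 = interaction_score_test(
            inst["y"], inst["g"], inst["X"], inst["Sigma"], inst["RSigma"], fit=fit
        )
        shift = inst["X"] @ np.array([2.0, -1.0])
        kernel_shift = fit_variance_components(
            inst["y"] + shift,
            inst["X"],
            [inst["RSigma"], inst["Sigma"]],
            starts=[
                np.maximum(
                    [
                        fit.variances["relatedness_x_context"],
                        fit.variances["context"],
                        fit.variances["noise"],
                    ],
                    1e-8,
                )
            ],
        )
        res2 = interaction_score_test(
            inst["y"] + shift,
            inst["g"],
            inst["X"],
            inst["Sigma"],
            inst["RSigma"],
            fit=kernel_shift,
        )
        np.testing.assert_allclose(res1.statistic, res2.statistic, rtol=1e-4)

    def test_pvalue_in_unit_interval(self):
        inst = make_instance(seed=26)
        res = interaction_score_test(
            inst["y"], inst["g"], inst["X"], inst["Sigma"], inst["RSigma"]
        )
        assert 0.0 < res.pvalue <= 1.0
        assert res.statistic >= 0.0
        assert (res.eigen_weights > 0).all()


class TestAssociationLRT:
    def test_null_calibration_smoke(self):
        # orthogonal genotype on pure-noise data: p should not be systematically small
        pvals = []
        for seed in range(40):
            inst = make_instance(seed=300 + seed, n_donors=10, cells_per_donor=10, k=2)
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(inst["n"])
            res = association_lrt(
                y, inst["g"], np.ones((inst["n"], 1)), inst["Sigma"], inst["RSigma"],
                mode="fast", n_starts=1,
            )
            pvals.append(res.pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_detects_strong_effect(self):
        inst = make_instance(seed=31, n_donors=20, cells_per_donor=20, k=2)
        rng = np.random.default_rng(1)
        y = 0.8 * inst["g"] + rng.standard_normal(inst["n"])
        res = association_lrt(
            y, inst["g"], np.ones((inst["n"], 1)), inst["Sigma"], inst["RSigma"]
        )
        assert res.pvalue < 1e-6
        assert res.lrt_stat >= 0
        assert abs(res.beta_G - 0.8) < 0.2

    def test_exact_vs_fast_agree_roughly(self):
        inst = make_instance(seed=32, n_donors=15, cells_per_donor=15, k=2)
        rng = np.random.default_rng(2)
        y = 0.3 * inst["g"] + rng.standard_normal(inst["n"])
        exact = association_lrt(
            y, inst["g"], np.ones((inst["n"], 1)), inst["Sigma"], inst["RSigma"],
            mode="exact",
        )
        fast = association_lrt(
            y, inst["g"], np.ones((inst["n"], 1)), inst["Sigma"], inst["RSigma"],
            mode="fast",
        )
        assert fast.mode == "fast"
        assert abs(np.log10(exact.pvalue) - np.log10(fast.pvalue)) < 1.0

    def test_collinear_genotype_rejected(self):
        inst = make_instance(seed=33)
        with pytest.raises(DegenerateInputError):
            association_lrt(
                inst["y"], np.ones(inst["n"]), np.ones((inst["n"], 1)),
                inst["Sigma"], inst["RSigma"],
            )


class TestFixedEffectComparators:
    def test_single_env_k1_no_adjustment(self):
        # with one context there is no Bonferroni factor and the two comparators
        # agree up to the variance-component refit of the joint LRT
        inst = make_instance(seed=41, n_donors=8, cells_per_donor=10, k=1)
        p_single = single_env_lrt(
            inst["y"], inst["g"], inst["X"], inst["C"], inst["Sigma"], inst["RSigma"]
        )
        p_multi = multi_env_lrt(
            inst["y"], inst["g"], inst["X"], inst["C"], inst["Sigma"], inst["RSigma"]
        )
        # the joint LRT refits variance components, so agreement is approximate
        # (systematically slightly smaller p); see the decisions ledger
        assert abs(np.log10(p_single) - np.log10(p_multi)) < 0.3

    def test_pvalues_bounded(self):
        inst = make_instance(seed=42, n_donors=8, cells_per_donor=10, k=4)
        p1 = single_env_lrt(
            inst["y"], inst["g"], inst["X"], inst["C"], inst["Sigma"], inst["RSigma"]
        )
        p2 = multi_env_lrt(
            inst["y"], inst["g"], inst["X"], inst["C"], inst["Sigma"], inst["RSigma"]
        )
        assert 0 < p1 <= 1 and 0 < p2 <= 1

    def test_single_env_projection_identity(self):
        # the one-shot projection statistic equals the explicit fixed-K
        # ML log-likelihood difference for each added interaction column
        from scgxc.null_model import GramKernel

        inst = make_instance(seed=44, n_donors=8, cells_per_donor=10, k=3)
        fit = fit_variance_components(
            inst["y"], inst["X"], [inst["RSigma"], inst["Sigma"]]
        )
        scales = [fit.variances["relatedness_x_context"], fit.variances["context"]]
        noise = fit.variances["noise"]
        blocks = [inst["RSigma"].factor, inst["Sigma"].factor]
        k0 = GramKernel(inst["y"], inst["X"], blocks)
        ll0 = k0.loglik(scales, noise, reml=False)
        C = inst["C"].values
        F = inst["g"][:, None] * C
        PF = fit.project(F)
        for j in range(C.shape[1]):
            X1 = np.column_stack([inst["X"], F[:, j]])
            ll1 = GramKernel(inst["y"], X1, blocks).loglik(scales, noise, reml=False)
            explicit = max(2.0 * (ll1 - ll0), 0.0)
            shortcut = (PF[:, j] @ inst["y"]) ** 2 / (F[:, j] @ PF[:, j])
            np.testing.assert_allclose(shortcut, explicit, rtol=1e-6, atol=1e-8)

    def test_single_env_detects_aligned_interaction(self):
        inst = make_instance(seed=43, n_donors=20, cells_per_donor=30, k=3)
        rng = np.random.default_rng(3)
        c1 = inst["C"].values[:, 0]
        y = 0.5 * inst["g"] * c1 + rng.standard_normal(inst["n"])
        p = single_env_lrt(
            inst["y"] * 0 + y, inst["g"], inst["X"], inst["C"],
            inst["Sigma"], inst["RSigma"],
        )
        assert p < 1e-4


class TestNoRelatednessVariant:
    def test_one_cell_per_donor_agrees_with_full_model(self):
        # with one cell per donor and data lacking donor-context structure, the
        # repeat-structure component fits to ~0 and both tests agree
        rng = np.random.default_rng(5)
        n = 120
        cell_map = CellDonorMap(np.arange(n))
        C = standardize_contexts(ContextMatrix(rng.standard_normal((n, 2))))
        Sigma = context_covariance(C)
        RSigma = relatedness_context_covariance(cell_map, C)
        g = rng.binomial(2, 0.3, n).astype(float)
        y = (
            0.4 * (C.values @ rng.standard_normal(2))
            + rng.standard_normal(n)
        )
        X = np.column_stack([np.ones(n), g])
        full = interaction_score_test(y, g, X, Sigma, RSigma)
        reduced = interaction_test_no_relatedness(y, g, X, Sigma)
        np.testing.assert_allclose(full.pvalue, reduced.pvalue, atol=1e-4)

    def test_single_context_mixture_identity(self):
        rng = np.random.default_rng(6)
        n = 80
        C = standardize_contexts(ContextMatrix(rng.standard_normal((n, 1))))
        Sigma = context_covariance(C)
        g = rng.binomial(2, 0.4, n).astype(float)
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), g])
        res = interaction_test_no_relatedness(y, g, X, Sigma)
        lam = res.eigen_weights[0]
        np.testing.assert_allclose(
            res.pvalue, stats.chi2.sf(res.statistic / lam, 1), rtol=1e-6
        )
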