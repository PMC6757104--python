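"""Marginal likelihoods, EM, responsibilities, and the two calling rules."""

import itertools

import numpy as np
import pytest
from scipy.integrate import dblquad
from scipy.stats import beta as beta_dist

from gwasmix.genotype_io import SuffStats
from gwasmix.hyperprior import Hyperparams
from gwasmix.mixture import (
    CallSet,
    LogMarginals,
    MixtureFit,
    call_at_fdr,
    call_max_posterior,
    compute_log_marginals,
    em_fit,
    init_from_snpwise,
    log_marginal_null,
    log_marginal_signed,
    prob_beta_greater,
    responsibilities,
)
from conftest import random_suffstats


def stats_row(n_x, m_x, h_x, n_y, m_y, h_y, snp_id="s"):
    return SuffStats(
        snp_ids=[snp_id], n_x=[n_x], m_x=[m_x], h_x=[h_x],
        n_y=[n_y], m_y=[m_y], h_y=[h_y],
    )


def enumerate_genotype_stats(n_x, n_y):
    """SuffStats for every point of the genotype sample space 3^(n_x+n_y)."""
    rows = []
    for gx in itertools.product([0, 1, 2], repeat=n_x):
        for gy in itertools.product([0, 1, 2], repeat=n_y):
            rows.append(
                (n_x, sum(gx), sum(1 for v in gx if v == 1),
                 n_y, sum(gy), sum(1 for v in gy if v == 1))
            )
    arr = np.array(rows)
    return SuffStats(
        snp_ids=np.arange(len(rows)).astype(object),
        n_x=arr[:, 0], m_x=arr[:, 1], h_x=arr[:, 2],
        n_y=arr[:, 3], m_y=arr[:, 4], h_y=arr[:, 5],
    )


class TestNullMarginal:
    def test_flat_prior_single_subjects(self):
        # both subjects homozygous reference: integral of (1-t)^4 dt = 1/5
        s = stats_row(1, 0, 0, 1, 0, 0)
        val = np.exp(log_marginal_null(s, Hyperparams(1, 1))[0])
        assert val == pytest.approx(0.2, abs=1e-12)

    def test_case_control_symmetry(self, rng):
        s = random_suffstats(rng, n_snps=10)
        hp = Hyperparams(2, 5)
        np.testing.assert_allclose(
            log_marginal_null(s, hp), log_marginal_null(s.swapped(), hp), atol=1e-12
        )

    def test_sums_to_one_over_sample_space(self):
        s = enumerate_genotype_stats(1, 1)
        total = np.exp(log_marginal_null(s, Hyperparams(1, 1))).sum()
        assert total == pytest.approx(1.0, abs=1e-12)


class TestProbBetaGreater:
    def test_exchangeable_gives_half(self):
        assert prob_beta_greater(3.7, 4.2, 3.7, 4.2) == pytest.approx(0.5, abs=1e-10)

    def test_closed_form_mean(self):
        # V uniform: P(U > V) = E[U] = 2/3 for U ~ Beta(2, 1)
        assert prob_beta_greater(2, 1, 1, 1) == pytest.approx(2 / 3, abs=1e-10)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(5)
        n = 10**7
        u = rng.beta(7, 13, n)
        v = rng.beta(3, 17, n)
        mc = (u > v).mean()
        se = np.sqrt(mc * (1 - mc) / n)
        assert prob_beta_greater(7, 13, 3, 17) == pytest.approx(mc, abs=3 * se)

    def test_nonpositive_parameter_raises(self):
        with pytest.raises(ValueError):
            prob_beta_greater(0, 1, 1, 1)


def signed_marginal_quadrature(s, hp, sign):
    """Independent oracle: adaptive 2-D quadrature of the defining integral."""
    n_x, m_x = int(s.n_x[0]), int(s.m_x[0])
    n_y, m_y = int(s.n_y[0]), int(s.m_y[0])

    def integrand(ty, tx):
        lik = (
            tx**m_x * (1 - tx) ** (2 * n_x - m_x)
            * ty**m_y * (1 - ty) ** (2 * n_y - m_y)
        )
        return 2 * lik * beta_dist.pdf(tx, hp.alpha, hp.beta) * beta_dist.pdf(
            ty, hp.alpha, hp.beta
        )

    if sign == "+":  # region theta_x > theta_y
        val, _ = dblquad(integrand, 0, 1, 0, lambda tx: tx, epsabs=1e-12, epsrel=1e-10)
    else:
        val, _ = dblquad(integrand, 0, 1, lambda tx: tx, 1, epsabs=1e-12, epsrel=1e-10)
    return val


class TestSignedMarginal:
    def test_flat_prior_symmetric_halves(self):
        # both subjects hom-ref: xi_+ = 2 * (1/2) * (1/3)^2 = 1/9
        s = stats_row(1, 0, 0, 1, 0, 0)
        val = np.exp(log_marginal_signed(s, Hyperparams(1, 1), "+")[0])
        assert val == pytest.approx(1 / 9, abs=1e-10)

    def test_matches_2d_quadrature(self):
        s = stats_row(5, 4, 2, 5, 1, 1)
        hp = Hyperparams(2, 5)
        for sign in ("+", "-"):
            got = np.exp(log_marginal_signed(s, hp, sign)[0]) / 2 ** (
                s.h_x[0] + s.h_y[0]
            )
            assert got == pytest.approx(
                signed_marginal_quadrature(s, hp, sign), abs=1e-7
            )

    def test_plus_minus_sum_identity(self, rng):
        # P(U>V) + P(U<V) = 1 => xi_+ + xi_- = 2 * product of group marginals
        s = random_suffstats(rng, n_snps=40)
        hp = Hyperparams(3.29, 9.56)
        from scipy.special import betaln

        xp = np.exp(log_marginal_signed(s, hp, "+", include_het_factor=False))
        xm = np.exp(log_marginal_signed(s, hp, "-", include_het_factor=False))
        indep = np.exp(
            betaln(hp.alpha + s.m_x, hp.beta + 2 * s.n_x - s.m_x)
            + betaln(hp.alpha + s.m_y, hp.beta + 2 * s.n_y - s.m_y)
            - 2 * betaln(hp.alpha, hp.beta)
        )
        np.testing.assert_allclose(xp + xm, 2 * indep, rtol=1e-10)

    def test_label_swap_antisymmetry(self, rng):
        s = random_suffstats(rng, n_snps=15)
        hp = Hyperparams(2, 5)
        lm = compute_log_marginals(s, hp)
        lm_swap = compute_log_marginals(s.swapped(), hp)
        np.testing.assert_allclose(lm_swap.logxi[:, 0], lm.logxi[:, 0], atol=1e-12)
        np.testing.assert_allclose(lm_swap.logxi[:, 1], lm.logxi[:, 2], atol=1e-12)
        np.testing.assert_allclose(lm_swap.logxi[:, 2], lm.logxi[:, 1], atol=1e-12)


class TestComputeLogMarginals:
    def test_het_factor_cancels_in_responsibilities(self, rng):
        s = random_suffstats(rng, n_snps=12)
        hp = Hyperparams(2, 5)
        lm_with = compute_log_marginals(s, hp, include_het_factor=True)
        lm_without = compute_log_marginals(s, hp, include_het_factor=False)
        shift = lm_with.logxi - lm_without.logxi
        np.testing.assert_allclose(shift - shift[:, :1], 0.0, atol=1e-10)
        pi = np.array([0.9, 0.06, 0.04])
        np.testing.assert_allclose(
            responsibilities(lm_with, pi), responsibilities(lm_without, pi), atol=1e-12
        )

    def test_vectorization_matches_scalar_ops(self, rng):
        s = random_suffstats(rng, n_snps=8)
        hp = Hyperparams(2.5, 7.0)
        lm = compute_log_marginals(s, hp, include_het_factor=True)
        for g in range(s.n_snps):
            row = stats_row(
                s.n_x[g], s.m_x[g], s.h_x[g], s.n_y[g], s.m_y[g], s.h_y[g]
            )
            expected = [
                log_marginal_null(row, hp)[0],
                log_marginal_signed(row, hp, "+")[0],
                log_marginal_signed(row, hp, "-")[0],
            ]
            np.testing.assert_allclose(lm.logxi[g], expected, atol=1e-10)

    def test_rows_finite_on_simulated_data(self, rng):
        s = random_suffstats(rng, n_snps=1000, n_x=100, n_y=100)
        lm = compute_log_marginals(s, Hyperparams(3.29, 9.56))
        assert np.isfinite(lm.logxi).all()


class TestInit:
    def test_no_signal_concentrates_on_null(self):
        s = random_suffstats(np.random.default_rng(0), n_snps=50)
        pi0 = init_from_snpwise(s, np.full(50, 0.5))
        assert pi0[0] > 0.9
        assert pi0[1] == pytest.approx(pi0[2])
        assert pi0.sum() == pytest.approx(1.0)

    def test_three_snp_arithmetic(self):
        s = SuffStats(
            snp_ids=["a", "b", "c"],
            n_x=[10] * 3, m_x=[8, 2, 5], h_x=[2, 2, 1],
            n_y=[10] * 3, m_y=[2, 8, 5], h_y=[2, 2, 1],
        )
        pi0 = init_from_snpwise(s, np.array([0.01, 0.01, 0.9]), p_cut=0.05)
        np.testing.assert_allclose(pi0, [1 / 3, 1 / 3, 1 / 3], atol=1e-12)

    def test_length_mismatch_raises(self, rng):
        s = random_suffstats(rng, n_snps=5)
        with pytest.raises(ValueError, match="length"):
            init_from_snpwise(s, np.array([0.5, 0.5]))


def uninformative_lm(g=200):
    logxi = np.tile(np.array([-3.0, -3.0, -3.0]), (g, 1))
    return LogMarginals(snp_ids=np.arange(g).astype(object), logxi=logxi,
                        includes_het_factor=False)


class TestEm:
    def test_uninformative_fixed_point(self):
        # identical xi columns: MAP fixed point is (b_k - 1) / sum(b_j - 1)
        fit = em_fit(uninformative_lm(), Hyperparams(2, 5, pseudo_counts=(3, 3, 3)))
        np.testing.assert_allclose(fit.pi, [1 / 3, 1 / 3, 1 / 3], atol=1e-10)

    def test_warm_restart_converges_immediately(self, rng):
        s = random_suffstats(rng, n_snps=300, n_x=50, n_y=50)
        hp = Hyperparams(2, 5)
        lm = compute_log_marginals(s, hp)
        fit1 = em_fit(lm, hp)
        assert fit1.converged
        fit2 = em_fit(lm, hp, pi0=fit1.pi)
        assert fit2.converged and fit2.n_iter <= 2
        np.testing.assert_allclose(fit2.pi, fit1.pi, atol=1e-4)

    def test_trace_monotone_and_gamma_normalized(self, rng):
        s = random_suffstats(rng, n_snps=400, n_x=30, n_y=30)
        hp = Hyperparams(3.29, 9.56)
        fit = em_fit(compute_log_marginals(s, hp), hp, pi0=np.array([0.5, 0.3, 0.2]))
        diffs = np.diff(fit.log_posterior_trace)
        assert (diffs >= -1e-9).all()
        np.testing.assert_allclose(fit.gamma.sum(axis=1), 1.0, atol=1e-12)
        assert fit.pi.sum() == pytest.approx(1.0, abs=1e-12)


class TestResponsibilities:
    def test_equal_xi_returns_pi(self):
        lm = uninformative_lm(10)
        pi = np.array([0.7, 0.2, 0.1])
        np.testing.assert_allclose(responsibilities(lm, pi), np.tile(pi, (10, 1)),
                                   atol=1e-12)

    def test_degenerate_pi(self):
        lm = uninformative_lm(5)
        gamma = responsibilities(lm, np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(gamma, np.tile([1.0, 0, 0], (5, 1)), atol=1e-12)

    def test_hand_arithmetic(self):
        lm = LogMarginals(
            snp_ids=np.array(["s"], dtype=object),
            logxi=np.log(np.array([[0.2, 0.4, 0.1]])),
            includes_het_factor=False,
        )
        gamma = responsibilities(lm, np.array([0.8, 0.1, 0.1]))
        np.testing.assert_allclose(gamma[0], [16 / 21, 4 / 21, 1 / 21], atol=1e-12)


def fit_from_gamma(gamma):
    gamma = np.asarray(gamma, dtype=float)
    return MixtureFit(
        snp_ids=np.arange(len(gamma)).astype(object),
        pi=gamma.mean(axis=0),
        gamma=gamma,
        log_posterior_trace=np.array([0.0]),
        n_iter=1,
        converged=True,
    )


class TestMaxPosteriorCalling:
    @pytest.mark.parametrize(
        "row,expected",
        [([0.7, 0.2, 0.1], 0), ([0.2, 0.5, 0.3], 1), ([0.4, 0.4, 0.2], 0),
         ([0.2, 0.3, 0.5], -1)],
    )
    def test_argmax_with_conservative_ties(self, row, expected):
        calls = call_max_posterior(fit_from_gamma([row]))
        assert calls.calls[0] == expected


def bruteforce_fdr_calls(gamma, nominal):
    """Exhaustive search over all threshold-defined called sets."""
    score = np.maximum(gamma[:, 1], gamma[:, 2])
    best = np.zeros(len(gamma), dtype=bool)
    for tau in np.unique(np.r_[score, 0.0, 1.0]):
        called = score > tau
        if not called.any():
            continue
        if gamma[called, 0].mean() <= nominal and called.sum() > best.sum():
            best = called
    return best


class TestFdrCalling:
    def test_two_snp_fdr_hat_mean(self):
        gamma = np.array([[0.01, 0.99, 0.0], [0.03, 0.0, 0.97], [0.9, 0.05, 0.05]])
        calls = call_at_fdr(fit_from_gamma(gamma), nominal=0.05)
        assert calls.fdr_hat == pytest.approx(0.02)
        np.testing.assert_array_equal(calls.calls, [1, -1, 0])

    def test_all_null_like_gives_empty_set(self):
        gamma = np.tile([0.6, 0.25, 0.15], (20, 1))
        calls = call_at_fdr(fit_from_gamma(gamma), nominal=0.05)
        assert not calls.called_mask.any()
        assert calls.fdr_hat == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(99)
        for trial in range(20):
            raw = rng.dirichlet(np.array([3.0, 1.0, 1.0]), size=50)
            nominal = rng.uniform(0.02, 0.3)
            calls = call_at_fdr(fit_from_gamma(raw), nominal=nominal)
            expected = bruteforce_fdr_calls(raw, nominal)
            np.testing.assert_array_equal(calls.called_mask, expected)
            if expected.any():
                assert raw[expected, 0].mean() <= nominal
                score = np.maximum(raw[:, 1], raw[:, 2])
                assert (score[calls.called_mask] > calls.tau).all()

    def test_strong_effect_snp_gets_high_plus_responsibility(self):
        # single SNP generated from cluster + with a 0.15 MAF gap at n=500
        rng = np.random.default_rng(42)
        dx = rng.binomial(2, 0.35, 500)
        dy = rng.binomial(2, 0.20, 500)
        s = SuffStats(
            snp_ids=["s"], n_x=[500], m_x=[dx.sum()], h_x=[(dx == 1).sum()],
            n_y=[500], m_y=[dy.sum()], h_y=[(dy == 1).sum()],
        )
        lm = compute_log_marginals(s, Hyperparams(3.29, 9.56))
        gamma = responsibilities(lm, np.array([1 / 3, 1 / 3, 1 / 3]))
        assert gamma[0, 1] > 0.9
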