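"""Three-cluster Beta-multinomial mixture model for case-control SNP data.

Each SNP's genotype profile is modelled as a multinomial draw under
Hardy-Weinberg equilibrium with unknown minor-allele frequency theta per
group.  Cluster 0 shares one theta between cases and controls under a
conjugate Beta(alpha, beta) prior; clusters + and - place a "half-flat"
bivariate prior on (theta_case, theta_control) equal to twice the product
of two Beta densities restricted to theta_case > theta_control (cluster +)
or theta_case < theta_control (cluster -).  The thetas are integrated out
analytically / by one-dimensional quadrature, leaving per-SNP cluster
marginal likelihoods xi_k.  An EM algorithm with a Dirichlet prior then
estimates the mixture proportions pi, and SNPs are called from their
posterior cluster responsibilities, either by maximum posterior or at a
target model-based FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import betainc, betaln, logsumexp
from scipy.stats import beta as beta_dist

from .genotype_io import SuffStats
from .hyperprior import Hyperparams

#: cluster order used in every (G, 3) array in this module
CLUSTERS: tuple[str, str, str] = ("0", "+", "-")

_GL_NODES = 256
_LOG_FLOOR = -745.0  # ~log of the smallest positive double; keeps log xi finite
_PPF_EPS = 1e-14

_gl_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gauss_legendre(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _gl_cache:
        x, w = leggauss(n)
        _gl_cache[n] = (x, w)
    return _gl_cache[n]


@dataclass
class LogMarginals:
    """Per-SNP log marginal likelihoods log xi_k, columns ordered (0, +, -).

    ``includes_het_factor`` records whether the shared 2^(h_x + h_y)
    multinomial coefficient is included.  It is identical across clusters and
    cancels in the responsibilities, so production code drops it; it is kept
    when checking that each cluster marginal sums to one over the genotype
    sample space.
    """

    snp_ids: np.ndarray
    logxi: np.ndarray
    includes_het_factor: bool

    def __post_init__(self) -> None:
        self.logxi = np.asarray(self.logxi, dtype=float)
        if self.logxi.ndim != 2 or self.logxi.shape[1] != 3:
            raise ValueError("logxi must be a (G, 3) array")
        if not np.isfinite(self.logxi).all():
            raise ValueError("non-finite log marginal likelihood encountered")


@dataclass
class MixtureFit:
    """EM output: mixture proportions, responsibilities, and the EM trace."""

    snp_ids: np.ndarray
    pi: np.ndarray
    gamma: np.ndarray
    log_posterior_trace: np.ndarray
    n_iter: int
    converged: bool


@dataclass
class CallSet:
    """Per-SNP cluster calls plus the decision rule that produced them.

    ``calls`` uses codes 0 (null), +1 (higher MAF in cases), -1 (lower).
    Under the FDR rule, ``tau`` is the responsibility threshold and
    ``fdr_hat`` the model-based FDR estimate of the called set (mean null
    responsibility over called SNPs; 0 for an empty set).
    """

    snp_ids: np.ndarray
    calls: np.ndarray
    rule: str
    tau: float | None = None
    fdr_hat: float | None = None

    @property
    def labels(self) -> np.ndarray:
        return np.array(["0", "+", "-"], dtype=object)[
            np.select([self.calls == 0, self.calls == 1], [0, 1], default=2)
        ]

    @property
    def called_mask(self) -> np.ndarray:
        return self.calls != 0


# ---------------------------------------------------------------------------
# marginal likelihoods
# ---------------------------------------------------------------------------

def _log_het_factor(s: SuffStats) -> np.ndarray:
    return (s.h_x + s.h_y) * np.log(2.0)


def log_marginal_null(s: SuffStats, hp: Hyperparams, include_het_factor: bool = True) -> np.ndarray:
    """log xi_0: one shared MAF integrated against the conjugate Beta prior.

    xi_0 = 2^(h_x+h_y) * B(alpha + m, beta + 2N - m) / B(alpha, beta)
    with m = m_x + m_y and N = n_x + n_y.
    """
    m = s.m_x + s.m_y
    two_n = 2 * (s.n_x + s.n_y)
    out = betaln(hp.alpha + m, hp.beta + two_n - m) - betaln(hp.alpha, hp.beta)
    if include_het_factor:
        out = out + _log_het_factor(s)
    return np.asarray(out, dtype=float)


def _log_prob_greater(
    a_u: np.ndarray, b_u: np.ndarray, a_v: np.ndarray, b_v: np.ndarray,
    n_nodes: int = _GL_NODES,
) -> np.ndarray:
    """log P(U > V) for independent U ~ Beta(a_u, b_u), V ~ Beta(a_v, b_v).

    Gauss-Legendre quadrature of  integral f_V(v) * [1 - I_v(a_u, b_u)] dv,
    evaluated in log space.  The integration interval is clipped to the
    union of the two distributions' essential supports so the fixed-order
    rule keeps resolving the integrand when both Betas are concentrated.
    """
    a_u, b_u, a_v, b_v = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(p, dtype=float)) for p in (a_u, b_u, a_v, b_v))
    )
    lo = np.minimum(beta_dist.ppf(_PPF_EPS, a_u, b_u), beta_dist.ppf(_PPF_EPS, a_v, b_v))
    hi = np.maximum(
        beta_dist.ppf(1 - _PPF_EPS, a_u, b_u), beta_dist.ppf(1 - _PPF_EPS, a_v, b_v)
    )
    x, w = _gauss_legendre(n_nodes)
    half = 0.5 * (hi - lo)
    v = lo[..., None] + half[..., None] * (x + 1.0)  # (..., K)
    v = np.clip(v, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    log_f_v = (
        (a_v[..., None] - 1.0) * np.log(v)
        + (b_v[..., None] - 1.0) * np.log1p(-v)
        - betaln(a_v, b_v)[..., None]
    )
    # 1 - I_v(a, b) = I_{1-v}(b, a)
    tail = betainc(b_u[..., None], a_u[..., None], 1.0 - v)
    with np.errstate(divide="ignore"):
        log_tail = np.log(tail)
    log_terms = np.log(w * half[..., None]) + log_f_v + log_tail
    out = logsumexp(log_terms, axis=-1)
    return np.maximum(out, _LOG_FLOOR)


def prob_beta_greater(a1: float, b1: float, a2: float, b2: float) -> float:
    """P(U > V) for independent U ~ Beta(a1, b1), V ~ Beta(a2, b2)."""
    if min(a1, b1, a2, b2) <= 0:
        raise ValueError("Beta parameters must be positive")
    return float(np.exp(_log_prob_greater(a1, b1, a2, b2)[0]))


def log_marginal_signed(
    s: SuffStats, hp: Hyperparams, sign: str, include_het_factor: bool = True
) -> np.ndarray:
    """log xi_+ or log xi_- under the half-flat ordered-MAF prior.

    xi_+ = 2^(h_x+h_y) * 2 * [B(a_x, b_x)/B(alpha, beta)]
                           * [B(a_y, b_y)/B(alpha, beta)] * P(U > V)
    with a_d = alpha + m_d, b_d = beta + 2 n_d - m_d, U ~ Beta(a_x, b_x)
    (case posterior), V ~ Beta(a_y, b_y) (control posterior); xi_- uses
    P(U < V).
    """
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+' or '-'")
    a_x = hp.alpha + s.m_x
    b_x = hp.beta + 2 * s.n_x - s.m_x
    a_y = hp.alpha + s.m_y
    b_y = hp.beta + 2 * s.n_y - s.m_y
    log_c = (
        betaln(a_x, b_x) + betaln(a_y, b_y) - 2.0 * betaln(hp.alpha, hp.beta)
    )
    if sign == "+":
        log_p = _log_prob_greater(a_x, b_x, a_y, b_y)
    else:
        log_p = _log_prob_greater(a_y, b_y, a_x, b_x)
    out = np.log(2.0) + log_c + log_p
    if include_het_factor:
        out = out + _log_het_factor(s)
    return np.asarray(out, dtype=float)


def compute_log_marginals(
    stats: SuffStats, hp: Hyperparams, include_het_factor: bool = False
) -> LogMarginals:
    """All three cluster log marginals for every SNP, vectorized.

    Computed once and reused by every EM iteration (pi is the only parameter
    the EM updates).  The shared 2^(h_x+h_y) factor is dropped by default
    since it cancels in the responsibilities.
    """
    if stats.n_snps < 1:
        raise ValueError("need at least one SNP")
    # xi_k depends on (n_d, m_d) only, apart from the separable 2^h factor;
    # SNPs sharing counts are computed once (a large saving at GWAS scale)
    keys = np.stack([stats.n_x, stats.m_x, stats.n_y, stats.m_y], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    ustats = SuffStats(
        snp_ids=np.arange(len(uniq)).astype(object),
        n_x=uniq[:, 0], m_x=uniq[:, 1], h_x=np.zeros(len(uniq), dtype=np.int64),
        n_y=uniq[:, 2], m_y=uniq[:, 3], h_y=np.zeros(len(uniq), dtype=np.int64),
    )
    logxi = np.column_stack(
        [
            log_marginal_null(ustats, hp, include_het_factor=False),
            log_marginal_signed(ustats, hp, "+", include_het_factor=False),
            log_marginal_signed(ustats, hp, "-", include_het_factor=False),
        ]
    )[inverse]
    if include_het_factor:
        logxi = logxi + _log_het_factor(stats)[:, None]
    return LogMarginals(
        snp_ids=stats.snp_ids,
        logxi=logxi,
        includes_het_factor=include_het_factor,
    )


# ---------------------------------------------------------------------------
# EM and calling
# ---------------------------------------------------------------------------

def init_from_snpwise(
    stats: SuffStats, pvalues: np.ndarray, p_cut: float = 0.05
) -> np.ndarray:
    """Initial mixture proportions from SNP-wise raw p-values.

    SNPs with p < p_cut are provisionally labelled + or - by the sign of the
    case-minus-control MAF estimate; everything else starts in cluster 0.
    The label proportions, floored at 1/G per component and renormalized,
    form pi^(0).
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if len(pvalues) != stats.n_snps:
        raise ValueError("p-values and sufficient statistics differ in length")
    if not 0.0 < p_cut < 1.0:
        raise ValueError("p_cut must lie in (0, 1)")
    maf_x, maf_y = stats.group_maf()
    sig = pvalues < p_cut
    plus = sig & (maf_x > maf_y)
    minus = sig & (maf_x < maf_y)
    g = stats.n_snps
    counts = np.array([g - plus.sum() - minus.sum(), plus.sum(), minus.sum()], float)
    pi0 = np.maximum(counts / g, 1.0 / g)
    return pi0 / pi0.sum()


def responsibilities(lm: LogMarginals, pi: np.ndarray) -> np.ndarray:
    """Posterior cluster membership gamma_gk = pi_k xi_k / sum_j pi_j xi_j."""
    pi = np.asarray(pi, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
        raise ValueError("pi must lie on the probability simplex")
    with np.errstate(divide="ignore"):
        a = np.log(pi)[None, :] + lm.logxi
    return np.exp(a - logsumexp(a, axis=1)[:, None])


def _log_posterior(logxi: np.ndarray, pi: np.ndarray, b: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
    loglik = logsumexp(logpi[None, :] + logxi, axis=1).sum()
    prior = np.where(b > 1.0, (b - 1.0) * logpi, 0.0).sum()
    return float(loglik + prior)


def em_fit(
    lm: LogMarginals,
    hp: Hyperparams,
    pi0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureFit:
    """Estimate mixture proportions by EM with a Dirichlet MAP M-step.

    E-step: responsibilities in log space.  M-step:
    pi_k <- (sum_g gamma_gk + b_k - 1) / (G + sum_j (b_j - 1)).
    Iterates until the log posterior changes by less than ``tol``.
    """
    g = lm.logxi.shape[0]
    b = np.asarray(hp.pseudo_counts, dtype=float)
    pi = np.full(3, 1.0 / 3.0) if pi0 is None else np.asarray(pi0, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
        raise ValueError("initial pi must lie on the probability simplex")
    denom = g + (b - 1.0).sum()
    trace = []
    converged = False
    for it in range(1, max_iter + 1):
        gamma = responsibilities(lm, pi)
        pi = (gamma.sum(axis=0) + b - 1.0) / denom
        lp = _log_posterior(lm.logxi, pi, b)
        if not np.isfinite(lp):
            raise FloatingPointError(f"non-finite log posterior at iteration {it}")
        trace.append(lp)
        if it > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    gamma = responsibilities(lm, pi)
    return MixtureFit(
        snp_ids=lm.snp_ids,
        pi=pi,
        gamma=gamma,
        log_posterior_trace=np.asarray(trace),
        n_iter=len(trace),
        converged=converged,
    )


def call_max_posterior(fit: MixtureFit) -> CallSet:
    """Assign each SNP to its highest-responsibility cluster (ties -> null)."""
    gamma = fit.gamma
    best = np.max(gamma, axis=1)
    calls = np.zeros(gamma.shape[0], dtype=np.int8)
    # a tie involving cluster 0 resolves to 0 (conservative)
    plus = (gamma[:, 1] == best) & (gamma[:, 0] < best)
    minus = (gamma[:, 2] == best) & (gamma[:, 0] < best) & ~plus
    calls[plus] = 1
    calls[minus] = -1
    return CallSet(snp_ids=fit.snp_ids, calls=calls, rule="max_posterior")


def call_at_fdr(fit: MixtureFit, nominal: float | None = None, hp: Hyperparams | None = None) -> CallSet:
    """Call SNPs whose effective-cluster responsibility exceeds a threshold tau.

    Candidate thresholds are the distinct values of max(gamma_+, gamma_-).
    For each threshold-defined called set, the model-based FDR estimate is
    the mean null responsibility gamma_0 over the set.  The estimate is not
    monotone in tau, so the rule returns the largest threshold-defined set
    whose estimate stays at or below the nominal level.  Called SNPs get the
    sign of the larger of gamma_+ and gamma_-.
    """
    if nominal is None:
        nominal = hp.nominal_fdr if hp is not None else 0.05
    if not 0.0 < nominal < 1.0:
        raise ValueError("nominal FDR must lie in (0, 1)")
    gamma = fit.gamma
    g = gamma.shape[0]
    score = np.maximum(gamma[:, 1], gamma[:, 2])
    order = np.argsort(-score, kind="stable")
    s_sorted = score[order]
    cum_fdr = np.cumsum(gamma[order, 0]) / np.arange(1, g + 1)
    # prefix of length r is threshold-definable iff it does not split a tie
    boundary = np.r_[s_sorted[:-1] > s_sorted[1:], True]
    feasible = boundary & (cum_fdr <= nominal)
    calls = np.zeros(g, dtype=np.int8)
    if feasible.any():
        r = int(np.nonzero(feasible)[0][-1])  # largest qualifying set
        tau = float(s_sorted[r + 1]) if r + 1 < g else 0.0
        called = order[: r + 1]
        calls[called] = np.where(gamma[called, 1] >= gamma[called, 2], 1, -1)
        fdr_hat = float(cum_fdr[r])
    else:
        tau = 1.0
        fdr_hat = 0.0
    return CallSet(
        snp_ids=fit.snp_ids, calls=calls, rule="fdr_threshold", tau=tau, fdr_hat=fdr_hat
    )


def fit_mixture(
    stats: SuffStats,
    hp: Hyperparams,
    snpwise_pvalues: np.ndarray | None = None,
    p_cut: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureFit:
    """Convenience wrapper: marginals + initialization + EM in one call."""
    lm = compute_log_marginals(stats, hp)
    if snpwise_pvalues is None:
        pi0 = None
    else:
        pi0 = init_from_snpwise(stats, snpwise_pvalues, p_cut)
    return em_fit(lm, hp, pi0=pi0, tol=tol, max_iter=max_iter)
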