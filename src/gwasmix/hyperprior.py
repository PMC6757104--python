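"""Beta prior elicitation for minor-allele frequencies by moment matching.

The mixture model needs a conjugate Beta(alpha, beta) prior on the MAF scale.
Two routes are provided: a reference prior obtained by moment-matching a
Beta(2, 5) truncated to the observed MAF range, and an empirical prior
moment-matched to the observed per-SNP MAF distribution.  Truncated Betas
are not conjugate for the multinomial genotype likelihood, hence the
untruncated Beta approximation with identical mean and variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betainc, betaln

from .genotype_io import SuffStats

#: Dirichlet pseudo counts treated as a weak prior on cluster proportions
DEFAULT_PSEUDO_COUNTS: tuple[float, float, float] = (3.0, 3.0, 3.0)
#: documented alternatives; (5,5,5) gives the same calls, (20,20,20) is stronger
PSEUDO_COUNT_PRESETS = {
    "weak": (3.0, 3.0, 3.0),
    "moderate": (5.0, 5.0, 5.0),
    "strong": (20.0, 20.0, 20.0),
}
DEFAULT_NOMINAL_FDR: float = 0.05


@dataclass(frozen=True)
class Hyperparams:
    """Fixed hyper-parameters of the hierarchical model.

    alpha, beta : shape of the Beta prior on the MAF scale.
    pseudo_counts : Dirichlet pseudo counts (b0, b+, b-) on the cluster
        proportions; each must be >= 1 so the MAP M-step stays well defined.
    nominal_fdr : target false discovery rate for the calling rule.
    """

    alpha: float
    beta: float
    pseudo_counts: tuple[float, float, float] = DEFAULT_PSEUDO_COUNTS
    nominal_fdr: float = DEFAULT_NOMINAL_FDR

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if len(self.pseudo_counts) != 3 or any(b < 1 for b in self.pseudo_counts):
            raise ValueError("pseudo_counts must be three values >= 1")
        if not 0 < self.nominal_fdr < 1:
            raise ValueError("nominal_fdr must lie in (0, 1)")


def truncated_beta_moments(
    alpha: float, beta: float, lower: float, upper: float
) -> tuple[float, float]:
    """Mean and variance of a Beta(alpha, beta) truncated to (lower, upper).

    Uses the exact identity
    ``E[theta^k | L < theta < U] =
    [B(a+k, b)/B(a, b)] * [I_U(a+k, b) - I_L(a+k, b)] / [I_U(a, b) - I_L(a, b)]``
    with I the regularized incomplete beta function.
    """
    if not 0.0 <= lower < upper <= 1.0:
        raise ValueError("need 0 <= lower < upper <= 1")
    mass = betainc(alpha, beta, upper) - betainc(alpha, beta, lower)
    if mass < 1e-12:
        raise ValueError("truncation interval carries negligible probability mass")

    def raw_moment(k: int) -> float:
        ratio = np.exp(betaln(alpha + k, beta) - betaln(alpha, beta))
        part = betainc(alpha + k, beta, upper) - betainc(alpha + k, beta, lower)
        return float(ratio * part / mass)

    m1 = raw_moment(1)
    m2 = raw_moment(2)
    return m1, m2 - m1 * m1


def moment_match(mean: float, variance: float) -> tuple[float, float]:
    """Beta(alpha, beta) with the given mean and variance.

    ``alpha = m (m(1-m)/v - 1)``, ``beta = (1-m) (m(1-m)/v - 1)``.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie in (0, 1)")
    if not 0.0 < variance < mean * (1.0 - mean):
        raise ValueError("no Beta distribution has this mean/variance pair")
    nu = mean * (1.0 - mean) / variance - 1.0
    return mean * nu, (1.0 - mean) * nu


def reference_prior(
    lower: float = 0.05,
    pseudo_counts: tuple[float, float, float] = DEFAULT_PSEUDO_COUNTS,
    nominal_fdr: float = DEFAULT_NOMINAL_FDR,
) -> Hyperparams:
    """Moment-matched Beta approximation of Beta(2, 5) truncated to (lower, 0.5).

    The recommended MAF prior when the data are too small to estimate an
    empirical MAF distribution; ``lower`` should be the minimum observed
    post-QC MAF.
    """
    if not 0.0 <= lower < 0.5:
        raise ValueError("lower must lie in [0, 0.5)")
    mean, var = truncated_beta_moments(2.0, 5.0, lower, 0.5)
    a, b = moment_match(mean, var)
    return Hyperparams(a, b, pseudo_counts=pseudo_counts, nominal_fdr=nominal_fdr)


def empirical_prior(
    stats: SuffStats,
    pseudo_counts: tuple[float, float, float] = DEFAULT_PSEUDO_COUNTS,
    nominal_fdr: float = DEFAULT_NOMINAL_FDR,
) -> Hyperparams:
    """Moment-match the observed pooled per-SNP MAF distribution to a Beta.

    The pooled (cases + controls) MAF estimate describes the common frequency
    scale; group differences are left to the mixture components.
    """
    if stats.n_snps < 2:
        raise ValueError("need at least 2 SNPs for an empirical prior")
    maf = stats.pooled_maf()
    if maf.max() == maf.min():
        raise ValueError("observed MAFs have zero variance; use reference_prior")
    mean = float(maf.mean())
    var = float(maf.var(ddof=1))
    a, b = moment_match(mean, var)
    return Hyperparams(a, b, pseudo_counts=pseudo_counts, nominal_fdr=nominal_fdr)
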