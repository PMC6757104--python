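"""Synthetic case-control GWAS generator with known cluster structure.

SNPs are independent.  Null SNPs share one MAF between cases and controls;
effective SNPs get two i.i.d. truncated-Beta MAF draws assigned by order
statistics (the larger value goes to cases for cluster +, to controls for
cluster -), which is the generative counterpart of the half-flat ordered
prior.  Genotypes are Hardy-Weinberg trinomial draws, i.e. the dosage of a
subject is Binomial(2, theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .genotype_io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class SimConfig:
    """One simulation scenario.

    Defaults reproduce the reference design: MAFs from Beta(2, 5) truncated
    to (0.05, 0.5), half cases / half controls, effective SNPs split evenly
    between clusters + and -.
    """

    n_snps: int = 20_000
    n_effective: int = 200
    n_cases: int = 100
    n_controls: int = 100
    frac_plus: float = 0.5
    maf_alpha: float = 2.0
    maf_beta: float = 5.0
    maf_lower: float = 0.05
    maf_upper: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0
    scenario_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.n_effective > self.n_snps:
            raise ValueError("n_effective cannot exceed n_snps")
        if not 0.0 <= self.frac_plus <= 1.0:
            raise ValueError("frac_plus must lie in [0, 1]")
        if not 0.0 <= self.maf_lower < self.maf_upper <= 1.0:
            raise ValueError("need 0 <= maf_lower < maf_upper <= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class SimTruth:
    """Generative truth per SNP: cluster label and the MAF pair used."""

    snp_ids: np.ndarray
    z: np.ndarray  # 0 null, +1, -1
    theta_case: np.ndarray
    theta_control: np.ndarray

    @property
    def effective_mask(self) -> np.ndarray:
        return self.z != 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "z": self.z,
                "theta_case": self.theta_case,
                "theta_control": self.theta_control,
            }
        )


def draw_truncated_beta(
    alpha: float,
    beta: float,
    lower: float,
    upper: float,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """i.i.d. draws from Beta(alpha, beta) truncated to (lower, upper).

    Exact inverse-CDF sampling: quantiles of U * [F(u) - F(l)] + F(l);
    no rejection loop, so the draw count per random stream is fixed.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    f_lo = beta_dist.cdf(lower, alpha, beta)
    f_hi = beta_dist.cdf(upper, alpha, beta)
    if f_hi - f_lo < 1e-12:
        raise ValueError("truncation interval carries negligible probability mass")
    u = rng.uniform(size=size)
    draws = beta_dist.ppf(f_lo + u * (f_hi - f_lo), alpha, beta)
    return np.clip(draws, np.nextafter(lower, 1.0), np.nextafter(upper, 0.0))


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Generate one dataset plus its truth labels, reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    g = cfg.n_snps
    n_plus = round(cfg.frac_plus * cfg.n_effective)
    n_minus = cfg.n_effective - n_plus

    z = np.zeros(g, dtype=np.int8)
    pos = rng.permutation(g)
    z[pos[:n_plus]] = 1
    z[pos[n_plus : cfg.n_effective]] = -1

    theta_case = np.empty(g)
    theta_control = np.empty(g)
    null = z == 0
    theta_null = draw_truncated_beta(
        cfg.maf_alpha, cfg.maf_beta, cfg.maf_lower, cfg.maf_upper, int(null.sum()), rng
    )
    theta_case[null] = theta_null
    theta_control[null] = theta_null
    n_eff = cfg.n_effective
    if n_eff:
        pair = draw_truncated_beta(
            cfg.maf_alpha, cfg.maf_beta, cfg.maf_lower, cfg.maf_upper, 2 * n_eff, rng
        ).reshape(n_eff, 2)
        lo, hi = pair.min(axis=1), pair.max(axis=1)
        eff_idx = pos[:n_eff]
        is_plus = z[eff_idx] == 1
        theta_case[eff_idx] = np.where(is_plus, hi, lo)
        theta_control[eff_idx] = np.where(is_plus, lo, hi)

    n = cfg.n_cases + cfg.n_controls
    dosages = np.empty((g, n), dtype=np.int8)
    dosages[:, : cfg.n_cases] = rng.binomial(
        2, theta_case[:, None], size=(g, cfg.n_cases)
    )
    dosages[:, cfg.n_cases :] = rng.binomial(
        2, theta_control[:, None], size=(g, cfg.n_controls)
    )
    if cfg.missing_rate > 0:
        mask = rng.uniform(size=dosages.shape) < cfg.missing_rate
        dosages[mask] = MISSING

    width = len(str(g))
    snp_ids = np.array([f"snp{i:0{width}d}" for i in range(g)], dtype=object)
    subject_ids = np.array(
        [f"case{i:04d}" for i in range(cfg.n_cases)]
        + [f"ctrl{i:04d}" for i in range(cfg.n_controls)],
        dtype=object,
    )
    phenotype = np.r_[
        np.ones(cfg.n_cases, dtype=np.int8), np.zeros(cfg.n_controls, dtype=np.int8)
    ]
    gm = GenotypeMatrix(
        snp_ids=snp_ids, dosages=dosages, phenotype=phenotype, subject_ids=subject_ids
    )
    truth = SimTruth(
        snp_ids=snp_ids, z=z, theta_case=theta_case, theta_control=theta_control
    )
    return gm, truth


#: the four generating MAF laws studied for prior misspecification
MAF_SETTINGS: tuple[tuple[float, float], ...] = (
    (2.0, 5.0),
    (2.0, 4.0),
    (1.5, 3.5),
    (1.5, 5.5),
)


def paper_scenarios(seed: int = 0) -> list[SimConfig]:
    """The benchmark scenario grid: 4 MAF laws x G in {1e3, 2e4, 5e5} x n in {200, 1000}.

    G = 500,000 and G = 20,000 rows carry 200 effective SNPs; the G = 1,000
    rows are scaled to 20 effective SNPs to keep the effective fraction
    comparable.
    """
    out = []
    for a, b in MAF_SETTINGS:
        for g in (1_000, 20_000, 500_000):
            for n_total in (200, 1_000):
                n_eff = 200 if g >= 20_000 else 20
                out.append(
                    SimConfig(
                        n_snps=g,
                        n_effective=n_eff,
                        n_cases=n_total // 2,
                        n_controls=n_total // 2,
                        maf_alpha=a,
                        maf_beta=b,
                        seed=seed,
                        scenario_id=f"beta{a:g}_{b:g}_G{g}_n{n_total}",
                    )
                )
    return out


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of a scenario with a different seed."""
    return replace(cfg, seed=seed)
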