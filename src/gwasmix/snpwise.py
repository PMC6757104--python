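"""Traditional SNP-wise association testing: the comparator for the mixture.

Per-SNP Cochran-Armitage trend tests (vectorized, the default in simulation
benchmarks) or per-SNP logistic regressions, Benjamini-Hochberg adjustment,
and a permutation-based one-sided validation procedure for candidate SNPs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .genotype_io import MISSING, GenotypeMatrix, SuffStats, sufficient_stats


def genotype_table(stats: SuffStats) -> tuple[np.ndarray, np.ndarray]:
    """Recover per-SNP genotype counts (hom-ref, het, hom-alt) per group."""
    hom_alt_x = (stats.m_x - stats.h_x) // 2
    cases = np.column_stack(
        [stats.n_x - stats.h_x - hom_alt_x, stats.h_x, hom_alt_x]
    )
    hom_alt_y = (stats.m_y - stats.h_y) // 2
    controls = np.column_stack(
        [stats.n_y - stats.h_y - hom_alt_y, stats.h_y, hom_alt_y]
    )
    return cases, controls


def trend_test(stats: SuffStats) -> pd.DataFrame:
    """Cochran-Armitage trend test with scores (0, 1, 2) per SNP.

    Two-sided p-values from the normal approximation with the
    margin-conditional (hypergeometric) variance.  Degenerate tables
    (a single genotype column occupied, or no case/control contrast)
    get statistic 0 and p = 1 with a flag.
    """
    cases, controls = genotype_table(stats)
    t = np.array([0.0, 1.0, 2.0])
    r = cases.astype(float)
    n_col = (cases + controls).astype(float)
    big_r = r.sum(axis=1)
    big_n = n_col.sum(axis=1)
    u = (r * t).sum(axis=1) - big_r / big_n * (n_col * t).sum(axis=1)
    s2 = (n_col * t**2).sum(axis=1) / big_n - ((n_col * t).sum(axis=1) / big_n) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        var = big_r * (big_n - big_r) / (big_n - 1.0) * s2
        z = u / np.sqrt(var)
    degenerate = ~np.isfinite(z) | (var <= 0)
    z = np.where(degenerate, 0.0, z)
    p = np.where(degenerate, 1.0, 2.0 * norm.sf(np.abs(z)))
    return pd.DataFrame(
        {
            "snp_id": stats.snp_ids,
            "statistic": z,
            "p_raw": np.clip(p, np.finfo(float).tiny, 1.0),
            "degenerate": degenerate,
        }
    )


def _logistic_one(y: np.ndarray, dosage: np.ndarray) -> tuple[float, float, bool]:
    """Wald z and its standard error for one SNP; flags degenerate fits."""
    import statsmodels.api as sm

    keep = dosage != MISSING
    yy, dd = y[keep].astype(float), dosage[keep].astype(float)
    if dd.std() == 0 or yy.std() == 0:
        return 0.0, np.nan, True
    x = sm.add_constant(dd)
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(yy, x).fit(disp=0, maxiter=100)
        coef, se = res.params[1], res.bse[1]
        if not np.isfinite(coef) or not np.isfinite(se) or se > 50:
            return 0.0, np.nan, True
        return float(coef), float(se), False
    except Exception:
        return 0.0, np.nan, True


def logistic_test(gm: GenotypeMatrix, sided: str = "two") -> pd.DataFrame:
    """Per-SNP logistic regression of case status on additive dosage.

    One-sided p-values (``sided='one'``) test the risk direction: positive
    log-odds, i.e. higher MAF in cases.  Separation or degenerate dosage
    gives a flagged row with p = 1.
    """
    if sided not in ("two", "one"):
        raise ValueError("sided must be 'two' or 'one'")
    y = gm.phenotype
    rows = []
    for g in range(gm.n_snps):
        coef, se, degen = _logistic_one(y, gm.dosages[g])
        if degen:
            rows.append((gm.snp_ids[g], 0.0, 1.0, np.nan, np.nan, np.nan, True))
            continue
        z = coef / se
        p = norm.sf(z) if sided == "one" else 2.0 * norm.sf(abs(z))
        or_ = np.exp(coef)
        lo, hi = np.exp(coef - 1.96 * se), np.exp(coef + 1.96 * se)
        rows.append((gm.snp_ids[g], z, max(p, np.finfo(float).tiny), or_, lo, hi, False))
    return pd.DataFrame(
        rows,
        columns=["snp_id", "statistic", "p_raw", "or", "or_ci_low", "or_ci_high", "degenerate"],
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        raise ValueError("no p-values to adjust")
    if ((pvalues <= 0) | (pvalues > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


def snpwise_test(
    stats: SuffStats, method: str = "trend", gm: GenotypeMatrix | None = None
) -> pd.DataFrame:
    """Run the SNP-wise test plus BH adjustment; the standard baseline table."""
    if method == "trend":
        table = trend_test(stats)
    elif method == "logistic":
        if gm is None:
            raise ValueError("logistic tests need the genotype matrix")
        table = logistic_test(gm, sided="two")
    else:
        raise ValueError(f"unknown method {method!r}")
    table["p_bh"] = bh_adjust(table["p_raw"].to_numpy())
    return table


def permutation_validation(
    gm: GenotypeMatrix,
    candidate_snps,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One-sided logistic permutation p-values for a candidate SNP list.

    The phenotype is permuted ``n_perm`` times, with the same permutations
    shared across candidates; the permutation p-value is the add-one
    estimator (1 + #{perm stat >= observed}) / (1 + n_perm), and BH is
    applied over the candidates only.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    candidate_snps = list(candidate_snps)
    index = {s: i for i, s in enumerate(gm.snp_ids)}
    missing_ids = [s for s in candidate_snps if s not in index]
    if missing_ids:
        raise ValueError("candidate SNPs not in data: " + ", ".join(map(str, missing_ids)))
    rows = [index[s] for s in candidate_snps]
    y = gm.phenotype
    obs = np.array(
        [_wald_z(y, gm.dosages[r]) for r in rows]
    )
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(rows), dtype=np.int64)
    for _ in range(n_perm):
        yp = rng.permutation(y)
        for j, r in enumerate(rows):
            if _wald_z(yp, gm.dosages[r]) >= obs[j]:
                exceed[j] += 1
    p_perm = (1.0 + exceed) / (1.0 + n_perm)
    asymptotic = logistic_test(gm.subset(np.isin(np.arange(gm.n_snps), rows)), sided="one")
    asym = asymptotic.set_index("snp_id").loc[candidate_snps]
    return pd.DataFrame(
        {
            "snp_id": candidate_snps,
            "statistic": obs,
            "p_raw": asym["p_raw"].to_numpy(),
            "or": asym["or"].to_numpy(),
            "or_ci_low": asym["or_ci_low"].to_numpy(),
            "or_ci_high": asym["or_ci_high"].to_numpy(),
            "p_perm": p_perm,
            "p_bh": bh_adjust(p_perm),
        }
    )


def _wald_z(y: np.ndarray, dosage: np.ndarray) -> float:
    coef, se, degen = _logistic_one(y, dosage)
    return -np.inf if degen else coef / se
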