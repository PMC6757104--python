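"""Genotype/phenotype I/O, quality control, and per-SNP sufficient statistics.

Genotypes are minor-allele dosages in {0, 1, 2} stored SNP-by-subject.
Orientation to the minor allele is decided once at load time on the pooled
sample (cases + controls), so that every stored pooled MAF is <= 0.5.
Missing genotypes are coded :data:`MISSING` and handled complete-case per
SNP: the per-group subject count ``n_d`` varies across SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype inside the dosage matrix
MISSING: int = -1

#: tokens accepted as "missing" in genotype TSV files
_MISSING_TOKENS = {".", "NA", "na", ""}


@dataclass
class GenotypeMatrix:
    """SNP x subject minor-allele dosage matrix with case/control labels.

    Attributes
    ----------
    snp_ids : np.ndarray of str, shape (G,)
    dosages : np.ndarray of int8, shape (G, n)
        Values in {0, 1, 2} or :data:`MISSING`.
    phenotype : np.ndarray of int8, shape (n,)
        1 = case, 0 = control.
    subject_ids : np.ndarray of str, shape (n,)
    flipped : np.ndarray of bool, shape (G,)
        True where the input allele coding was swapped (2 - dosage) to make
        the stored allele the pooled minor allele.
    """

    snp_ids: np.ndarray
    dosages: np.ndarray
    phenotype: np.ndarray
    subject_ids: np.ndarray
    flipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.flipped is None:
            self.flipped = np.zeros(len(self.snp_ids), dtype=bool)
        valid = (self.dosages == MISSING) | (
            (self.dosages >= 0) & (self.dosages <= 2)
        )
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or MISSING")
        if len(np.unique(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("SNP IDs must be unique")
        if not ((self.phenotype == 1).any() and (self.phenotype == 0).any()):
            raise ValueError("phenotype needs at least one case and one control")
        if self.dosages.shape != (len(self.snp_ids), len(self.subject_ids)):
            raise ValueError("dosage matrix shape does not match IDs")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subset(self, snp_mask: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the SNPs where ``snp_mask`` is True."""
        return GenotypeMatrix(
            snp_ids=self.snp_ids[snp_mask],
            dosages=self.dosages[snp_mask],
            phenotype=self.phenotype,
            subject_ids=self.subject_ids,
            flipped=self.flipped[snp_mask],
        )


@dataclass
class SuffStats:
    """Per-SNP, per-group sufficient statistics of the genotype likelihood.

    For group ``d`` (x = cases, y = controls): ``n_d`` non-missing subjects,
    ``m_d`` total minor-allele count, ``h_d`` heterozygote count.  Under
    Hardy-Weinberg sampling these are all the likelihood needs.
    """

    snp_ids: np.ndarray
    n_x: np.ndarray
    m_x: np.ndarray
    h_x: np.ndarray
    n_y: np.ndarray
    m_y: np.ndarray
    h_y: np.ndarray

    def __post_init__(self) -> None:
        for name in ("n_x", "m_x", "h_x", "n_y", "m_y", "h_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def pooled_maf(self) -> np.ndarray:
        """Pooled minor-allele frequency estimate (m_x+m_y)/(2 n_x + 2 n_y)."""
        return (self.m_x + self.m_y) / (2.0 * (self.n_x + self.n_y))

    def group_maf(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-group MAF estimates (cases, controls)."""
        return self.m_x / (2.0 * self.n_x), self.m_y / (2.0 * self.n_y)

    def swapped(self) -> "SuffStats":
        """Exchange the case and control blocks (used in symmetry checks)."""
        return SuffStats(
            snp_ids=self.snp_ids,
            n_x=self.n_y, m_x=self.m_y, h_x=self.h_y,
            n_y=self.n_x, m_y=self.m_x, h_y=self.h_x,
        )


def _orient_to_minor(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip dosage coding (2 - d) where the coded allele is the pooled major one."""
    miss = dosages == MISSING
    counts = np.where(miss, 0, dosages).sum(axis=1)
    n_obs = (~miss).sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq = counts / np.maximum(2 * n_obs, 1)
    flip = freq > 0.5
    out = dosages.copy()
    out[flip] = np.where(miss[flip], MISSING, 2 - dosages[flip])
    return out, flip


def _read_phenotype(path) -> pd.Series:
    pheno = pd.read_csv(path, sep="\t", dtype={0: str})
    if pheno.shape[1] != 2:
        raise ValueError(f"phenotype file {path} must have exactly 2 columns")
    pheno.columns = ["subject_id", "status"]
    status = pd.to_numeric(pheno["status"], errors="raise")
    if not status.isin([0, 1]).all():
        raise ValueError("phenotype status must be 0 (control) or 1 (case)")
    return pd.Series(status.to_numpy(np.int8), index=pheno["subject_id"].to_numpy())


def read_genotypes(path, format: str = "tsv", phenotype_path=None) -> GenotypeMatrix:
    """Read a genotype matrix plus binary phenotype into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path : str or Path
        Genotype TSV (SNPs as rows, header of subject IDs) or a VCF.
    format : {"tsv", "vcf"}
    phenotype_path : str or Path
        Two-column TSV mapping subject ID to status (1 = case, 0 = control).
        Subjects are taken in phenotype-file order; a phenotype subject absent
        from the genotype file is an error.
    """
    if phenotype_path is None:
        raise ValueError("phenotype_path is required")
    pheno = _read_phenotype(phenotype_path)

    if format == "tsv":
        snp_ids, dosages, subj = _read_tsv(path)
    elif format == "vcf":
        snp_ids, dosages, subj = _read_vcf(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    subj_index = {s: i for i, s in enumerate(subj)}
    unknown = [s for s in pheno.index if s not in subj_index]
    if unknown:
        raise ValueError(
            "phenotype subjects missing from genotype data: " + ", ".join(map(str, unknown))
        )
    dropped = [s for s in subj if s not in set(pheno.index)]
    if dropped:
        logger.warning("dropping %d genotyped subjects without phenotype", len(dropped))
    order = [subj_index[s] for s in pheno.index]
    dosages = dosages[:, order]
    dosages, flipped = _orient_to_minor(dosages)
    return GenotypeMatrix(
        snp_ids=np.asarray(snp_ids, dtype=object),
        dosages=dosages,
        phenotype=pheno.to_numpy(),
        subject_ids=np.asarray(list(pheno.index), dtype=object),
        flipped=flipped,
    )


def _read_tsv(path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    snp_ids = df.iloc[:, 0].to_numpy(dtype=object)
    subj = list(df.columns[1:])
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    dosages = np.empty(raw.shape, dtype=np.int8)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = raw[i, j]
            tok = "" if tok is None or (isinstance(tok, float) and np.isnan(tok)) else str(tok).strip()
            if tok in _MISSING_TOKENS:
                dosages[i, j] = MISSING
            elif tok in ("0", "1", "2"):
                dosages[i, j] = int(tok)
            else:
                raise ValueError(
                    f"malformed dosage token {tok!r} at line {i + 2} of {path}"
                )
    return snp_ids, dosages, subj


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subj = list(vcf.samples)
    snp_ids, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic record %s", var.ID or var.POS)
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        if any(len(g) != 3 for g in gts):
            logger.warning("skipping non-diploid record %s", var.ID or var.POS)
            continue
        row = np.empty(len(subj), dtype=np.int8)
        for j, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            row[j] = MISSING if a0 < 0 or a1 < 0 else (a0 > 0) + (a1 > 0)
        snp_ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        rows.append(row)
    vcf.close()
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    return np.asarray(snp_ids, dtype=object), np.vstack(rows), subj


def write_genotypes(gm: GenotypeMatrix, genotype_path, phenotype_path=None) -> None:
    """Write the genotype TSV (and optionally the phenotype TSV) back to disk."""
    body = gm.dosages.astype(object)
    body[gm.dosages == MISSING] = "NA"
    df = pd.DataFrame(body, columns=list(gm.subject_ids))
    df.insert(0, "snp_id", gm.snp_ids)
    df.to_csv(genotype_path, sep="\t", index=False)
    if phenotype_path is not None:
        pd.DataFrame(
            {"subject_id": gm.subject_ids, "status": gm.phenotype}
        ).to_csv(phenotype_path, sep="\t", index=False)


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic SNP.

    Conditions on the observed allele counts and sums the probability of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed one (the standard two-sided exact test).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * n_hom_alt + n_het
    if n_rare > n:  # orient to the rarer allele
        n_rare = 2 * n - n_rare
    # possible heterozygote counts share the parity of n_rare
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        gammaln(n + 1)
        - gammaln(hom_r + 1) - gammaln(hets + 1) - gammaln(hom_c + 1)
        + hets * np.log(2.0)
    )
    logp -= logsumexp(logp)
    idx = np.nonzero(hets == n_het)[0]
    if idx.size == 0:  # inconsistent table (cannot happen for real counts)
        return 1.0
    p_obs = logp[idx[0]]
    p = float(np.exp(logp[logp <= p_obs + 1e-12]).sum())
    return min(p, 1.0)


def apply_qc(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter SNPs on call rate, pooled MAF, and HWE (exact test in controls).

    Returns the filtered matrix and a per-SNP QC report listing every input
    SNP with its metric values and per-filter pass flags.
    """
    for thr in (min_call_rate, min_maf, hwe_alpha):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    miss = gm.dosages == MISSING
    call_rate = 1.0 - miss.mean(axis=1)
    counts = np.where(miss, 0, gm.dosages).sum(axis=1)
    n_obs = (~miss).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = counts / np.maximum(2 * n_obs, 1)
    maf = np.minimum(maf, 1.0 - maf)

    ctrl = gm.phenotype == 0
    hwe_p = np.ones(gm.n_snps)
    for g in range(gm.n_snps):
        d = gm.dosages[g, ctrl]
        d = d[d != MISSING]
        hwe_p[g] = hwe_exact_pvalue(
            int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())
        )

    pass_call = call_rate >= min_call_rate
    pass_maf = maf >= min_maf
    pass_hwe = hwe_p >= hwe_alpha
    keep = pass_call & pass_maf & pass_hwe
    report = pd.DataFrame(
        {
            "snp_id": gm.snp_ids,
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "pass_call_rate": pass_call,
            "pass_maf": pass_maf,
            "pass_hwe": pass_hwe,
            "pass": keep,
        }
    )
    if not keep.any():
        raise ValueError(
            "all SNPs removed by QC; relax min_call_rate/min_maf/hwe_alpha"
        )
    return gm.subset(keep), report


def sufficient_stats(gm: GenotypeMatrix) -> SuffStats:
    """Reduce a genotype matrix to per-SNP, per-group sufficient statistics."""
    case = gm.phenotype == 1
    out = {}
    for tag, mask in (("x", case), ("y", ~case)):
        d = gm.dosages[:, mask]
        miss = d == MISSING
        out["n_" + tag] = (~miss).sum(axis=1)
        out["m_" + tag] = np.where(miss, 0, d).sum(axis=1)
        out["h_" + tag] = (d == 1).sum(axis=1)
    bad = (out["n_x"] == 0) | (out["n_y"] == 0)
    if bad.any():
        raise ValueError(
            "SNPs with no observed genotypes in one group cannot be modelled: "
            + ", ".join(map(str, gm.snp_ids[bad][:5]))
        )
    return SuffStats(snp_ids=gm.snp_ids, **out)
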