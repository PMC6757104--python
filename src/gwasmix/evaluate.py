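"""Scoring against simulation truth and replicated method comparison.

Realized (true) FDR is the proportion of truly non-effective SNPs among the
SNPs called significant; sensitivity is the proportion of truly effective
SNPs called significant.  A call to either effective cluster counts as a
true positive regardless of its sign; directional correctness is reported
separately as ``sign_agreement``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, wilcoxon

from .genotype_io import sufficient_stats
from .hyperprior import empirical_prior, reference_prior
from .mixture import CallSet, call_at_fdr, compute_log_marginals, em_fit, init_from_snpwise
from .simulate import SimConfig, SimTruth, simulate_dataset, with_seed
from .snpwise import snpwise_test

#: analysis arms of the benchmark
METHODS: tuple[str, ...] = ("snpwise", "mixture_ref", "mixture_emp")


def score_calls(calls: CallSet, truth: SimTruth) -> tuple[float, float]:
    """(realized FDR, sensitivity) of a call set against simulation truth."""
    if len(calls.snp_ids) != len(truth.snp_ids) or (
        calls.snp_ids != truth.snp_ids
    ).any():
        raise ValueError("call set and truth are not aligned on SNP IDs")
    called = calls.called_mask
    effective = truth.effective_mask
    n_called = int(called.sum())
    fdr = float((called & ~effective).sum() / n_called) if n_called else 0.0
    n_eff = int(effective.sum())
    sens = float((called & effective).sum() / n_eff) if n_eff else 0.0
    return fdr, sens


def sign_agreement(calls: CallSet, truth: SimTruth) -> float:
    """Fraction of correctly-called effective SNPs whose direction also matches."""
    tp = calls.called_mask & truth.effective_mask
    if not tp.any():
        return float("nan")
    return float((calls.calls[tp] == truth.z[tp]).mean())


def snpwise_calls(table: pd.DataFrame, stats, nominal: float) -> CallSet:
    """CallSet from a SNP-wise test table: BH-significant SNPs, signed by MAF diff."""
    maf_x, maf_y = stats.group_maf()
    sig = table["p_bh"].to_numpy() <= nominal
    calls = np.zeros(len(table), dtype=np.int8)
    calls[sig] = np.where(maf_x[sig] >= maf_y[sig], 1, -1)
    return CallSet(snp_ids=stats.snp_ids, calls=calls, rule="bh")


def analyze_replicate(
    cfg: SimConfig,
    methods=METHODS,
    nominal_fdr: float = 0.05,
    pseudo_counts: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> list[dict]:
    """Simulate one dataset and run every requested analysis arm on it."""
    gm, truth = simulate_dataset(cfg)
    stats = sufficient_stats(gm)
    table = snpwise_test(stats, method="trend")
    rows = []

    def record(method: str, calls: CallSet) -> None:
        fdr, sens = score_calls(calls, truth)
        rows.append(
            {
                "scenario": cfg.scenario_id or "ad-hoc",
                "seed": cfg.seed,
                "method": method,
                "n_called": int(calls.called_mask.sum()),
                "fdr": fdr,
                "sensitivity": sens,
                "sign_agreement": sign_agreement(calls, truth),
            }
        )

    if "snpwise" in methods:
        record("snpwise", snpwise_calls(table, stats, nominal_fdr))

    mixture_arms = [m for m in methods if m.startswith("mixture")]
    if mixture_arms:
        p_raw = table["p_raw"].to_numpy()
        pi0 = init_from_snpwise(stats, p_raw)
        maf_lower = float(np.clip(stats.pooled_maf().min(), 0.0, 0.49))
        for method in mixture_arms:
            if method == "mixture_ref":
                hp = reference_prior(
                    maf_lower, pseudo_counts=pseudo_counts, nominal_fdr=nominal_fdr
                )
            elif method == "mixture_emp":
                hp = empirical_prior(
                    stats, pseudo_counts=pseudo_counts, nominal_fdr=nominal_fdr
                )
            else:
                raise ValueError(f"unknown method {method!r}")
            lm = compute_log_marginals(stats, hp)
            fit = em_fit(lm, hp, pi0=pi0)
            record(method, call_at_fdr(fit, nominal_fdr))
    return rows


def replicate_seeds(master_seed: int, n_replicates: int) -> np.ndarray:
    """Deterministic per-replicate seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n_replicates, dtype=np.uint32) & 0x7FFFFFFF


def run_comparison(
    cfg: SimConfig,
    n_replicates: int,
    methods=METHODS,
    master_seed: int = 0,
    nominal_fdr: float = 0.05,
) -> pd.DataFrame:
    """Replicated benchmark: one row per (replicate, method).

    Every method sees the same simulated dataset within a replicate and is
    run end-to-end at the same nominal FDR.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rows = []
    for rep, seed in enumerate(replicate_seeds(master_seed, n_replicates)):
        try:
            rep_rows = analyze_replicate(
                with_seed(cfg, int(seed)), methods=methods, nominal_fdr=nominal_fdr
            )
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"analysis failed in replicate {rep} (seed {seed}): {exc}"
            ) from exc
        for row in rep_rows:
            row["replicate"] = rep
        rows.extend(rep_rows)
    return pd.DataFrame(rows)[
        [
            "scenario",
            "replicate",
            "seed",
            "method",
            "n_called",
            "fdr",
            "sensitivity",
            "sign_agreement",
        ]
    ]


def paired_metric_diff(
    scores: pd.DataFrame,
    metric: str,
    method_a: str = "mixture_ref",
    method_b: str = "snpwise",
    nominal_fdr: float = 0.05,
) -> np.ndarray:
    """Per-replicate paired differences oriented so positive favours method_a.

    ``sensitivity``: sensitivity(a) - sensitivity(b).
    ``abs_fdr_dev``: |FDR(b) - nominal| - |FDR(a) - nominal| (smaller
    deviation from the nominal level is better).
    """
    wide = scores.pivot(index="replicate", columns="method")
    if metric == "sensitivity":
        diff = wide[("sensitivity", method_a)] - wide[("sensitivity", method_b)]
    elif metric == "abs_fdr_dev":
        diff = (wide[("fdr", method_b)] - nominal_fdr).abs() - (
            wide[("fdr", method_a)] - nominal_fdr
        ).abs()
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return diff.to_numpy(dtype=float)


def wilcoxon_signed_rank(diffs: np.ndarray, alternative: str = "greater") -> tuple[float, bool]:
    """One-sided Wilcoxon signed-rank p-value on paired differences.

    Zeros are dropped (Wilcoxon convention).  Exact null distribution when
    n <= 25 and there are no tied magnitudes; otherwise the normal
    approximation with tie correction.  Returns (p, all_zero_flag).
    """
    diffs = np.asarray(diffs, dtype=float)
    nz = diffs[diffs != 0.0]
    if nz.size == 0:
        return 1.0, True
    ranks = rankdata(np.abs(nz))
    ties = len(np.unique(ranks)) < len(ranks)
    method = "exact" if (nz.size <= 25 and not ties) else "approx"
    res = wilcoxon(nz, alternative=alternative, method=method, correction=False)
    return float(res.pvalue), False


def paired_wilcoxon(
    scores: pd.DataFrame,
    metric: str,
    method_a: str = "mixture_ref",
    method_b: str = "snpwise",
    nominal_fdr: float = 0.05,
) -> float:
    """One-sided Wilcoxon signed-rank test that method_a beats method_b."""
    diffs = paired_metric_diff(scores, metric, method_a, method_b, nominal_fdr)
    if diffs.size < 6:
        raise ValueError("need at least 6 paired replicates")
    p, _ = wilcoxon_signed_rank(diffs, alternative="greater")
    return p


def summarize(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-method means of the benchmark metrics."""
    return (
        scores.groupby("method")[["n_called", "fdr", "sensitivity", "sign_agreement"]]
        .mean()
        .reset_index()
    )
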