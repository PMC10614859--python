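"""Variant associations with extreme XCI ratios via the AUROC.

Samples are ranked by the magnitude of their XCI skew (the folded
estimate — under phase loss "extreme" is direction-free) and each variant
is scored by the probability that a carrier outranks a non-carrier:
AUROC = U / (npos * nneg), with U the Mann-Whitney rank-sum statistic and
tied ranks counting one half.  Two-sided p-values come from the exact U
distribution when npos*nneg <= 400 and there are no ties, otherwise from
the tie-corrected normal approximation with continuity correction.
A one-shuffle null AUROC per variant, Benjamini-Hochberg FDR across all
variants (all species pooled), carrier frequency, and bootstrap power
summaries complete the per-variant report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MIN_CARRIERS = 10
EXACT_MAX_PAIRS = 400
MODERATE_AUROC = 0.75


@dataclass
class VariantAssociation:
    snp_id: str
    gene: str
    n_carriers: int
    n_noncarriers: int
    auroc: float
    p_value: float
    frequency: float
    null_auroc: float = float("nan")
    fdr: float = float("nan")
    power: float = float("nan")
    effect_power: float = float("nan")
    boot_var: float = float("nan")
    ref_biased: bool = False


def _auroc_from_ranks(pos: np.ndarray, neg: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def compute_auroc(
    xci_ratios,
    carriers,
    min_carriers: int = MIN_CARRIERS,
) -> tuple[float, float]:
    """AUROC of carriers within the XCI-ranked samples, with two-sided p.

    ``carriers`` is a boolean mask over ``xci_ratios``.  Requires at least
    ``min_carriers`` carriers and one non-carrier.
    """
    ratios = np.asarray(xci_ratios, dtype=float)
    mask = np.asarray(carriers, dtype=bool)
    pos, neg = ratios[mask], ratios[~mask]
    if pos.size < min_carriers:
        raise ValueError(f"need >= {min_carriers} carriers, got {pos.size}")
    if neg.size < 1:
        raise ValueError("need at least one non-carrier")
    has_ties = np.unique(ratios).size < ratios.size
    method = "exact" if (pos.size * neg.size <= EXACT_MAX_PAIRS and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    auroc = float(res.statistic / (pos.size * neg.size))
    return auroc, float(res.pvalue)


def null_auroc(xci_ratios, n_carriers: int, seed: int | np.random.Generator = 0) -> float:
    """AUROC of one random reassignment of carrier labels.

    One shuffle per variant: across many variants these nulls trace the
    chance AUROC distribution the observed one is compared against.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ratios = np.asarray(xci_ratios, dtype=float)
    idx = rng.permutation(ratios.size)
    pos = ratios[idx[:n_carriers]]
    neg = ratios[idx[n_carriers:]]
    return _auroc_from_ranks(pos, neg)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bootstrap_power(
    xci_ratios,
    carriers,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    effect_cut: float = MODERATE_AUROC,
) -> tuple[float, float, float]:
    """Bootstrap the AUROC: (power, effect-size power, bootstrap variance).

    Carriers and non-carriers are resampled independently with replacement
    at their original sizes; each replicate yields an AUROC and p-value.
    Power is the significant fraction (p <= ``alpha``); effect-size power
    the fraction with AUROC >= ``effect_cut``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ratios = np.asarray(xci_ratios, dtype=float)
    mask = np.asarray(carriers, dtype=bool)
    pos, neg = ratios[mask], ratios[~mask]
    npos, nneg = pos.size, neg.size

    pos_boot = pos[rng.integers(0, npos, size=(n_boot, npos))]
    neg_boot = neg[rng.integers(0, nneg, size=(n_boot, nneg))]
    aurocs = np.empty(n_boot)
    pvals = np.empty(n_boot)
    for b in range(n_boot):
        res = stats.mannwhitneyu(pos_boot[b], neg_boot[b], alternative="two-sided", method="asymptotic")
        aurocs[b] = res.statistic / (npos * nneg)
        pvals[b] = res.pvalue
    power = float(np.mean(pvals <= alpha))
    effect_power = float(np.mean(aurocs >= effect_cut))
    return power, effect_power, float(np.var(aurocs))


def associate_variants(
    counts: pd.DataFrame,
    estimates: pd.DataFrame,
    ref_bias_report: pd.DataFrame | None = None,
    min_carriers: int = MIN_CARRIERS,
    detection_min_reads: int = 20,
    n_boot: int = 0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Score every detected variant against the XCI-ranked samples.

    A sample carries a variant when the variant passes the detection
    filter there (total depth >= ``detection_min_reads``).  Variants with
    fewer than ``min_carriers`` carriers are skipped (logged).  Bootstrap
    power summaries are computed when ``n_boot`` > 0.  FDR is adjusted
    across all variants in ``counts``; pool counts across species first to
    adjust study-wide.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    est = estimates[np.isfinite(estimates["mu"])][["sample_id", "mu"]]
    ranked = est.set_index("sample_id")["mu"]
    total = len(ranked)
    if "snp_id" not in counts.columns:
        from xcimosaic.counts_io import _attach_derived

        counts = _attach_derived(counts)
    detected = counts[(counts["ref_reads"] + counts["alt_reads"]) >= detection_min_reads]
    detected = detected[detected["sample_id"].isin(ranked.index)]

    flagged: set[str] = set()
    if ref_bias_report is not None:
        flagged = set(ref_bias_report.loc[ref_bias_report["flagged"], "snp_id"])

    ratios = ranked.to_numpy()
    sample_pos = {s: i for i, s in enumerate(ranked.index)}
    n_skipped = 0
    rows = []
    for snp_id, grp in detected.groupby("snp_id", sort=True):
        carrier_idx = [sample_pos[s] for s in set(grp["sample_id"])]
        if len(carrier_idx) < min_carriers or len(carrier_idx) >= total:
            n_skipped += 1
            continue
        mask = np.zeros(total, dtype=bool)
        mask[carrier_idx] = True
        auroc, p = compute_auroc(ratios, mask, min_carriers=min_carriers)
        null = null_auroc(ratios, int(mask.sum()), seed=rng)
        row = {
            "snp_id": snp_id,
            "gene": grp["gene"].iloc[0],
            "n_carriers": int(mask.sum()),
            "n_noncarriers": int(total - mask.sum()),
            "auroc": auroc,
            "p_value": p,
            "null_auroc": null,
            "frequency": mask.sum() / total,
            "ref_biased": snp_id in flagged,
        }
        if n_boot > 0:
            row["power"], row["effect_power"], row["boot_var"] = bootstrap_power(
                ratios, mask, n_boot=n_boot, seed=rng
            )
        else:
            row["power"] = row["effect_power"] = row["boot_var"] = float("nan")
        rows.append(row)
    if n_skipped:
        logger.info("skipped %d variants with < %d carriers (or no non-carriers)", n_skipped, min_carriers)
    results = pd.DataFrame(
        rows,
        columns=[
            "snp_id", "gene", "n_carriers", "n_noncarriers", "auroc", "p_value",
            "null_auroc", "frequency", "power", "effect_power", "boot_var", "ref_biased",
        ],
    )
    if len(results):
        results["fdr"] = bh_adjust(results["p_value"].to_numpy())
    else:
        results["fdr"] = pd.Series(dtype=float)
    return results


def association_report(
    results: pd.DataFrame, moderate_cut: float = MODERATE_AUROC
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split results into (main, ref-biased companion, moderate set).

    Reference-biased variants are excluded from the main table but kept in
    a companion table; the moderate set is the main-table subset with
    AUROC >= ``moderate_cut``.
    """
    if results.empty:
        empty = results.copy()
        return empty, empty.copy(), empty.copy()
    main = results[~results["ref_biased"]].reset_index(drop=True)
    companion = results[results["ref_biased"]].reset_index(drop=True)
    moderate = main[main["auroc"] >= moderate_cut].reset_index(drop=True)
    return main, companion, moderate
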