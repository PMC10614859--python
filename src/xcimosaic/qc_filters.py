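"""Removal of non-XCI signal before population modeling.

Three controls, mirroring how confounded allelic signal arises in
reference-aligned RNA-seq:

* **reference bias** — SNPs whose cross-sample mean (unfolded) reference
  ratio deviates strongly from 0.50 reflect mapping bias or eQTL effects,
  not XCI, and are excluded from modeling (but reported, since the
  association stage wants to know about them);
* **escape from XCI** — 1-Mb X bins that stay balanced in clearly skewed
  samples are excluded, as are configured terminal pseudo-autosomal (PAR)
  windows regardless of their signal;
* **global allelic imbalance** — samples whose two size-matched autosomes
  show a folded imbalance >= 0.60 carry genome-wide allelic effects and
  are dropped entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from xcimosaic.counts_io import depth_filter, fold, max_power_per_gene, _attach_derived
from xcimosaic.folded_model import estimate_all_samples

logger = logging.getLogger(__name__)

BIN_SIZE = 1_000_000


@dataclass(frozen=True)
class QcThresholds:
    """Per-species QC thresholds.

    ``skew_select`` picks the clearly skewed samples used to scan for
    escape (0.70 default; 0.60 suits low-variance species where skew is
    rare).  ``escape_cut`` is the bin-mean folded ratio below which a bin
    is called escaping (0.65 default; 0.60 / 0.675 variants).
    """

    skew_select: float = 0.70
    escape_cut: float = 0.65
    ref_bias_band: tuple[float, float] = (0.40, 0.60)
    autosome_cut: float = 0.60


def reference_bias_filter(
    counts: pd.DataFrame, band: tuple[float, float] = (0.40, 0.60)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag SNPs whose cross-sample mean reference ratio leaves ``band``.

    Returns ``(retained, report)``: the counts restricted to unflagged
    SNPs, and a per-SNP report (snp_id, mean_ratio, n_samples, flagged).
    """
    if "ref_ratio" not in counts.columns:
        counts = _attach_derived(counts)
    lo, hi = band
    per_snp = counts.groupby("snp_id")["ref_ratio"].agg(["mean", "size"])
    per_snp.columns = ["mean_ratio", "n_samples"]
    per_snp["flagged"] = (per_snp["mean_ratio"] < lo) | (per_snp["mean_ratio"] > hi)
    flagged_ids = set(per_snp.index[per_snp["flagged"]])
    retained = counts[~counts["snp_id"].isin(flagged_ids)].reset_index(drop=True)
    return retained, per_snp.reset_index()


def bin_index(pos) -> np.ndarray:
    """1-Mb bin index: floor((pos - 1) / 1e6)."""
    return (np.asarray(pos, dtype=np.int64) - 1) // BIN_SIZE


def detect_escape_bins(
    counts: pd.DataFrame,
    sample_estimates: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
    par_bins: list[int] | None = None,
) -> pd.DataFrame:
    """Scan 1-Mb bins for escape from XCI using clearly skewed samples.

    Robust escape yields balanced biallelic expression precisely where the
    rest of the chromosome is skewed, so only samples with a first-pass
    folded estimate >= ``skew_select`` inform the scan.  A bin is excluded
    when its mean folded SNP ratio (across those samples) falls below
    ``escape_cut``.  Bins listed in ``par_bins`` are excluded regardless of
    signal; when ``par_bins`` is None the first and last three occupied
    bins are treated as putative PAR windows (logged).

    Returns a per-bin report: chrom, bin_index, n_snps, mean_folded,
    excluded, par_flag.
    """
    if "ref_ratio" not in counts.columns:
        counts = _attach_derived(counts)
    counts = counts.copy()
    counts["bin_index"] = bin_index(counts["pos"])

    occupied = np.sort(counts["bin_index"].unique())
    if par_bins is None:
        par_bins = list(occupied[:3]) + list(occupied[-3:]) if len(occupied) else []
        logger.info("no PAR windows configured; defaulting to terminal bins %s", par_bins)
    par_set = set(int(b) for b in par_bins)

    skewed_ids = set(
        sample_estimates.loc[sample_estimates["mu"] >= thresholds.skew_select - 1e-9, "sample_id"].astype(str)
    )
    if not skewed_ids:
        logger.warning("no samples with folded estimate >= %.2f; only PAR bins excluded", thresholds.skew_select)

    skewed = counts[counts["sample_id"].astype(str).isin(skewed_ids)]
    folded = fold(skewed["ref_ratio"].to_numpy()) if len(skewed) else np.array([])
    per_bin = (
        pd.DataFrame({"bin_index": skewed["bin_index"].to_numpy(), "folded": folded})
        .groupby("bin_index")["folded"]
        .agg(["mean", "size"])
        if len(skewed)
        else pd.DataFrame(columns=["mean", "size"])
    )

    rows = []
    chrom = str(counts["chrom"].iloc[0]) if len(counts) else ""
    for b in occupied:
        b = int(b)
        if b in per_bin.index:
            mean_folded = float(per_bin.loc[b, "mean"])
            n_snps = int(per_bin.loc[b, "size"])
        else:
            mean_folded, n_snps = float("nan"), 0
        par = b in par_set
        excluded = par or (n_snps > 0 and mean_folded < thresholds.escape_cut)
        rows.append(
            {
                "chrom": chrom,
                "bin_index": b,
                "n_snps": n_snps,
                "mean_folded": mean_folded,
                "excluded": excluded,
                "par_flag": par,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "bin_index", "n_snps", "mean_folded", "excluded", "par_flag"])


def apply_escape_exclusion(counts: pd.DataFrame, escape_bins: pd.DataFrame) -> pd.DataFrame:
    """Drop SNPs falling in excluded bins."""
    excluded = set(escape_bins.loc[escape_bins["excluded"], "bin_index"].astype(int))
    keep = ~pd.Series(bin_index(counts["pos"]), index=counts.index).isin(excluded)
    return counts[keep].reset_index(drop=True)


def autosomal_imbalance_filter(
    autosome_counts: dict[str, pd.DataFrame],
    cut: float = 0.60,
    min_per_allele: int = 10,
    n_min: int = 10,
    ref_bias_band: tuple[float, float] = (0.40, 0.60),
) -> pd.DataFrame:
    """Per-sample keep/drop decision from two autosomal controls.

    Each autosome is pushed through the same filters and folded-normal fit
    as the X; a sample is dropped iff its folded estimate is >= ``cut`` on
    either autosome.  The report distinguishes ``global`` (both autosomes
    imbalanced) from ``single_autosome``; a sample lacking enough SNPs on
    an autosome is ``unevaluable`` there and retained with a warning.

    Returns: sample_id, mu_<chrom> per autosome, keep, status.
    """
    if len(autosome_counts) != 2:
        raise ValueError("expected counts for exactly two autosomes")
    names = sorted(autosome_counts)
    per_autosome = {}
    all_ids: set[str] = set()
    for name in names:
        counts = autosome_counts[name]
        all_ids.update(counts["sample_id"].astype(str))
        filtered = max_power_per_gene(depth_filter(counts, min_per_allele=min_per_allele))
        filtered, _ = reference_bias_filter(filtered, band=ref_bias_band)
        est = estimate_all_samples(filtered, n_min=n_min)
        per_autosome[name] = est.set_index("sample_id")["mu"]

    rows = []
    for sid in sorted(all_ids):
        mus = {}
        for name in names:
            mu = per_autosome[name].get(sid, float("nan"))
            mus[name] = float(mu) if pd.notna(mu) else float("nan")
        evaluable = [n for n in names if np.isfinite(mus[n])]
        # tolerance keeps the >= boundary exact despite float accumulation
        imbalanced = [n for n in evaluable if mus[n] >= cut - 1e-9]
        if not evaluable:
            status, keep = "unevaluable", True
            logger.warning("sample %s unevaluable on both autosomes; retained", sid)
        elif len(imbalanced) == len(names):
            status, keep = "global", False
        elif imbalanced:
            status, keep = "single_autosome", False
        else:
            status, keep = "balanced", True
            if len(evaluable) < len(names):
                logger.warning("sample %s unevaluable on one autosome; retained", sid)
        rows.append({"sample_id": sid, **{f"mu_{n}": mus[n] for n in names}, "keep": keep, "status": status})
    return pd.DataFrame(rows)
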