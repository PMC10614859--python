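"""Reading and filtering allelic-count tables.

The atomic observation is one heterozygous SNP's reference/alternate read
counts in one sample.  Tables are plain pandas DataFrames with the columns

    sample_id, chrom, pos, ref, alt, gene, ref_reads, alt_reads

(1-based positions, VCF convention).  A derived ``snp_id`` column keys a
variant as ``chrom:pos:ref:alt`` so the same site can be tracked across
samples.  Supported on-disk formats are a tab-separated dialect with that
exact header and VCF 4.x with per-sample ``AD`` allelic depths.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "gene", "ref_reads", "alt_reads"]

_INT_COLUMNS = ["pos", "ref_reads", "alt_reads"]


class ParseError(ValueError):
    """A malformed row in an allelic-count file."""


def snp_ids(counts: pd.DataFrame) -> pd.Series:
    """``chrom:pos:ref:alt`` key for each row."""
    return (
        counts["chrom"].astype(str)
        + ":"
        + counts["pos"].astype(str)
        + ":"
        + counts["ref"].astype(str)
        + ":"
        + counts["alt"].astype(str)
    )


def _attach_derived(counts: pd.DataFrame) -> pd.DataFrame:
    counts = counts.copy()
    counts["snp_id"] = snp_ids(counts)
    total = counts["ref_reads"] + counts["alt_reads"]
    counts["total_reads"] = total
    with np.errstate(invalid="ignore"):
        counts["ref_ratio"] = counts["ref_reads"] / total
    return counts


def read_counts(path: str | os.PathLike, fmt: str | None = None) -> pd.DataFrame:
    """Read an allelic-count table from TSV or VCF.

    Parameters
    ----------
    path:
        Input file.  ``fmt`` may be omitted, in which case ``.vcf`` /
        ``.vcf.gz`` extensions select the VCF reader and anything else the
        TSV reader.
    fmt:
        ``"tsv"`` or ``"vcf"``.

    Returns
    -------
    DataFrame with :data:`COUNT_COLUMNS` plus derived ``snp_id``,
    ``total_reads`` and ``ref_ratio`` columns.  Only biallelic SNVs are
    kept; multiallelic records and indels are dropped with a logged count.
    """
    path = os.fspath(path)
    if fmt is None:
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'vcf'")


def _read_tsv(path: str) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file without header") from exc
    missing = [c for c in COUNT_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    raw = raw[COUNT_COLUMNS]
    for col in _INT_COLUMNS:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() | (converted != converted.astype("Int64").astype("float"))
        bad |= converted < 0
        if bad.any():
            # +2: header line plus 1-based line numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(f"{path}:{line}: invalid value {raw[col].iloc[line - 2]!r} in column {col!r}")
        raw[col] = converted.astype(int)
    counts = raw
    n_zero = int((counts["ref_reads"] + counts["alt_reads"] < 1).sum())
    if n_zero:
        logger.info("dropped %d rows with zero total reads", n_zero)
        counts = counts[counts["ref_reads"] + counts["alt_reads"] >= 1]
    bad_pos = counts["pos"] < 1
    if bad_pos.any():
        line = int(np.flatnonzero(bad_pos.to_numpy())[0]) + 2
        raise ParseError(f"{path}:{line}: position must be >= 1")
    return _attach_derived(counts.reset_index(drop=True))


def _read_vcf(path: str) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    rows = []
    n_dropped = 0
    for variant in vcf:
        # biallelic SNVs only: exactly two identified genotypes, no indels
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_dropped += 1
            continue
        gene = variant.INFO.get("GENE") or ""
        ad = variant.format("AD")
        if ad is None:
            n_dropped += 1
            continue
        gt = variant.gt_types  # gts012: 1 == het
        for i, sample in enumerate(samples):
            if gt[i] != 1:
                continue
            ref_reads, alt_reads = int(ad[i][0]), int(ad[i][1])
            if ref_reads < 0 or alt_reads < 0 or ref_reads + alt_reads < 1:
                continue
            rows.append(
                (sample, variant.CHROM, variant.POS, variant.REF, variant.ALT[0], gene, ref_reads, alt_reads)
            )
    if n_dropped:
        logger.info("dropped %d multiallelic/indel/AD-less records from %s", n_dropped, path)
    counts = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    counts.attrs["n_dropped_records"] = n_dropped
    return _attach_derived(counts)


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a count table in the TSV dialect (derived columns stripped)."""
    counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def depth_filter(
    counts: pd.DataFrame,
    min_per_allele: int = 10,
    mode: str = "per_allele",
    min_total: int = 20,
) -> pd.DataFrame:
    """Retain well-powered SNPs.

    Default mode requires at least ``min_per_allele`` reads mapped to *both*
    alleles (hence a total depth of at least twice that).  The alternative
    ``"total_depth_only"`` mode requires only ``min_total`` total reads
    regardless of the allelic split; the per-allele rule censors extreme
    skew at low depth, which that mode avoids at the cost of admitting
    homozygous-looking sites.
    """
    if mode == "per_allele":
        keep = (counts["ref_reads"] >= min_per_allele) & (counts["alt_reads"] >= min_per_allele)
    elif mode == "total_depth_only":
        keep = (counts["ref_reads"] + counts["alt_reads"]) >= min_total
    else:
        raise ValueError(f"unknown depth-filter mode {mode!r}")
    return counts[keep].reset_index(drop=True)


def max_power_per_gene(counts: pd.DataFrame) -> pd.DataFrame:
    """Reduce to one SNP per gene per sample: the max-powered representative.

    For each (sample, gene) the SNP with the highest read count is kept; ties
    break to the lowest position, then lexicographically smallest ``snp_id``.
    SNPs without a gene annotation are dropped — only SNPs within annotated
    genes enter XCI modeling.
    """
    if "snp_id" not in counts.columns:
        counts = _attach_derived(counts)
    annotated = counts[counts["gene"].astype(str) != ""].copy()
    if annotated.empty:
        return annotated.reset_index(drop=True)
    total = annotated["ref_reads"] + annotated["alt_reads"]
    annotated["_depth"] = total
    annotated = annotated.sort_values(
        ["sample_id", "gene", "_depth", "pos", "snp_id"],
        ascending=[True, True, False, True, True],
        kind="mergesort",
    )
    best = annotated.drop_duplicates(["sample_id", "gene"], keep="first")
    return best.drop(columns="_depth").reset_index(drop=True)


def fold(ratio):
    """Fold an allelic ratio about 0.5: ``max(r, 1 - r)``.

    Folding maps the unphased reference-allele ratio onto [0.5, 1], the
    observable scale when the parental origin of each read is unknown.
    Accepts scalars or arrays; values outside [0, 1] raise ``ValueError``.
    """
    arr = np.asarray(ratio, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("allelic ratios must lie in [0, 1]")
    folded = np.maximum(arr, 1.0 - arr)
    if np.isscalar(ratio) or arr.ndim == 0:
        return float(folded)
    return folded


def folded_ratios(counts: pd.DataFrame) -> pd.Series:
    """Folded reference-allele ratio per row."""
    if "ref_ratio" not in counts.columns:
        counts = _attach_derived(counts)
    return pd.Series(fold(counts["ref_ratio"].to_numpy()), index=counts.index, name="folded_ratio")


def sample_snp_sets(counts: pd.DataFrame) -> Iterable[tuple[str, np.ndarray]]:
    """Yield ``(sample_id, folded ratios)`` per sample, in sorted id order."""
    if "ref_ratio" not in counts.columns:
        counts = _attach_derived(counts)
    for sample_id, group in counts.groupby("sample_id", sort=True):
        yield str(sample_id), fold(group["ref_ratio"].to_numpy())
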