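"""Per-sample X-linked heterozygosity and its relation to XCI estimates.

Heterozygosity is scored as the fraction of a species' union SNP catalog
detected in a sample (detection = total depth >= 20 reads).  Because
X-linked heterozygosity indexes inbreeding, correlating it with the fitted
folded-normal mean and standard deviation asks whether genetic diversity,
rather than embryonic stochasticity, shapes XCI ratios.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DETECTION_MIN_READS = 20
MIN_DETECTED_SNPS = 10


def score_heterozygosity(
    counts: pd.DataFrame,
    species: str = "",
    min_reads: int = DETECTION_MIN_READS,
    min_snps: int = MIN_DETECTED_SNPS,
) -> pd.DataFrame:
    """Heterozygosity score per sample: n_detected / n_union.

    Detection requires ``min_reads`` total reads at the SNP (a total-depth
    rule, deliberately looser than the per-allele modeling filter).  The
    union is over unique SNPs detected in *any* sample of the species;
    samples with fewer than ``min_snps`` detected SNPs are excluded.
    Duplicate (sample, SNP) rows count once, so scores are invariant to
    row order and duplication.
    """
    if counts.empty:
        raise ValueError(f"no counts provided for species {species!r}")
    if "snp_id" not in counts.columns:
        from xcimosaic.counts_io import _attach_derived

        counts = _attach_derived(counts)
    detected = counts[(counts["ref_reads"] + counts["alt_reads"]) >= min_reads]
    detected = detected.drop_duplicates(["sample_id", "snp_id"])
    if detected.empty:
        raise ValueError(f"no detected SNPs for species {species!r}")
    n_union = detected["snp_id"].nunique()
    per_sample = detected.groupby("sample_id")["snp_id"].nunique().rename("n_detected").reset_index()
    per_sample = per_sample[per_sample["n_detected"] >= min_snps].reset_index(drop=True)
    per_sample["n_union"] = n_union
    per_sample["score"] = per_sample["n_detected"] / n_union
    per_sample.insert(0, "species", species)
    return per_sample


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks on ties.

    Returns NaN with a warning when either vector is constant (ranks are
    then undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant input vector; Spearman correlation undefined")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(x, y).statistic
    return float(rho)


def heterozygosity_report(scores: pd.DataFrame, estimates: pd.DataFrame) -> pd.DataFrame:
    """Correlate heterozygosity with the fitted mu and sigma per species.

    ``scores`` comes from :func:`score_heterozygosity`; ``estimates`` from
    :func:`xcimosaic.folded_model.estimate_all_samples`.  Joined on
    sample_id; species with fewer than 3 joined samples yield NaN with a
    warning.
    """
    est = estimates[np.isfinite(estimates["mu"])]
    joined = scores.merge(est[["sample_id", "mu", "sigma"]], on="sample_id", how="inner")
    rows = []
    for species, grp in joined.groupby("species", sort=True):
        if len(grp) < 3:
            logger.warning("species %r has only %d joined samples; correlations undefined", species, len(grp))
            corr_mu = corr_sigma = float("nan")
        else:
            corr_mu = spearman(grp["score"], grp["mu"])
            corr_sigma = spearman(grp["score"], grp["sigma"])
        rows.append(
            {"species": species, "n_samples": len(grp), "corr_score_mu": corr_mu, "corr_score_sigma": corr_sigma}
        )
    return pd.DataFrame(rows, columns=["species", "n_samples", "corr_score_mu", "corr_score_sigma"])
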