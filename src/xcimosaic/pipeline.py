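"""End-to-end orchestration: counts -> QC -> estimates -> population models.

The run order mirrors how the confounders nest: a first estimation pass on
all well-powered SNPs identifies clearly skewed samples, which drive the
escape-bin scan; second-pass estimates on escape-excluded SNPs feed
everything downstream; the autosomal imbalance control then drops samples
with genome-wide allelic effects before the population cell-count fit,
the heterozygosity report and the variant-association scan.

Every stage is a pure function of (inputs, config, seed); rerunning a
config reproduces its outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from xcimosaic import counts_io
from xcimosaic.association import associate_variants, association_report
from xcimosaic.folded_model import estimate_all_samples
from xcimosaic.heterozygosity import heterozygosity_report, score_heterozygosity
from xcimosaic.population import estimate_population
from xcimosaic.qc_filters import (
    QcThresholds,
    apply_escape_exclusion,
    autosomal_imbalance_filter,
    detect_escape_bins,
    reference_bias_filter,
)
from xcimosaic.simulate import DistSpec, SimulationConfig, VariantEffect, simulate_dataset, write_fixture

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and its cause."""


@dataclass
class RunConfig:
    species: str = "synthetic"
    simulation: SimulationConfig | None = None
    counts_path: str | None = None
    counts_format: str | None = None
    x_chrom: str = "X"
    autosomes: tuple[str, str] = ("A1", "A2")
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    par_bins: list[int] | None = None
    min_per_allele: int = 10
    depth_mode: str = "per_allele"
    n_min_snps: int = 10
    tail_lo: float = 0.40
    tail_hi: float = 0.60
    cell_grid: tuple[int, int] = (2, 200)
    n_boot: int = 2000
    assoc_min_carriers: int = 10
    assoc_n_boot: int = 0
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if self.simulation is None and self.counts_path is None:
            raise ValueError("either a simulation config or a counts path is required")
        if not 0 < self.tail_lo < self.tail_hi < 1:
            raise ValueError("tail bounds must satisfy 0 < tail_lo < tail_hi < 1")
        if not 1 <= self.cell_grid[0] <= self.cell_grid[1]:
            raise ValueError("cell grid must be an increasing integer range")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            for key in ("snps_per_sample", "depth_per_snp"):
                if key in sim and isinstance(sim[key], dict):
                    sim[key] = DistSpec(**sim[key])
            if "variant_effects" in sim:
                sim["variant_effects"] = tuple(
                    VariantEffect(**v) if isinstance(v, dict) else v for v in sim["variant_effects"]
                )
            raw["simulation"] = SimulationConfig(**sim)
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            th = dict(raw["thresholds"])
            if "ref_bias_band" in th:
                th["ref_bias_band"] = tuple(th["ref_bias_band"])
            raw["thresholds"] = QcThresholds(**th)
        for key in ("autosomes", "cell_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("input")
def _load_tables(config: RunConfig):
    if config.simulation is not None:
        tables, truth = simulate_dataset(config.simulation)
        return tables, truth
    counts = counts_io.read_counts(config.counts_path, config.counts_format)
    wanted = [config.x_chrom, *config.autosomes]
    tables = {c: counts[counts["chrom"].astype(str) == c].reset_index(drop=True) for c in wanted}
    if tables[config.x_chrom].empty:
        raise ValueError(f"no counts found for X chromosome {config.x_chrom!r}")
    return tables, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a dict of artifacts.

    Keys: tables, truth (simulated runs), estimates_pass1, escape_bins,
    estimates (pass 2), autosome_report, exclusions, distribution,
    cell_count, het_scores, het_report, associations, assoc_main,
    assoc_companion, assoc_moderate, ref_bias_report, summary.
    When ``config.outdir`` is set every table plus a JSON summary is
    written there.
    """
    config.validate()
    tables, truth = _load_tables(config)
    x_chrom = config.x_chrom

    @_stage("snp_filters")
    def _filter_x():
        # bias flags come from detection-level counts (total depth >= 20):
        # the per-allele modeling filter censors extreme ratios, which would
        # drag biased SNPs' cross-sample means back toward 0.5
        detected = counts_io.depth_filter(tables[x_chrom], mode="total_depth_only")
        _, report = reference_bias_filter(detected, band=config.thresholds.ref_bias_band)
        flagged = set(report.loc[report["flagged"], "snp_id"])
        filtered = counts_io.depth_filter(
            tables[x_chrom], min_per_allele=config.min_per_allele, mode=config.depth_mode
        )
        filtered = filtered[~filtered["snp_id"].isin(flagged)].reset_index(drop=True)
        modeling = counts_io.max_power_per_gene(filtered)
        return modeling, report

    x_modeling, ref_bias_report = _filter_x()

    @_stage("estimate_pass1")
    def _pass1():
        return estimate_all_samples(x_modeling, n_min=config.n_min_snps)

    estimates1 = _pass1()

    @_stage("escape_scan")
    def _escape():
        bins = detect_escape_bins(x_modeling, estimates1, config.thresholds, par_bins=config.par_bins)
        return bins, apply_escape_exclusion(x_modeling, bins)

    escape_bins, x_final = _escape()

    @_stage("estimate_pass2")
    def _pass2():
        return estimate_all_samples(x_final, n_min=config.n_min_snps)

    estimates2 = _pass2()

    @_stage("autosomal_qc")
    def _autosome():
        return autosomal_imbalance_filter(
            {c: tables[c] for c in config.autosomes},
            cut=config.thresholds.autosome_cut,
            min_per_allele=config.min_per_allele,
            n_min=config.n_min_snps,
            ref_bias_band=config.thresholds.ref_bias_band,
        )

    autosome_report = _autosome()

    # exclusion log: each excluded sample exactly once, first reason wins
    exclusions = []
    insufficient = set(estimates2.loc[~np.isfinite(estimates2["mu"]), "sample_id"])
    for sid in sorted(insufficient):
        exclusions.append({"sample_id": sid, "reason": "insufficient_snps"})
    dropped = autosome_report[~autosome_report["keep"]]
    for _, row in dropped.iterrows():
        if row["sample_id"] in insufficient:
            continue
        exclusions.append({"sample_id": row["sample_id"], "reason": f"autosomal_imbalance_{row['status']}"})
    exclusions_df = pd.DataFrame(exclusions, columns=["sample_id", "reason"])

    keep_auto = set(autosome_report.loc[autosome_report["keep"], "sample_id"])
    # samples absent from the autosome tables have no evaluable control; retained
    keep_auto |= set(estimates2["sample_id"]) - set(autosome_report["sample_id"])
    retained = estimates2[np.isfinite(estimates2["mu"]) & estimates2["sample_id"].isin(keep_auto)]

    @_stage("population")
    def _population():
        return estimate_population(
            retained["mu"].to_numpy(),
            species=config.species,
            n_boot=config.n_boot,
            seed=np.random.default_rng((config.seed, 10)),
            tail_lo=config.tail_lo,
            tail_hi=config.tail_hi,
            grid=config.cell_grid,
        )

    dist, cell_count = _population()

    @_stage("heterozygosity")
    def _het():
        scores = score_heterozygosity(tables[x_chrom], species=config.species)
        scores = scores[scores["sample_id"].isin(set(retained["sample_id"]))].reset_index(drop=True)
        return scores, heterozygosity_report(scores, retained)

    het_scores, het_report = _het()

    @_stage("association")
    def _assoc():
        results = associate_variants(
            tables[x_chrom],
            retained,
            ref_bias_report=ref_bias_report,
            min_carriers=config.assoc_min_carriers,
            n_boot=config.assoc_n_boot,
            seed=np.random.default_rng((config.seed, 11)),
        )
        return results, association_report(results)

    associations, (assoc_main, assoc_companion, assoc_moderate) = _assoc()

    summary = {
        "species": config.species,
        "seed": config.seed,
        "n_samples_input": int(tables[x_chrom]["sample_id"].nunique()),
        "n_samples_estimated_pass1": int(np.isfinite(estimates1["mu"]).sum()),
        "n_samples_estimated": int(np.isfinite(estimates2["mu"]).sum()),
        "n_samples_retained": int(len(retained)),
        "n_excluded_insufficient_snps": int(len(insufficient)),
        "n_excluded_autosomal_imbalance": int((~autosome_report["keep"]).sum()),
        "n_escape_bins_excluded": int(escape_bins["excluded"].sum()),
        "n_ref_biased_snps": int(ref_bias_report["flagged"].sum()),
        "cell_count": {
            "n_cells": cell_count.n_cells,
            "ci95": list(cell_count.ci95) if cell_count.ci95 else None,
            "sse": cell_count.sse,
            "fit_error": cell_count.fit_error,
            "log2_cells": float(np.log2(cell_count.n_cells)),
        },
        "association": {
            "n_tested": int(len(associations)),
            "n_significant_fdr05": int((associations["fdr"] <= 0.05).sum()) if len(associations) else 0,
            "n_moderate": int(len(assoc_moderate)),
        },
        "heterozygosity": het_report.to_dict(orient="records"),
    }

    artifacts = {
        "tables": tables,
        "truth": truth,
        "x_modeling_counts": x_modeling,
        "ref_bias_report": ref_bias_report,
        "estimates_pass1": estimates1,
        "escape_bins": escape_bins,
        "estimates": estimates2,
        "autosome_report": autosome_report,
        "exclusions": exclusions_df,
        "retained": retained.reset_index(drop=True),
        "distribution": dist,
        "cell_count": cell_count,
        "het_scores": het_scores,
        "het_report": het_report,
        "associations": associations,
        "assoc_main": assoc_main,
        "assoc_companion": assoc_companion,
        "assoc_moderate": assoc_moderate,
        "summary": summary,
    }

    if config.outdir:
        _write_artifacts(config, artifacts)
    return artifacts


@_stage("write_outputs")
def _write_artifacts(config: RunConfig, artifacts: dict) -> None:
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    if artifacts["truth"] is not None:
        write_fixture(artifacts["tables"], artifacts["truth"], os.path.join(outdir, "simulated"))
    for name in (
        "ref_bias_report", "estimates_pass1", "escape_bins", "estimates", "autosome_report",
        "exclusions", "retained", "het_scores", "het_report", "associations",
        "assoc_main", "assoc_companion", "assoc_moderate",
    ):
        artifacts[name].to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t", index=False)
    cc = artifacts["cell_count"]
    pd.DataFrame(
        [
            {
                "species": config.species,
                "n_samples": artifacts["distribution"].n_samples,
                "n_cells_hat": cc.n_cells,
                "ci_low": cc.ci95[0] if cc.ci95 else "",
                "ci_high": cc.ci95[1] if cc.ci95 else "",
                "sse": cc.sse,
                "fit_error": cc.fit_error,
                "log2_cells": np.log2(cc.n_cells),
            }
        ]
    ).to_csv(os.path.join(outdir, "cell_count.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(artifacts["summary"], fh, indent=2, sort_keys=True)
        fh.write("\n")
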