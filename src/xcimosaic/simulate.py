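"""Synthetic populations of allelic-count tables with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without external sequencing data:

* each sample's true XCI ratio is ``Binomial(n_cells, p_inact) / n_cells``
  — the embryonic coin-flip that fixes mosaicism for life;
* per-SNP reads are binomial draws at negative-binomially distributed
  depths, with the reference allele randomly maternal or paternal per SNP
  (phase loss under reference alignment);
* escape regions in terminal X bins pull allelic ratios toward 0.5;
* a configurable fraction of SNPs carry a reference-mapping bias;
* a configurable fraction of samples carry a genome-wide allelic
  imbalance (one haplotype amplified on autosomes and X alike);
* rare variants can shift their carriers' XCI ratios away from 0.5.

Two pseudo-autosomes are emitted alongside the X so the autosomal
imbalance control can run on the same footing as in real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import os

import numpy as np
import pandas as pd

from xcimosaic.counts_io import COUNT_COLUMNS, _attach_derived

_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """An invalid simulation-configuration field (named in the message)."""


@dataclass(frozen=True)
class DistSpec:
    """Negative-binomial count spec: ``var = mean + mean^2 / dispersion``."""

    mean: float
    dispersion: float
    minimum: int = 1


@dataclass(frozen=True)
class VariantEffect:
    """A rare variant whose carriers' XCI ratios are shifted toward skew."""

    variant_id: str
    carrier_frequency: float
    skew_shift: float


@dataclass(frozen=True)
class SimulationConfig:
    n_cells: int = 13
    n_samples: int = 500
    p_inact: float = 0.5
    snps_per_sample: DistSpec = field(default_factory=lambda: DistSpec(mean=50, dispersion=7, minimum=12))
    depth_per_snp: DistSpec = field(default_factory=lambda: DistSpec(mean=56, dispersion=3, minimum=20))
    escape_fraction: float = 0.05
    escape_pull: float = 0.75
    ref_bias_fraction: float = 0.05
    ref_bias_shift: float = 0.15
    global_imbalance_fraction: float = 0.05
    variant_effects: tuple[VariantEffect, ...] = ()
    drift_generations: int = 0
    drift_cells: int | None = None
    x_n_snps: int = 600
    autosome_n_snps: int = 400
    x_length_mb: int = 155
    autosome_length_mb: int = 170
    escape_terminal_mb: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        for name in ("p_inact", "escape_fraction", "escape_pull", "ref_bias_fraction", "global_imbalance_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.depth_per_snp.minimum < 1:
            raise ConfigurationError("depth_per_snp.minimum must be >= 1")
        if self.snps_per_sample.minimum < 1:
            raise ConfigurationError("snps_per_sample.minimum must be >= 1")
        for eff in self.variant_effects:
            if not 0.0 < eff.carrier_frequency < 1.0:
                raise ConfigurationError(f"variant_effects[{eff.variant_id}].carrier_frequency must lie in (0, 1)")
        if self.drift_generations < 0:
            raise ConfigurationError("drift_generations must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    config: SimulationConfig
    samples: pd.DataFrame  # sample_id, true_ratio, tissue_ratio, global_imbalance, imbalance_factor, carrier_variants
    catalogs: dict[str, pd.DataFrame]  # chrom -> snp_id,chrom,pos,ref,alt,gene,escape,ref_biased,variant_id
    orientation: pd.DataFrame | None = None  # sample_id, snp_id, ref_is_maternal (filled by simulate_counts)


def _rng(config: SimulationConfig, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((config.seed, salt))


def _draw_nb(rng: np.random.Generator, spec: DistSpec, size: int) -> np.ndarray:
    k, m = spec.dispersion, spec.mean
    draws = rng.negative_binomial(k, k / (k + m), size=size)
    return np.maximum(draws, spec.minimum)


def simulate_embryo_ratios(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """True XCI ratios for a population of embryos.

    Each of ``n_samples`` embryos has ``n_cells`` epiblast cells that each
    independently inactivate the maternal X with probability ``p_inact``;
    the ratio is the maternal-inactive fraction, on the lattice
    {0, 1/C, ..., 1}.
    """
    config.validate()
    if rng is None:
        rng = _rng(config, salt=1)
    return rng.binomial(config.n_cells, config.p_inact, size=config.n_samples) / config.n_cells


def _make_catalog(
    rng: np.random.Generator,
    chrom: str,
    n_snps: int,
    length_mb: int,
    escape_fraction: float,
    ref_bias_fraction: float,
    terminal_mb: int,
) -> pd.DataFrame:
    n_escape = int(round(escape_fraction * n_snps))
    n_interior = n_snps - n_escape
    lo = terminal_mb * 1_000_000
    hi = length_mb * 1_000_000
    pos_interior = rng.integers(lo + 1, hi - lo, size=n_interior)
    # escape SNPs live in the terminal bins, mimicking pseudo-autosomal ends
    half = n_escape // 2
    pos_escape = np.concatenate(
        [
            rng.integers(1, lo, size=half),
            rng.integers(hi - lo, hi, size=n_escape - half),
        ]
    )
    pos = np.concatenate([pos_interior, pos_escape])
    escape = np.concatenate([np.zeros(n_interior, bool), np.ones(n_escape, bool)])
    order = np.argsort(pos, kind="stable")
    pos, escape = pos[order], escape[order]
    # dedupe positions to keep snp_id unique
    pos = pos + np.arange(len(pos))
    ref_idx = rng.integers(0, 4, size=n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4
    gene = np.array([f"{chrom}G{p // 200_000}" for p in pos])
    ref_biased = rng.random(n_snps) < ref_bias_fraction
    ref_biased &= ~escape
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos.astype(int),
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "gene": gene,
            "escape": escape,
            "ref_biased": ref_biased,
            "variant_id": "",
        }
    )
    df["snp_id"] = df["chrom"] + ":" + df["pos"].astype(str) + ":" + df["ref"] + ":" + df["alt"]
    return df


def generate_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the per-sample and per-SNP latent state for one population."""
    config.validate()
    rng = _rng(config, salt=2)

    ratios = simulate_embryo_ratios(config, rng=rng)
    sample_ids = np.array([f"S{i:05d}" for i in range(config.n_samples)])

    # rare skew variants: carriers' ratio is redrawn from the base
    # distribution, then pushed away from 0.5 by the variant's shift
    carrier_sets = [[] for _ in range(config.n_samples)]
    for eff in config.variant_effects:
        carriers = rng.random(config.n_samples) < eff.carrier_frequency
        redrawn = rng.binomial(config.n_cells, config.p_inact, size=config.n_samples) / config.n_cells
        direction = np.where(redrawn >= 0.5, 1.0, -1.0)
        shifted = np.clip(redrawn + direction * eff.skew_shift, 0.02, 0.98)
        ratios = np.where(carriers, shifted, ratios)
        for i in np.flatnonzero(carriers):
            carrier_sets[i].append(eff.variant_id)

    tissue = ratios.copy()
    if config.drift_generations > 0:
        n_drift = config.drift_cells or config.n_cells
        for _ in range(config.drift_generations):
            tissue = rng.binomial(n_drift, tissue) / n_drift

    imbalance = rng.random(config.n_samples) < config.global_imbalance_fraction
    b = rng.uniform(0.60, 0.80, size=config.n_samples)
    factor = np.where(imbalance, b / (1 - b), 1.0)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "true_ratio": ratios,
            "tissue_ratio": tissue,
            "global_imbalance": imbalance,
            "imbalance_factor": factor,
            "carrier_variants": [",".join(c) for c in carrier_sets],
        }
    )

    catalogs = {
        "X": _make_catalog(
            rng, "X", config.x_n_snps, config.x_length_mb,
            config.escape_fraction, config.ref_bias_fraction, config.escape_terminal_mb,
        ),
        "A1": _make_catalog(rng, "A1", config.autosome_n_snps, config.autosome_length_mb, 0.0, config.ref_bias_fraction, 0),
        "A2": _make_catalog(rng, "A2", config.autosome_n_snps, config.autosome_length_mb, 0.0, config.ref_bias_fraction, 0),
    }

    # effect variants are dedicated X catalog entries detected only in carriers
    if config.variant_effects:
        cat = catalogs["X"]
        extra = []
        lo = config.escape_terminal_mb * 1_000_000
        hi = config.x_length_mb * 1_000_000 - lo
        for eff in config.variant_effects:
            p = int(rng.integers(lo + 1, hi))
            ref_i = int(rng.integers(0, 4))
            alt_i = (ref_i + int(rng.integers(1, 4))) % 4
            extra.append(
                {
                    "chrom": "X",
                    "pos": p,
                    "ref": _BASES[ref_i],
                    "alt": _BASES[alt_i],
                    "gene": f"XG{p // 200_000}",
                    "escape": False,
                    "ref_biased": False,
                    "variant_id": eff.variant_id,
                    "snp_id": f"X:{p}:{_BASES[ref_i]}:{_BASES[alt_i]}",
                }
            )
        catalogs["X"] = pd.concat([cat, pd.DataFrame(extra)], ignore_index=True)

    return GroundTruth(config=config, samples=samples, catalogs=catalogs)


def simulate_counts(truth: GroundTruth, config: SimulationConfig | None = None) -> dict[str, pd.DataFrame]:
    """Sample read counts for every SNP of every sample.

    Per SNP the reference-read count is ``Binomial(depth, q)`` where ``q``
    is the maternal tissue ratio (or its complement when the reference
    allele is paternal), after the escape pull toward 0.5, the sample's
    global-imbalance amplification, and any reference-bias shift.  Returns
    a dict of count tables keyed ``"X"``, ``"A1"``, ``"A2"`` and fills
    ``truth.orientation``.
    """
    config = config or truth.config
    config.validate()
    rng = _rng(config, salt=3)

    effect_ids = {eff.variant_id for eff in config.variant_effects}
    tables: dict[str, pd.DataFrame] = {}
    orient_rows = {"sample_id": [], "snp_id": [], "ref_is_maternal": []}

    samples = truth.samples
    carrier_lookup = [set(c.split(",")) if c else set() for c in samples["carrier_variants"]]

    for chrom, catalog in truth.catalogs.items():
        base_idx = np.flatnonzero(~catalog["variant_id"].astype(bool).to_numpy())
        effect_rows = {
            vid: i for i, vid in enumerate(catalog["variant_id"]) if vid in effect_ids
        }
        n_det = _draw_nb(rng, config.snps_per_sample, config.n_samples)
        n_det = np.minimum(n_det, len(base_idx))

        out = {c: [] for c in ("sample_id", "pos_idx", "ref_reads", "alt_reads")}
        for i in range(len(samples)):
            chosen = rng.choice(base_idx, size=int(n_det[i]), replace=False)
            extra = [effect_rows[v] for v in carrier_lookup[i] if v in effect_rows]
            idx = np.sort(np.concatenate([chosen, np.asarray(extra, dtype=int)]))
            m = len(idx)

            p_mat = samples["tissue_ratio"].iat[i] if chrom == "X" else 0.5
            p = np.full(m, p_mat)
            esc = catalog["escape"].to_numpy()[idx]
            p = np.where(esc, config.escape_pull * 0.5 + (1 - config.escape_pull) * p, p)
            f = samples["imbalance_factor"].iat[i]
            if f != 1.0:
                p = f * p / (f * p + (1 - p))
            ref_is_mat = rng.random(m) < 0.5
            q = np.where(ref_is_mat, p, 1 - p)
            biased = catalog["ref_biased"].to_numpy()[idx]
            q = np.where(biased, np.clip(q + config.ref_bias_shift, 0.02, 0.98), q)

            depth = _draw_nb(rng, config.depth_per_snp, m)
            ref_reads = rng.binomial(depth, q)

            out["sample_id"].append(np.repeat(samples["sample_id"].iat[i], m))
            out["pos_idx"].append(idx)
            out["ref_reads"].append(ref_reads)
            out["alt_reads"].append(depth - ref_reads)
            orient_rows["sample_id"].extend([samples["sample_id"].iat[i]] * m)
            orient_rows["snp_id"].extend(catalog["snp_id"].to_numpy()[idx])
            orient_rows["ref_is_maternal"].extend(ref_is_mat.tolist())

        idx_all = np.concatenate(out["pos_idx"]) if out["pos_idx"] else np.array([], int)
        table = pd.DataFrame(
            {
                "sample_id": np.concatenate(out["sample_id"]) if out["sample_id"] else np.array([], str),
                "chrom": catalog["chrom"].to_numpy()[idx_all],
                "pos": catalog["pos"].to_numpy()[idx_all],
                "ref": catalog["ref"].to_numpy()[idx_all],
                "alt": catalog["alt"].to_numpy()[idx_all],
                "gene": catalog["gene"].to_numpy()[idx_all],
                "ref_reads": np.concatenate(out["ref_reads"]).astype(int) if out["ref_reads"] else np.array([], int),
                "alt_reads": np.concatenate(out["alt_reads"]).astype(int) if out["alt_reads"] else np.array([], int),
            }
        )
        tables[chrom] = _attach_derived(table)

    truth.orientation = pd.DataFrame(orient_rows)
    return tables


def simulate_dataset(config: SimulationConfig) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Convenience: draw ground truth then counts in one call."""
    truth = generate_truth(config)
    tables = simulate_counts(truth, config)
    return tables, truth


def write_fixture(tables: dict[str, pd.DataFrame], truth: GroundTruth, directory: str | os.PathLike) -> dict[str, str]:
    """Write the count TSV plus ground-truth sidecars; returns paths.

    ``counts.tsv`` round-trips losslessly through
    :func:`xcimosaic.counts_io.read_counts`.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {
        "counts": os.path.join(directory, "counts.tsv"),
        "truth_samples": os.path.join(directory, "truth_samples.tsv"),
        "truth_snps": os.path.join(directory, "truth_snps.tsv"),
    }
    frames = [tables[k][COUNT_COLUMNS] for k in sorted(tables)] if tables else []
    combined = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=COUNT_COLUMNS)
    combined.to_csv(paths["counts"], sep="\t", index=False)
    truth.samples[["sample_id", "true_ratio", "carrier_variants", "global_imbalance"]].to_csv(
        paths["truth_samples"], sep="\t", index=False
    )
    cat = pd.concat(truth.catalogs.values(), ignore_index=True) if truth.catalogs else pd.DataFrame()
    cat.to_csv(paths["truth_snps"], sep="\t", index=False)
    return paths
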