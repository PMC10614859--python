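# xcimosaic

Population-scale analysis of X-chromosome inactivation (XCI) from
unphased allele-specific RNA-seq counts.

Every female mammal is a mosaic: early in embryonic development each cell
permanently silences one of its two X chromosomes at random, and the
resulting **XCI ratio** — the fraction of cells that silenced a given
parental allele — varies widely between individuals. Because the choice is
made when the epiblast contains only a handful of cells, the *population
variance* of XCI ratios is a window into early development: with `n` cells
each flipping a fair coin, ratios follow `Bin(n, 0.5)/n`, so
`Var = 0.25/n`. Measuring XCI variability in adults therefore estimates
how many embryonic cells were present when inactivation was fixed.

`xcimosaic` implements that analysis for anyone with per-sample tables of
heterozygous-SNP allelic read counts (from a VCF with `AD` fields or a
flat TSV) — no phasing or strain information required:

* **Per-sample XCI ratios.** Reference alignment loses parental phase, so
  each SNP's allelic ratio is observed *folded* about 0.5
  (`x = max(r, 1-r)`). Per sample the folded ratios are fitted by maximum
  likelihood with the folded normal
  `f(x; μ, σ) = φ(x; μ, σ) + φ(x; 1-μ, σ)`, `μ ∈ [0.5, 1]`;
  the fitted `μ` is the folded XCI ratio.
* **Quality control.** SNPs with cross-sample mean allelic ratio outside
  (0.40, 0.60) are flagged as reference-biased; 1-Mb chromosome bins that
  stay balanced in clearly skewed samples (escape from XCI, enriched near
  pseudo-autosomal ends) are excluded; samples with a folded imbalance
  ≥ 0.60 on either of two autosomal controls are dropped.
* **Embryonic cell counts.** Folded estimates are mirror-unfolded into a
  symmetric population distribution and `Normal(0.5, 0.25/n)` is fitted by
  minimizing the summed squared CDF error over the distribution tails
  (ratios ≤ 0.40 or ≥ 0.60), grid-searching `n ∈ [2, 200]`, with
  percentile-bootstrap 95% confidence intervals.
* **Genetic correlates.** Per-sample X-linked heterozygosity scores and
  their Spearman correlations with the fitted `μ` and `σ`; per-variant
  association with extreme XCI ratios via the Mann-Whitney AUROC
  (`AUROC = U/(n_pos · n_neg)`), with one-shuffle nulls, pooled
  Benjamini-Hochberg FDR, carrier frequencies, and bootstrap power.
* **Synthetic data.** A generator that emulates the full statistical
  structure — binomial embryonic sampling, negative-binomial depths, phase
  loss, escape regions, reference bias, global imbalance, rare
  skew-shifting variants — with complete ground truth, so the entire
  pipeline is testable without external data.

## Worked example

Infer the cell count behind a population whose unfolded XCI ratios have
standard deviation 0.13868 (`examples/03_infer_cell_count.py`):

```python
import numpy as np
from xcimosaic import fold, unfold, fit_cell_count, bootstrap_ci

rng = np.random.default_rng(3)
vals = np.clip(rng.normal(0.5, 0.13868, 5000), 0, 1)
dist = unfold(fold(vals))
est = fit_cell_count(dist)
lo, hi = bootstrap_ci(dist, n_boot=2000, seed=3)
```

which prints

```
estimated cell count: 13
95% bootstrap CI:     [12, 13]
tail fit error:       0.00069 (mean |model CDF - empirical CDF|)
cell divisions:       3.70 (log2 scale)
```

`sd = 0.13868` is exactly `sqrt(0.25/13)`, so the estimator returns 13
cells — the human-scale answer — and the tail fit error shows the normal
model reproduces the empirical CDF to well under a percentage point.

The full pipeline runs from one config
(`examples/06_full_pipeline.py`, or `xci-mosaic run --config run.yaml`):
simulation or file input → SNP filters → two-pass estimation with escape
exclusion → autosomal QC → population fit → heterozygosity and
association reports, all written as TSVs plus a JSON summary. The other
`examples/*.py` scripts each exercise one capability and print the
numbers they compute.

A thin CLI mirrors the stages: `xci-mosaic simulate | counts | estimate |
qc | population | het | assoc | run`.

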