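# Methods

## The observation model

A heterozygous X-linked SNP in a bulk RNA-seq sample reports the allelic
activity of the two X haplotypes. If the tissue's maternal-active
fraction is `p`, the maternal read count at a SNP of depth `d` is
`Bin(d, p)`. After reference alignment the parental origin of each read
is unknown: each SNP's reference allele is maternal or paternal
essentially at random, so the observable is the **folded** ratio
`x = max(r, 1-r) ∈ [0.5, 1]`, distributed as a depth-dependent folded
binomial.

Rather than fitting the folded-binomial mixture across heterogeneous
depths, the per-sample likelihood uses its continuous approximation, the
folded normal

    f(x; μ, σ) = φ(x; μ, σ) + φ(x; 1-μ, σ),   μ ∈ [0.5, 1], σ > 0,

where `φ` is the normal density. `μ` is the sample's folded XCI ratio and
`σ` absorbs read-sampling noise plus any residual biological spread
across SNPs. The MLE of `μ` over at least 10 filtered SNPs is the
sample's estimate. Samples with fewer than 10 usable SNPs are flagged
`insufficient_snps` and carry no estimate.

### Fitting

`fit_folded_normal` runs bounded L-BFGS-B with the analytic gradient from
three starts (moment estimate, the balanced point `μ = 0.5`, and a
dominant-branch start `2·mean − 0.5`), bounds `μ ∈ [0.5, 1]`,
`σ ∈ [1e-4, 0.5]`. The `σ` floor prevents likelihood divergence when all
ratios coincide. `check_grid=True` additionally evaluates a dense grid
(`μ` step 0.001, `σ` log-spaced 0.005–0.3) and re-polishes from the grid
optimum if it improves the NLL by more than 1e-6; the grid also serves as
the independent oracle in the tests.

`estimate_all_samples` uses an equivalent but much faster batch path: the
folded normal is, up to a constant, an equal-weight two-component
Gaussian mixture with reflected means `(μ, 1-μ)` and tied `σ`, so EM
applies with closed-form updates and vectorizes across samples. Because
`μ = 0.5` is always an EM fixed point (by symmetry), samples converging
there are re-polished with the gradient optimizer from an interior start;
the batch and per-sample paths agree to ≤ 1e-6 NLL in the test suite.
The folded-binomial pmf is implemented only as a test oracle, not used in
production fitting.

## SNP filtering

* Only biallelic SNVs with heterozygous genotypes are read (VCF `AD`
  field, or the TSV dialect `sample_id, chrom, pos, ref, alt, gene,
  ref_reads, alt_reads`); multiallelic records and indels are dropped and
  counted.
* Depth filter, default mode: ≥ 10 reads on *both* alleles (total ≥ 20).
  An alternative `total_depth_only` mode requires only total depth ≥ 20.
  The per-allele rule censors extreme ratios at moderate depth — at depth
  `d` no surviving SNP can show a ratio above `(d-10)/d`, so a depth-25
  SNP is confined to [0.4, 0.6] regardless of the true skew. This biases
  strongly skewed samples toward 0.5 and truncates the population tails;
  the total-depth mode avoids it at the cost of admitting sites whose
  minor allele is barely covered. Both modes are exposed everywhere; the
  end-to-end recovery checks use `total_depth_only` for exactly this
  reason.
* Reference-bias filter: a SNP whose cross-sample mean (unfolded)
  reference ratio leaves (0.40, 0.60) is excluded from modeling and
  flagged for the association report. The pipeline computes these means
  on detection-level counts (total ≥ 20) rather than per-allele-filtered
  counts, because the per-allele censoring would drag biased SNPs' means
  back toward 0.5 and hide them.
* One SNP per annotated gene per sample: the highest-depth SNP
  represents the gene (ties: lowest position, then lexicographic id —
  arbitrary but deterministic). SNPs without gene annotation are dropped
  from modeling.

## Escape from XCI and autosomal controls

Robust escape produces balanced expression precisely where the rest of
the chromosome is skewed. A first estimation pass over all well-powered
SNPs selects clearly skewed samples (folded `μ` ≥ 0.70 by default; 0.60
is appropriate for low-variance species where skew is rare). Mean folded
SNP ratios are then computed in 1-Mb bins (`bin = floor((pos-1)/1e6)`)
across those samples; bins with mean < 0.65 (configurable: 0.60, 0.675)
are excluded, as are configured terminal pseudo-autosomal windows
regardless of signal. When no PAR windows are configured the first and
last three occupied bins are used and logged. Second-pass estimates on
the surviving SNPs feed all downstream analysis.

The same filters and fit run on two autosomes (the generator emits two
pseudo-autosomes; on real data pick the two closest in size to the X).
Any sample with a folded autosomal estimate ≥ 0.60 on either autosome is
excluded; the report distinguishes global (both autosomes) from
single-autosome imbalance. A sample that cannot be evaluated on an
autosome (< 10 SNPs) is retained with a warning. Threshold comparisons
use a 1e-9 tolerance so the ≥ boundary survives float accumulation.

## Population model and cell-count inference

XCI is a binomial sampling event across the `n` epiblast cells present
when inactivation is fixed: ratios are `Bin(n, 0.5)/n` with variance
`0.25/n`. The folded per-sample estimates are mirror-unfolded — each
folded value `f` contributes `f` and `1-f` at half weight — which adds no
randomness, preserves the folded information exactly, and makes the
distribution symmetric about 0.5 by construction.

`fit_cell_count` grid-searches `n ∈ [2, 200]`, scoring each candidate by
the summed squared difference between the `Normal(0.5, 0.25/n)` CDF and
the empirical CDF on the fixed ratio grid
`{0, 0.005, …, 0.40} ∪ {0.60, …, 1.0}`. Only the tails are scored because
folded estimates between 0.5 and 0.6 (unfolded 0.4–0.6) are the least
reliable. Ties break to the smaller `n` (the more conservative variance
explanation); an all-balanced population therefore returns the grid
maximum 200, documented degenerate behavior. The grid step 0.005 keeps
discretization error far below sampling error at realistic cohort sizes.
`fit_error` — the mean absolute CDF deviation over the evaluation grid at
the optimum — is reported as the goodness-of-fit summary; it is this
package's interpretation of tail-fit error, defined here rather than
inherited from anywhere.

Confidence intervals are percentile bootstrap: the folded estimates (the
actual observations) are resampled with replacement at the original
sample size, re-unfolded and refitted 2,000 times (configurable); the 95%
interval leaves 2.5% of the bootstrap distribution outside each end.
Coverage measured over 200 synthetic populations (true n = 13, 500
samples, 300 bootstrap replicates) is ~97%.

`log2(n)` expresses estimates as cell divisions; the plausible mammalian
range (8 to 65 cells) spans only ~3 divisions.

## Heterozygosity and variant association

Heterozygosity is the fraction of the species' union SNP catalog detected
in a sample, with detection defined as total depth ≥ 20 (deliberately the
looser total-depth rule — it is a detection question, not a modeling
one); samples with fewer than 10 detected SNPs are excluded. Spearman
correlations (average ranks on ties; undefined-on-constant returns NaN
with a warning) relate the score to the fitted `μ` and `σ` per species.
Under the default generator (no genetic effects) both correlations are
near zero — the null the analysis is designed to be able to reject.

For each variant with ≥ 10 carriers, samples are ranked by their folded
estimate — under phase loss "extreme XCI" has no direction, so magnitude
is the right ranking — and the AUROC is `U/(n_pos·n_neg)` with tied
ranks counting ½. Carrier status means the variant passed detection
(total ≥ 20) in that sample. Two-sided p-values use the exact U
distribution when `n_pos·n_neg ≤ 400` and no ties exist, otherwise the
tie-corrected normal approximation with continuity correction. Each
variant gets one label-shuffle null AUROC; across variants these trace
the chance distribution. FDR is Benjamini-Hochberg across all variants
passed in (pool species before calling to adjust study-wide); AUROC
≥ 0.75 defines the moderate-association set. Reference-biased variants
are excluded from the main table and reported separately. Bootstrap
power resamples carriers and non-carriers independently at original
sizes: `power` = fraction of replicates with p ≤ 0.05, `effect_power` =
fraction with AUROC ≥ 0.75, plus the bootstrap AUROC variance.

## The synthetic-data generator

Defaults describe a human-like cohort: 13 epiblast cells, ~50 SNPs per
sample (negative binomial, dispersion 7, min 12, over a 600-SNP X
catalog), per-SNP depth ~56 (negative binomial, dispersion 3, floored at
20 — heavy-tailed, as RNA-seq depths are), fair inactivation
(`p_inact = 0.5`). Contaminants default to modest levels chosen as
plausible rather than measured: 5% escape SNPs confined to the terminal
3 Mb with a 0.75 pull toward balance, 5% reference-biased SNPs with a
+0.15 ratio shift, 5% globally imbalanced samples. Global imbalance is a
multiplicative amplification of one haplotype (factor `b/(1-b)`,
`b ~ U(0.60, 0.80)`) applied to autosomes and X alike, so the autosomal
control can catch it. Rare skew variants redraw their carriers' ratio
from the base distribution and push it away from 0.5 by the configured
shift; carriers, and only carriers, detect the variant's SNP. An
off-by-default drift option resamples the tissue ratio binomially
through extra generations for sensitivity analyses; cross-tissue
consistency arguments suggest drift is a minor factor, hence off.

What the generator does **not** emulate: read-level artifacts (mapping,
duplicates, allele-specific mapping loss beyond the scalar bias shift),
LD between variants, gene-expression structure (every SNP is
exchangeable given its gene label), eQTL allelic effects distinct from
the bias shift, and partial, gene-specific escape away from chromosome
ends. Passing tests demonstrate the statistical machinery is correct
under the assumed model — not that real libraries satisfy the model.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: estimator-only
recovery uses 5,000-sample populations (modal estimate over 10 seeds);
the end-to-end pipeline check uses 1,000 samples; bootstrap coverage uses
200 populations × 300 replicates. These sizes make the checks stable
while keeping the whole suite around a minute. All randomness flows
through `numpy.random.default_rng` seeded from configuration; a fixed
seed reproduces every table byte for byte.

## Known limitations

* Cell-count estimates are lower bounds in the presence of any variance
  source beyond inactivation choice (drift, residual imbalance,
  estimation noise), since extra variance mimics fewer cells.
* The per-allele depth filter's censoring (above) biases `μ` downward
  for strongly skewed samples at depths below ~100; use
  `total_depth_only` when extreme skew matters.
* Folded estimates near 0.5 are intrinsically noisy (the fold boundary);
  the tail-restricted population fit mitigates but does not remove this.
* The escape scan needs skewed samples; in a population with no skew it
  can only exclude the configured PAR windows (it warns in that case).
* Default PAR windows (terminal 3 bins) are a heuristic; supply real
  coordinates per species when known.
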