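"""Simulate a synthetic population of allelic-count tables.

Builds a 200-sample cohort under the default study conditions (13
epiblast cells at the time of X inactivation, ~50 X-linked SNPs per
sample at ~56x depth) and prints what the generator produced.  The true
XCI ratios live on the lattice k/13 and their variance should be close
to the binomial prediction 0.25/13 = 0.0192.
"""

import numpy as np

from xcimosaic import SimulationConfig, simulate_dataset

config = SimulationConfig(n_samples=200, seed=1)
tables, truth = simulate_dataset(config)

ratios = truth.samples["true_ratio"]
print(f"samples:               {config.n_samples}")
print(f"true ratio variance:   {ratios.var():.5f}  (binomial prediction {0.25 / config.n_cells:.5f})")
print(f"X count rows:          {len(tables['X'])}")
print(f"SNPs/sample (mean):    {tables['X'].groupby('sample_id').size().mean():.1f}")
print(f"depth/SNP (mean):      {tables['X']['total_reads'].mean():.1f}")
print(f"escape SNPs in catalog: {int(truth.catalogs['X']['escape'].sum())}")
print(f"globally imbalanced:   {int(truth.samples['global_imbalance'].sum())} samples")
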