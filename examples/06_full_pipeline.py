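"""Run the full analysis end to end on synthetic data.

Simulation -> SNP filters -> two-pass folded-normal estimation (escape
bins excluded between passes) -> autosomal imbalance QC -> population
cell-count fit with bootstrap CI -> heterozygosity and association
reports.  The cell-count estimate should recover the simulated 13 cells.
Equivalent shell invocation: `xci-mosaic run --config run.yaml`.
"""

import json

from xcimosaic import RunConfig, run_pipeline, SimulationConfig

config = RunConfig(
    simulation=SimulationConfig(n_cells=13, n_samples=400, seed=6),
    seed=6,
    n_boot=500,
    depth_mode="total_depth_only",
)
artifacts = run_pipeline(config)
print(json.dumps(artifacts["summary"], indent=2, sort_keys=True))
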