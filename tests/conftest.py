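import numpy as np
import pandas as pd
import pytest

from xcimosaic.pipeline import RunConfig, run_pipeline
from xcimosaic.simulate import SimulationConfig, simulate_dataset


def make_counts(rows):
    """Build a count table from (sample_id, chrom, pos, ref, alt, gene, ref_reads, alt_reads) tuples."""
    from xcimosaic.counts_io import COUNT_COLUMNS, _attach_derived

    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return _attach_derived(df)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic dataset shared across tests."""
    config = SimulationConfig(n_samples=300, seed=42)
    tables, truth = simulate_dataset(config)
    return config, tables, truth


@pytest.fixture(scope="session")
def pipeline_run():
    """One full pipeline run on default study conditions (300 samples)."""
    config = RunConfig(
        simulation=SimulationConfig(n_samples=300, seed=42),
        seed=42,
        n_boot=200,
    )
    return config, run_pipeline(config)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
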