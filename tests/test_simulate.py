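import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xcimosaic.counts_io import COUNT_COLUMNS, read_counts
from xcimosaic.simulate import (
    ConfigurationError,
    DistSpec,
    SimulationConfig,
    VariantEffect,
    generate_truth,
    simulate_counts,
    simulate_dataset,
    simulate_embryo_ratios,
    write_fixture,
)


class TestEmbryoRatios:
    def test_single_cell_all_or_none(self):
        ratios = simulate_embryo_ratios(SimulationConfig(n_cells=1, n_samples=500, seed=1))
        assert set(np.unique(ratios)) <= {0.0, 1.0}

    def test_variance_matches_closed_form(self):
        # var = p(1-p)/n_cells = 0.25/200 = 0.00125
        ratios = simulate_embryo_ratios(SimulationConfig(n_cells=200, n_samples=10000, seed=2))
        assert np.var(ratios) == pytest.approx(0.00125, rel=0.10)

    def test_tail_fraction_matches_exact_binomial(self):
        # P(X >= 8 | n=13, p=0.5) by direct summation
        exact = sum(stats.binom.pmf(k, 13, 0.5) for k in range(8, 14))
        ratios = simulate_embryo_ratios(SimulationConfig(n_cells=13, n_samples=50000, seed=3))
        assert np.mean(ratios >= 0.60) == pytest.approx(exact, abs=0.02)

    def test_lattice_values(self):
        ratios = simulate_embryo_ratios(SimulationConfig(n_cells=7, n_samples=1000, seed=4))
        assert np.allclose(ratios * 7, np.round(ratios * 7))

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"n_cells": 0}, "n_cells"),
            ({"n_samples": 0}, "n_samples"),
            ({"p_inact": 1.5}, "p_inact"),
            ({"escape_fraction": -0.1}, "escape_fraction"),
            ({"depth_per_snp": DistSpec(mean=50, dispersion=2, minimum=0)}, "depth_per_snp"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            simulate_embryo_ratios(SimulationConfig(**kwargs))


def _truth_with_ratio(config, p_mat):
    truth = generate_truth(config)
    truth.samples["true_ratio"] = p_mat
    truth.samples["tissue_ratio"] = p_mat
    return truth


class TestSimulateCounts:
    def test_balanced_high_depth_symmetric(self):
        config = SimulationConfig(
            n_samples=5,
            seed=5,
            escape_fraction=0.0,
            ref_bias_fraction=0.0,
            global_imbalance_fraction=0.0,
            depth_per_snp=DistSpec(mean=10000, dispersion=1e9, minimum=9000),
        )
        truth = _truth_with_ratio(config, 0.5)
        tables = simulate_counts(truth, config)
        assert np.all(np.abs(tables["X"]["ref_ratio"] - 0.5) < 0.02)

    def test_full_escape_forces_balance(self):
        config = SimulationConfig(
            n_samples=20,
            seed=6,
            escape_fraction=0.3,
            escape_pull=1.0,
            ref_bias_fraction=0.0,
            global_imbalance_fraction=0.0,
            depth_per_snp=DistSpec(mean=2000, dispersion=1e9, minimum=1500),
        )
        truth = _truth_with_ratio(config, 0.9)
        tables = simulate_counts(truth, config)
        x = tables["X"].merge(truth.catalogs["X"][["snp_id", "escape"]], on="snp_id")
        esc = x[x["escape"]]
        assert len(esc) > 50
        assert np.all(np.abs(esc["ref_ratio"] - 0.5) < 0.05)

    def test_mean_folded_ratio_matches_folded_binomial_enumeration(self):
        # oracle: per realized depth d, enumerate the d+1 outcomes of
        # Bin(d, 0.8), fold each count, and average the folded ratios
        config = SimulationConfig(
            n_samples=120,
            seed=7,
            snps_per_sample=DistSpec(mean=90, dispersion=1e9, minimum=80),
            depth_per_snp=DistSpec(mean=50, dispersion=1e9, minimum=35),
            escape_fraction=0.0,
            ref_bias_fraction=0.0,
            global_imbalance_fraction=0.0,
        )
        truth = _truth_with_ratio(config, 0.8)
        tables = simulate_counts(truth, config)
        x = tables["X"]

        def folded_mean(d):
            ks = np.arange(d + 1)
            return np.sum(stats.binom.pmf(ks, d, 0.8) * np.maximum(ks, d - ks) / d)

        expected = x["total_reads"].map({d: folded_mean(d) for d in x["total_reads"].unique()}).mean()
        folded = np.maximum(x["ref_ratio"], 1 - x["ref_ratio"])
        assert folded.mean() == pytest.approx(expected, abs=0.005)

    def test_phase_loss_symmetry(self):
        # marginal reference ratio symmetric about 0.5 even for a skewed sample
        config = SimulationConfig(
            n_samples=30,
            seed=8,
            snps_per_sample=DistSpec(mean=100, dispersion=1e9, minimum=90),
            escape_fraction=0.0,
            ref_bias_fraction=0.0,
            global_imbalance_fraction=0.0,
        )
        truth = _truth_with_ratio(config, 0.85)
        tables = simulate_counts(truth, config)
        assert tables["X"]["ref_ratio"].mean() == pytest.approx(0.5, abs=0.02)

    def test_autosomes_balanced_without_imbalance(self):
        config = SimulationConfig(n_samples=30, seed=9, global_imbalance_fraction=0.0, ref_bias_fraction=0.0)
        tables, _ = simulate_dataset(config)
        for chrom in ("A1", "A2"):
            assert tables[chrom]["ref_ratio"].mean() == pytest.approx(0.5, abs=0.02)

    def test_determinism_bit_identical(self):
        config = SimulationConfig(n_samples=40, seed=10)
        t1, g1 = simulate_dataset(config)
        t2, g2 = simulate_dataset(config)
        for chrom in t1:
            pd.testing.assert_frame_equal(t1[chrom], t2[chrom])
        pd.testing.assert_frame_equal(g1.samples, g2.samples)

    def test_variant_carriers_detected_only_in_carriers(self):
        eff = VariantEffect("rs_test", carrier_frequency=0.2, skew_shift=0.3)
        config = SimulationConfig(n_samples=100, seed=11, variant_effects=(eff,))
        tables, truth = simulate_dataset(config)
        vid = truth.catalogs["X"].loc[truth.catalogs["X"]["variant_id"] == "rs_test", "snp_id"].iloc[0]
        carriers = set(
            truth.samples.loc[truth.samples["carrier_variants"].str.contains("rs_test"), "sample_id"]
        )
        observed = set(tables["X"].loc[tables["X"]["snp_id"] == vid, "sample_id"])
        assert observed == carriers
        assert len(carriers) > 0


class TestWriteFixture:
    def test_round_trip(self, tmp_path, default_sim):
        _, tables, truth = default_sim
        paths = write_fixture(tables, truth, tmp_path)
        back = read_counts(paths["counts"])
        combined = pd.concat([tables[k][COUNT_COLUMNS] for k in sorted(tables)], ignore_index=True)
        pd.testing.assert_frame_equal(combined, back[COUNT_COLUMNS])

    def test_carrier_frequency_within_binomial_ci(self, tmp_path):
        eff = VariantEffect("rs_x", carrier_frequency=0.10, skew_shift=0.25)
        config = SimulationConfig(n_samples=400, seed=12, variant_effects=(eff,))
        tables, truth = simulate_dataset(config)
        paths = write_fixture(tables, truth, tmp_path)
        side = pd.read_csv(paths["truth_samples"], sep="\t", keep_default_na=False)
        n_carriers = side["carrier_variants"].str.contains("rs_x").sum()
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 400, 0.10)
        assert lo <= n_carriers <= hi

    def test_empty_tables_write_headers(self, tmp_path):
        config = SimulationConfig(n_samples=1, seed=13)
        truth = generate_truth(config)
        empty = pd.DataFrame(columns=COUNT_COLUMNS)
        paths = write_fixture({"X": empty}, truth, tmp_path)
        assert read_counts(paths["counts"]).empty


def test_global_imbalance_shifts_autosomes():
    config = SimulationConfig(n_samples=40, seed=14, global_imbalance_fraction=1.0, ref_bias_fraction=0.0)
    tables, truth = simulate_dataset(config)
    a1 = tables["A1"]
    folded = np.maximum(a1["ref_ratio"], 1 - a1["ref_ratio"])
    # every sample is imbalanced at >= 0.60, so autosomal folded ratios are high
    assert folded.mean() > 0.57
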