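import itertools

import numpy as np
import pandas as pd
import pytest

from xcimosaic.association import (
    association_report,
    associate_variants,
    bh_adjust,
    bootstrap_power,
    compute_auroc,
    null_auroc,
)
from xcimosaic.counts_io import fold
from xcimosaic.simulate import SimulationConfig, VariantEffect, generate_truth


def brute_force_auroc(pos, neg):
    """Oracle: enumerate all carrier/non-carrier pairs; ties count 1/2."""
    wins = 0.0
    for p, n in itertools.product(pos, neg):
        wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestComputeAuroc:
    def test_perfect_separation(self):
        ratios = np.concatenate([np.linspace(0.8, 0.95, 10), np.linspace(0.5, 0.7, 20)])
        carriers = np.arange(30) < 10
        auroc, p = compute_auroc(ratios, carriers)
        assert auroc == 1.0
        assert p < 0.001

    def test_random_labels_mean_half(self, rng):
        ratios = rng.uniform(0.5, 1.0, 200)
        aurocs = []
        for _ in range(300):
            carriers = np.zeros(200, bool)
            carriers[rng.choice(200, 20, replace=False)] = True
            aurocs.append(compute_auroc(ratios, carriers)[0])
        assert np.mean(aurocs) == pytest.approx(0.5, abs=0.02)

    def test_worked_pair_enumeration(self):
        # carriers hold ranks 1 and 3 of five: 5 winning half-pairs of 6
        ratios = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        carriers = np.array([True, False, True, False, False])
        auroc, _ = compute_auroc(ratios, carriers, min_carriers=2)
        assert auroc == pytest.approx(5 / 6)

    def test_min_carriers_enforced(self, rng):
        ratios = rng.uniform(0.5, 1, 50)
        carriers = np.arange(50) < 5
        with pytest.raises(ValueError, match="carriers"):
            compute_auroc(ratios, carriers)

    def test_oracle_equivalence_on_random_instances(self, rng):
        """AUROC equals brute-force pair enumeration whenever the exact
        small-sample regime applies (npos * nneg <= 400), ties included."""
        for _ in range(50):
            npos = int(rng.integers(2, 15))
            nneg = int(rng.integers(2, min(26, 400 // npos)))
            vals = rng.choice(np.linspace(0.5, 1.0, 12), size=npos + nneg)  # forces ties
            carriers = np.zeros(npos + nneg, bool)
            carriers[:npos] = True
            auroc, _ = compute_auroc(vals, carriers, min_carriers=2)
            assert auroc == pytest.approx(brute_force_auroc(vals[:npos], vals[npos:]))

    def test_complement_symmetry_without_ties(self, rng):
        ratios = rng.permutation(np.linspace(0.5, 1.0, 40))
        carriers = np.zeros(40, bool)
        carriers[rng.choice(40, 15, replace=False)] = True
        a1, _ = compute_auroc(ratios, carriers)
        a2, _ = compute_auroc(ratios, ~carriers)
        assert a1 + a2 == pytest.approx(1.0)

    def test_type_one_error_calibrated(self, rng):
        """Under the null, ~5% of variants reach p <= 0.05."""
        ratios = rng.uniform(0.5, 1.0, 200)
        hits = 0
        n_var = 2000
        for _ in range(n_var):
            carriers = np.zeros(200, bool)
            carriers[rng.choice(200, 20, replace=False)] = True
            _, p = compute_auroc(ratios, carriers)
            hits += p <= 0.05
        assert hits / n_var == pytest.approx(0.05, abs=0.02)


class TestNullAuroc:
    def test_reproducible(self, rng):
        ratios = rng.uniform(0.5, 1, 100)
        assert null_auroc(ratios, 15, seed=3) == null_auroc(ratios, 15, seed=3)

    def test_all_tied_gives_half(self):
        assert null_auroc(np.full(50, 0.7), 10, seed=1) == pytest.approx(0.5)

    def test_centered_at_half(self, rng):
        ratios = rng.uniform(0.5, 1, 150)
        nulls = [null_auroc(ratios, 15, seed=s) for s in range(400)]
        assert np.mean(nulls) == pytest.approx(0.5, abs=0.02)


class TestBhAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        # m=3: 0.01*3/1=0.03, 0.02*3/2=0.03, 0.03*3/3=0.03
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_empty(self):
        assert bh_adjust([]).size == 0


class TestBootstrapPower:
    def test_clear_separation_high_effect_power(self, rng):
        ratios = np.concatenate([rng.uniform(0.85, 1.0, 10), rng.uniform(0.5, 0.7, 100)])
        carriers = np.arange(110) < 10
        power, effect_power, boot_var = bootstrap_power(ratios, carriers, n_boot=400, seed=5)
        assert effect_power > 0.95
        assert power > 0.9
        assert boot_var < 0.01

    def test_null_variant_power_near_alpha(self, rng):
        ratios = rng.uniform(0.5, 1.0, 200)
        carriers = np.zeros(200, bool)
        carriers[rng.choice(200, 30, replace=False)] = True
        power, _, _ = bootstrap_power(ratios, carriers, n_boot=400, seed=6)
        assert power < 0.25

    def test_deterministic_given_seed(self, rng):
        ratios = rng.uniform(0.5, 1.0, 60)
        carriers = np.arange(60) < 12
        a = bootstrap_power(ratios, carriers, n_boot=100, seed=9)
        b = bootstrap_power(ratios, carriers, n_boot=100, seed=9)
        assert a == b


class TestPlantedVariants:
    def test_skew_variant_reaches_moderate_auroc(self):
        """A variant shifting carriers' XCI ratios by 0.25 at 5% frequency is
        recovered with AUROC >= 0.75 in >= 80% of simulated populations."""
        hits = 0
        n_seeds = 10
        for s in range(n_seeds):
            eff = VariantEffect("rs_skew", carrier_frequency=0.05, skew_shift=0.25)
            truth = generate_truth(SimulationConfig(n_samples=500, seed=100 + s, variant_effects=(eff,)))
            ratios = fold(truth.samples["tissue_ratio"].to_numpy())
            carriers = truth.samples["carrier_variants"].str.contains("rs_skew").to_numpy()
            if carriers.sum() < 10:
                continue
            auroc, _ = compute_auroc(ratios, carriers)
            hits += auroc >= 0.75
        assert hits / n_seeds >= 0.8


class TestAssociateVariants:
    def test_report_split_and_moderate_threshold(self):
        results = pd.DataFrame(
            {
                "snp_id": ["a", "b", "c"],
                "auroc": [0.80, 0.74, 0.9],
                "ref_biased": [False, False, True],
            }
        )
        main, companion, moderate = association_report(results)
        assert list(main["snp_id"]) == ["a", "b"]
        assert list(companion["snp_id"]) == ["c"]
        assert list(moderate["snp_id"]) == ["a"]  # 0.74 misses the cut

    def test_empty_input(self):
        main, companion, moderate = association_report(pd.DataFrame())
        assert main.empty and companion.empty and moderate.empty

    def test_pipeline_level_planted_variant(self, rng):
        """End to end on counts: the planted skew variant is among the
        highest-AUROC variants and is excluded when reference-biased."""
        from xcimosaic.simulate import simulate_dataset
        from xcimosaic.folded_model import estimate_all_samples
        from xcimosaic.counts_io import depth_filter, max_power_per_gene

        eff = VariantEffect("rs_skew", carrier_frequency=0.08, skew_shift=0.3)
        config = SimulationConfig(
            n_samples=250, seed=33, variant_effects=(eff,), global_imbalance_fraction=0.0
        )
        tables, truth = simulate_dataset(config)
        modeling = max_power_per_gene(depth_filter(tables["X"], mode="total_depth_only"))
        est = estimate_all_samples(modeling)
        results = associate_variants(tables["X"], est, seed=1)
        vid = truth.catalogs["X"].loc[truth.catalogs["X"]["variant_id"] == "rs_skew", "snp_id"].iloc[0]
        row = results[results["snp_id"] == vid]
        assert len(row) == 1
        assert row["auroc"].iloc[0] >= 0.75
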