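"""Generator contracts: planted structure, zero-noise exactness, determinism."""

import json

import numpy as np
import pytest

from coregmap.config import SimulationConfig
from coregmap.synthetic import (
    build_layout,
    class_mean_trajectories,
    make_tile_grid,
    reporter_condition_mean,
    simulate_all,
    simulate_chip_experiment,
    simulate_expression_timecourse,
    simulate_reporter_assays,
    write_fixture_bundle,
)


class TestTileGrid:
    def test_closed_form_matches_enumeration(self):
        """Tile count floor((L - tile)/step) + 1, checked by explicitly
        enumerating valid start positions."""
        config = SimulationConfig()
        tiles = make_tile_grid(config)
        starts = list(
            range(0, config.genome_length - config.tile_length + 1, config.tile_step)
        )
        assert len(tiles) == len(starts)
        assert len(tiles) == (
            (config.genome_length - config.tile_length) // config.tile_step + 1
        )
        assert [t.start for t in tiles] == starts

    def test_grid_not_covering_genome_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(genome_length=1000, tile_length=3000, tile_step=1500)


class TestConfigValidation:
    def test_step_larger_than_tile_rejected(self):
        with pytest.raises(ValueError, match="tile_step"):
            SimulationConfig(tile_step=4000)

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(class_proportions={"null": 0.5, "down_both": 0.4})

    def test_cobind_fraction_range(self):
        with pytest.raises(ValueError):
            SimulationConfig(cobind_fraction=1.4)


class TestChipSimulation:
    def test_zero_noise_site_inside_tile_gives_exact_effect(self):
        config = SimulationConfig(
            genome_length=300_000,
            n_genes=100,
            n_bound_A=5,
            n_bound_B=5,
            chip_noise_sd=0.0,
            n_offtarget_per_antibody=0,
            antibody_efficiency=(1.0, 1.0),
            seed=7,
        )
        matrices, fragments, truth = simulate_chip_experiment(config)
        data = matrices["A"].data
        site = truth.sites_for("A")[0]
        tp = site.timepoints[0]
        containing = [
            f.id for f in fragments if f.start <= site.start and site.end <= f.end
        ]
        assert containing
        ip_cols = [c for c in data.columns if f"_ip_{tp}_" in c]
        mock_cols = [c for c in data.columns if f"_mock_{tp}_" in c]
        np.testing.assert_allclose(
            data.loc[containing[0], ip_cols], config.chip_effect_log2
        )
        np.testing.assert_allclose(data[mock_cols].to_numpy(), 0.0)

    def test_planted_counts_and_cobind_fraction(self, small_config, small_sim):
        truth = small_sim["truth"]
        n_A = len(truth.sites_for("A"))
        n_B = len(truth.sites_for("B"))
        n_cob = len([s for s in truth.sites if set(s.factors) == {"A", "B"}])
        assert n_A == small_config.n_bound_A
        assert n_B == small_config.n_bound_B
        assert n_cob == round(small_config.cobind_fraction * small_config.n_bound_A)

    def test_sites_inside_genome_and_disjoint(self, small_config, small_sim):
        sites = sorted(small_sim["truth"].sites, key=lambda s: s.start)
        for s in sites:
            assert 0 <= s.start < s.end <= small_config.genome_length
        for s1, s2 in zip(sites, sites[1:]):
            assert s1.end <= s2.start

    def test_every_nonnull_gene_links_to_a_region(self, small_sim):
        truth = small_sim["truth"]
        for gene, cls in truth.gene_class.items():
            if cls != "null":
                assert truth.gene_region_links.get(gene)


class TestExpressionSimulation:
    def test_zero_noise_class_trajectory_exact(self):
        config = SimulationConfig(
            genome_length=300_000, n_genes=100, n_bound_A=5, n_bound_B=5,
            expr_noise_sd=0.0, expr_effect_log2=1.5, seed=3,
        )
        tensors, gene_ids, truth = simulate_expression_timecourse(config)
        down_both = [
            i for i, g in enumerate(gene_ids) if truth.gene_class[g] == "down_both"
        ]
        assert down_both
        i = down_both[0]
        for mutant in ("A_mut", "B_mut"):
            affected = tensors[mutant][i, 2:, :]  # timepoints 3-6
            np.testing.assert_allclose(affected, -1.5)
            np.testing.assert_allclose(tensors[mutant][i, :2, :], 0.0)

    def test_all_null_mixture_centers_at_zero(self):
        config = SimulationConfig(
            genome_length=600_000, n_genes=400, n_bound_A=0, n_bound_B=0,
            class_proportions={"null": 1.0}, seed=11,
        )
        tensors, _, truth = simulate_expression_timecourse(config)
        assert set(truth.gene_class.values()) == {"null"}
        grand = tensors["A_mut"].mean()
        se = config.expr_noise_sd / np.sqrt(tensors["A_mut"].size)
        assert abs(grand) < 4 * se

    def test_planted_mean_recovered_within_3_se(self, small_config, small_sim):
        """Monte-Carlo check of the generative mean for down_both genes."""
        truth = small_sim["truth"]
        tensors = small_sim["expression"]
        gene_ids = small_sim["gene_ids"]
        idx = [
            i for i, g in enumerate(gene_ids) if truth.gene_class[g] == "down_both"
        ]
        values = tensors["A_mut"][idx, 2:, :]  # affected timepoints
        se = small_config.expr_noise_sd / np.sqrt(values.size)
        assert abs(values.mean() - (-small_config.expr_effect_log2)) < 3 * se


class TestReporterSimulation:
    def test_additive_worked_example(self):
        """Planted folds 3.6 and 2.4 yield a combined mean of exactly 5."""
        f_AB = reporter_condition_mean(
            "additive", 3.6, 2.4, 10.0, 10.0, synergy_gamma=1.0, repression_kappa=0.3
        )
        assert f_AB == pytest.approx(5.0)

    def test_repression_vanishes_without_repressor(self):
        f = reporter_condition_mean(
            "repressive", 1.0, 3.0, 0.0, 10.0, synergy_gamma=1.0, repression_kappa=0.3
        )
        assert f == pytest.approx(3.0)

    def test_cooperative_reduces_to_additive_at_gamma_zero(self):
        coop = reporter_condition_mean(
            "cooperative", 2.0, 3.0, 10.0, 10.0, synergy_gamma=0.0, repression_kappa=0.3
        )
        add = reporter_condition_mean(
            "additive", 2.0, 3.0, 10.0, 10.0, synergy_gamma=0.0, repression_kappa=0.3
        )
        assert coop == pytest.approx(add)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            reporter_condition_mean(
                "additive", 2.0, 2.0, -1.0, 0.0, synergy_gamma=0, repression_kappa=0
            )

    def test_replicate_count_and_control_rows(self, small_config, small_sim):
        table = small_sim["reporters"]
        counts = table.groupby(["enhancer", "dose_A_ng", "dose_B_ng"]).size()
        assert (counts == small_config.n_reporter_replicates).all()
        assert ((table.dose_A_ng == 0) & (table.dose_B_ng == 0)).any()


class TestDeterminismAndBundle:
    def test_same_seed_same_manifest(self, small_config, tmp_path):
        m1 = write_fixture_bundle(simulate_all(small_config), tmp_path / "a")
        m2 = write_fixture_bundle(simulate_all(small_config), tmp_path / "b")
        assert m1["files"] == m2["files"]

    def test_different_seed_differs(self, small_config, tmp_path):
        cfg2 = SimulationConfig(**{**small_config.to_dict(), "seed": 43})
        m1 = write_fixture_bundle(simulate_all(small_config), tmp_path / "a")
        m2 = write_fixture_bundle(simulate_all(cfg2), tmp_path / "b")
        assert m1["files"] != m2["files"]

    def test_truth_region_bed_matches_planted_count(self, small_config, small_sim, tmp_path):
        write_fixture_bundle(small_sim, tmp_path)
        lines = (tmp_path / "truth_regions_A.bed").read_text().strip().splitlines()
        assert len(lines) == small_config.n_bound_A

    def test_truth_json_round_trip(self, small_sim, tmp_path):
        from coregmap.synthetic import GroundTruth

        write_fixture_bundle(small_sim, tmp_path)
        loaded = GroundTruth.from_dict(
            json.loads((tmp_path / "truth.json").read_text())
        )
        assert loaded.gene_class == small_sim["truth"].gene_class
        assert loaded.sites == small_sim["truth"].sites

    def test_layout_deterministic(self, small_config):
        g1, t1 = build_layout(small_config)
        g2, t2 = build_layout(small_config)
        assert g1 == g2
        assert t1.sites == t2.sites


class TestClassTrajectories:
    def test_divergent_mirrors_between_mutants(self):
        traj = class_mean_trajectories("divergent", 6, 1.5)
        np.testing.assert_allclose(traj["A_mut"], [0, 0, 0, -1.5, -1.5, -1.5])
        np.testing.assert_allclose(traj["B_mut"], [0, 0, 0, 1.5, 1.5, 1.5])

    def test_null_is_flat(self):
        traj = class_mean_trajectories("null", 6, 1.5)
        assert not traj["A_mut"].any() and not traj["B_mut"].any()
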