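import numpy as np
import pytest

from conftest import make_chain_network
from synoptic.exceptions import ConfigError
from synoptic.leverage import subcatchment_leverage
from synoptic.simulate import (
    SEASONS,
    SimConfig,
    generate_network,
    generate_source_field,
    generate_source_fields,
    partition_patches,
    route_and_mix,
    simulate_dataset,
    study_design,
)


class TestGenerateNetwork:
    def test_minimal_tree_two_headwaters(self):
        net = generate_network(SimConfig(watershed_id="W", n_headwaters=2, seed=0))
        assert net.n_sites == 3
        assert len(net.leaves()) == 2

    @pytest.mark.parametrize("n_hw", [2, 8, 30])
    def test_binary_merge_tree_shape(self, n_hw):
        net = generate_network(SimConfig(watershed_id="W", n_headwaters=n_hw, seed=3))
        assert net.n_sites == 2 * n_hw - 1
        assert len(net.leaves()) == n_hw
        assert all(len(k) in (0, 2) for k in net.children.values())

    def test_incremental_areas_accumulate(self):
        net = generate_network(SimConfig(watershed_id="W", n_headwaters=12, seed=1))
        assert sum(net.incremental_area.values()) == pytest.approx(
            net.total_area_km2, rel=1e-12
        )

    def test_same_seed_identical_networks(self):
        cfg = SimConfig(watershed_id="W", n_headwaters=15, seed=9)
        n1, n2 = generate_network(cfg), generate_network(cfg)
        assert {s: r.downstream_id for s, r in n1.sites.items()} == {
            s: r.downstream_id for s, r in n2.sites.items()
        }
        assert all(
            n1.area(s) == n2.area(s) for s in n1.sites
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            generate_network(SimConfig(n_headwaters=1))
        with pytest.raises(ConfigError):
            SimConfig(rho_season=1.5).validate()
        with pytest.raises(ConfigError):
            SimConfig(patch_area_km2=-1).validate()


class TestPartitionPatches:
    def test_whole_watershed_single_patch_when_target_exceeds_area(self):
        net = generate_network(SimConfig(watershed_id="W", n_headwaters=8, seed=2))
        with pytest.warns(UserWarning, match="one patch"):
            patches = partition_patches(net, net.total_area_km2 * 2)
        assert len(set(patches.values())) == 1
        assert set(patches) == set(net.sites)

    def test_tiny_target_every_reach_its_own_patch(self):
        net = generate_network(SimConfig(watershed_id="W", n_headwaters=8, seed=2))
        a_min = min(net.incremental_area.values())
        patches = partition_patches(net, a_min * 0.99)
        assert len(set(patches.values())) == net.n_sites

    def test_chain_greedy_rule(self):
        # 4 reaches of incremental area 1 each, target 2 -> two 2-reach patches
        net = make_chain_network([1, 2, 3, 4])
        patches = partition_patches(net, 2.0)
        assert patches["s0"] == patches["s1"]
        assert patches["s2"] == patches["s3"]
        assert patches["s0"] != patches["s2"]

    @pytest.mark.parametrize("seed", range(3))
    def test_partition_covers_and_bounds_patch_areas(self, seed):
        net = generate_network(SimConfig(watershed_id="W", n_headwaters=20, seed=seed))
        a_p = 6.0
        patches = partition_patches(net, a_p)
        assert set(patches) == set(net.sites)
        areas = {}
        for sid, p in patches.items():
            areas[p] = areas.get(p, 0.0) + net.incremental_area[sid]
        assert sum(areas.values()) == pytest.approx(net.total_area_km2, rel=1e-9)
        a_max = max(net.incremental_area.values())
        outlet_patch = patches[net.outlet_id]
        for p, a in areas.items():
            if p != outlet_patch:  # the outlet patch may close undersized
                # overshoot bounded by the largest chunk merged in
                assert a_p <= a < a_p + max(a_p, a_max) + 1e-9


class TestSourceFields:
    def test_no_noise_gives_baseline_everywhere(self):
        cfg = SimConfig(watershed_id="W", n_headwaters=10, patch_sd=0.0,
                        local_sd=0.0, seed=4)
        net = generate_network(cfg)
        patches = partition_patches(net, cfg.patch_area_km2)
        n_p = len(set(patches.values()))
        field = generate_source_field(
            net, patches, cfg, np.ones(n_p), np.ones(net.n_sites)
        )
        assert all(v == cfg.baseline_concentration for v in field.values())

    def test_rho_one_gives_identical_seasons(self, rng):
        cfg = SimConfig(watershed_id="W", n_headwaters=10, rho_season=1.0, seed=4)
        net = generate_network(cfg)
        patches = partition_patches(net, cfg.patch_area_km2)
        fields = generate_source_fields(net, patches, cfg, rng)
        assert fields["early"] == fields["late"]

    def test_rho_zero_fields_uncorrelated_over_seeds(self):
        """With rho=0 the median cross-season Spearman r_s sits near zero."""
        from synoptic.recovery import stability_recovery

        df = stability_recovery(rhos=(0.0,), n_seeds=50, base_seed=0)
        assert abs(float(df["r_s"].median())) < 0.1

    def test_sources_truncated_at_zero(self):
        cfg = SimConfig(watershed_id="W", n_headwaters=10, patch_sd=50.0, seed=4)
        net = generate_network(cfg)
        patches = partition_patches(net, cfg.patch_area_km2)
        rng = np.random.default_rng(0)
        fields = generate_source_fields(net, patches, cfg, rng)
        assert min(fields["early"].values()) >= 0.0


class TestRouting:
    def test_uniform_sources_pass_through_unchanged(self):
        net = generate_network(SimConfig(watershed_id="W", n_headwaters=12, seed=5))
        conc = route_and_mix(net, {s: 3.7 for s in net.sites}, k_r=0.0)
        assert all(v == pytest.approx(3.7, rel=1e-12) for v in conc.values())

    @pytest.mark.parametrize("n_hw", [10, 100])
    def test_outlet_matches_flattened_area_weighted_mean(self, n_hw, rng):
        """Conservative routing equals the flatten-the-tree oracle."""
        net = generate_network(SimConfig(watershed_id="W", n_headwaters=n_hw, seed=6))
        sources = {s: float(v) for s, v in
                   zip(sorted(net.sites), rng.random(net.n_sites) * 10)}
        conc = route_and_mix(net, sources, k_r=0.0)
        oracle = sum(
            net.incremental_area[s] * sources[s] for s in net.sites
        ) / net.total_area_km2
        assert conc[net.outlet_id] == pytest.approx(oracle, rel=1e-12)
        # every interior node obeys the same identity on its own subtree
        for sid in net.sites:
            subtree_mass, stack = 0.0, [sid]
            while stack:
                cur = stack.pop()
                subtree_mass += net.incremental_area[cur] * sources[cur]
                stack.extend(net.children[cur])
            assert conc[sid] == pytest.approx(
                subtree_mass / net.area(sid), rel=1e-12
            )

    def test_removal_lowers_outlet_below_conservative(self, rng):
        net = generate_network(SimConfig(watershed_id="W", n_headwaters=15, seed=7))
        sources = {s: float(v) + 1 for s, v in
                   zip(sorted(net.sites), rng.random(net.n_sites))}
        c0 = route_and_mix(net, sources, k_r=0.0)
        c1 = route_and_mix(net, sources, k_r=0.3)
        assert c1[net.outlet_id] < c0[net.outlet_id]


class TestSimulateDataset:
    def test_study_design_cardinality(self):
        configs, params = study_design(seed=0)
        ds, truth = simulate_dataset(configs, solute_params=params)
        assert sum(len(s) for s in ds.sites.values()) == 114
        assert {len(s) for s in ds.sites.values()} == {31, 41, 42}
        assert len(truth) == 9  # watershed x solute
        assert ds.n_cells() == 114 * 2 * 3

    def test_truth_round_trips_through_csv(self, tmp_path):
        configs, params = study_design(seed=1)
        _, truth = simulate_dataset(configs, solute_params=params)
        p = tmp_path / "truth.csv"
        truth.to_csv(p, index=False)
        import pandas as pd

        back = pd.read_csv(p)
        pd.testing.assert_frame_equal(back, truth, check_dtype=False)

    def test_conservative_watershed_keeps_leverage_contract(self):
        cfg = SimConfig(watershed_id="W", n_headwaters=12, k_r=0.0, seed=8)
        ds, _ = simulate_dataset([cfg], solutes=("DOC",))
        res = subcatchment_leverage(
            ds.network("W"), SEASONS[0], "DOC", partition="incremental"
        )
        assert res.summary_stats.mean == pytest.approx(0.0, abs=1e-9)

    def test_oversampling_rejected(self):
        cfg = SimConfig(watershed_id="W", n_headwaters=8, n_sites_sampled=99)
        with pytest.raises(ConfigError):
            simulate_dataset([cfg])

    def test_too_few_headwaters_rejected(self):
        with pytest.raises(ConfigError, match="n_headwaters"):
            simulate_dataset([SimConfig(watershed_id="W", n_headwaters=4)])

    def test_deterministic_under_seed(self):
        cfg = SimConfig(watershed_id="W", n_headwaters=10, seed=11,
                        n_sites_sampled=12)
        ds1, t1 = simulate_dataset([cfg])
        ds2, t2 = simulate_dataset([cfg])
        assert t1.equals(t2)
        for sid, rec in ds1.sites["W"].items():
            assert ds2.sites["W"][sid].concentrations == rec.concentrations

    def test_sampled_subnetwork_is_valid_and_nested(self):
        cfg = SimConfig(watershed_id="W", n_headwaters=20, seed=12,
                        n_sites_sampled=15)
        ds, _ = simulate_dataset([cfg])
        net = ds.network("W")
        assert net.n_sites == 15
        assert sum(net.incremental_area.values()) == pytest.approx(
            net.total_area_km2, rel=1e-9
        )
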