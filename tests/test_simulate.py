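import numpy as np
import pytest

from nucorg.errors import ValidationError
from nucorg.genome import probes_overlapping
from nucorg.permutation import mean_diff_statistic
from nucorg.simulate import (
    FeaturePlan,
    OccupancyModel,
    SignalModel,
    SimulationConfig,
    make_genome_and_features,
    simulate_occupancy,
    simulate_probe_signal,
    simulate_spots,
    tile_probes,
    write_simulation,
)
from nucorg.zones import assign_zone


class TestGenomeGeneration:
    def test_feature_counts_and_no_overlap(self):
        cfg = SimulationConfig(
            seed=3,
            chromosomes=(100_000, 100_000),
            features=(FeaturePlan("tRNA", count=20, length=80),),
        )
        _, fs = make_genome_and_features(cfg)
        assert len(fs) == 20
        assert fs.classes == {"tRNA"}
        ivs = sorted((f.interval.chrom, f.interval.start, f.interval.end)
                     for f in fs)
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            assert c1 != c2 or e1 <= s2

    def test_subtelomere_plan_covers_both_ends(self):
        cfg = SimulationConfig(
            seed=0,
            chromosomes=(100_000, 100_000),
            features=(FeaturePlan("subtelomere", length=10_000,
                                  placement="ends"),),
        )
        layout, fs = make_genome_and_features(cfg)
        subs = [f for f in fs if f.feature_class == "subtelomere"]
        assert len(subs) == 4
        assert all(len(f.interval) == 10_000 for f in subs)
        starts = {(f.interval.chrom, f.interval.start) for f in subs}
        assert ("I", 0) in starts and ("II", 0) in starts

    def test_same_seed_gives_byte_identical_gff(self, tmp_path):
        cfg = SimulationConfig(seed=11)
        make_genome_and_features(cfg, tmp_path / "a")
        make_genome_and_features(cfg, tmp_path / "b")
        assert (tmp_path / "a/features.gff3").read_bytes() == \
               (tmp_path / "b/features.gff3").read_bytes()

    def test_infeasible_placement_reports(self):
        cfg = SimulationConfig(
            seed=1,
            chromosomes=(2_000,),
            features=(FeaturePlan("tRNA", count=50, length=200),),
        )
        with pytest.raises(ValidationError, match="place"):
            make_genome_and_features(cfg)


class TestSignalSimulation:
    def test_lag1_autocorrelation_matches_rho(self):
        cfg = SimulationConfig(
            seed=8, chromosomes=(3_000_000,), probe_step=60,
            features=(FeaturePlan("tRNA", count=1, length=80),),
            signal=SignalModel(rho=0.7, sd=0.5),
        )
        layout, fs = make_genome_and_features(cfg)
        _, _, ratio = simulate_probe_signal(layout, fs, cfg)
        x = ratio.value
        assert x.size == 50_000
        x = x - x.mean()
        rho_hat = (x[:-1] * x[1:]).sum() / (x * x).sum()
        assert abs(rho_hat - 0.7) < 0.02
        assert abs(x.std() - 0.5) < 0.02

    def test_zero_effect_has_no_class_bias(self):
        cfg = SimulationConfig(
            seed=2, chromosomes=(120_000,),
            features=(FeaturePlan("tRNA", count=30, length=400),),
        )
        layout, fs = make_genome_and_features(cfg)
        grid = tile_probes(layout, cfg.probe_step)
        mask = probes_overlapping(fs, grid, {"tRNA"})
        stats = []
        rng = np.random.default_rng(5)
        for _ in range(60):
            _, _, ratio = simulate_probe_signal(layout, fs, cfg, rng)
            stats.append(mean_diff_statistic(ratio.value, mask))
        se = np.std(stats) / np.sqrt(len(stats))
        assert abs(np.mean(stats)) < 3 * se + 1e-3

    def test_ratio_consistent_with_condition_over_control(self):
        cfg = SimulationConfig(seed=4, chromosomes=(60_000,),
                               features=(FeaturePlan("tRNA", 5, 80),),
                               signal=SignalModel(effects={"tRNA": 1.0}))
        layout, fs = make_genome_and_features(cfg)
        cond, ctrl, ratio = simulate_probe_signal(layout, fs, cfg)
        assert np.allclose(np.log2(cond.value / ctrl.value), ratio.value)

    def test_effect_recovered_by_mean_difference(self):
        cfg = SimulationConfig(
            seed=6, chromosomes=(300_000,), probe_step=60,
            features=(FeaturePlan("tRNA", count=75, length=400),),
            signal=SignalModel(effects={"tRNA": 1.0}),
        )
        layout, fs = make_genome_and_features(cfg)
        grid = tile_probes(layout, cfg.probe_step)
        mask = probes_overlapping(fs, grid, {"tRNA"})
        rng = np.random.default_rng(7)
        stats = [
            mean_diff_statistic(
                simulate_probe_signal(layout, fs, cfg, rng)[2].value, mask
            )
            for _ in range(25)
        ]
        assert abs(np.mean(stats) - 1.0) < 0.1


class TestOccupancySimulation:
    def test_rows_are_paired_and_nonnegative(self):
        cfg = SimulationConfig(seed=5)
        _, fs = make_genome_and_features(cfg)
        tab = simulate_occupancy(fs, cfg)
        assert len(tab) == len(fs)
        assert (tab.df["mean_a"] >= 0).all() and (tab.df["mean_b"] >= 0).all()

    def test_poisson_limit_of_dispersion(self):
        cfg = SimulationConfig(
            seed=10,
            features=(FeaturePlan("tRNA", count=40, length=80),),
            occupancy=OccupancyModel(mean=100.0, dispersion=np.inf),
        )
        _, fs = make_genome_and_features(cfg)
        rng = np.random.default_rng(0)
        draws = np.concatenate([
            simulate_occupancy(fs, cfg, rng).df["mean_a"].to_numpy()
            for _ in range(100)
        ])
        ratio = draws.var() / draws.mean()
        assert abs(ratio - 1.0) < 0.05

    def test_overdispersion_at_finite_dispersion(self):
        cfg = SimulationConfig(
            seed=10,
            features=(FeaturePlan("tRNA", count=40, length=80),),
            occupancy=OccupancyModel(mean=100.0, dispersion=10.0),
        )
        _, fs = make_genome_and_features(cfg)
        rng = np.random.default_rng(0)
        draws = np.concatenate([
            simulate_occupancy(fs, cfg, rng).df["mean_a"].to_numpy()
            for _ in range(100)
        ])
        # NB variance = mu + mu^2/k = 100 + 1000
        assert draws.var() / draws.mean() > 5


class TestSpotSimulation:
    def test_generator_matches_assigner_exactly(self):
        cfg = SimulationConfig(seed=21)
        spots = simulate_spots(cfg, "wildtype", 2_000)
        zones = [assign_zone(m) for m in spots]
        # recovered zone-1 fraction near the preset 0.75
        frac1 = np.mean([z == 1 for z in zones])
        assert abs(frac1 - 0.75) < 0.03

    def test_extreme_preset_pins_all_spots_peripheral(self):
        cfg = SimulationConfig(seed=1)
        cfg.spot_presets["pinned"] = (1.0, 0.0, 0.0)
        spots = simulate_spots(cfg, "pinned", 500)
        assert all(assign_zone(m) == 1 for m in spots)

    def test_uniform_preset_is_uniform_in_ball(self):
        cfg = SimulationConfig(seed=33)
        spots = simulate_spots(cfg, "uniform", 30_000)
        zones = np.array([assign_zone(m) for m in spots])
        frac = np.bincount(zones, minlength=4)[1:] / zones.size
        assert np.all(np.abs(frac - 1 / 3) < 0.01)

    def test_unknown_strain_rejected(self):
        with pytest.raises(ValidationError, match="preset"):
            simulate_spots(SimulationConfig(), "nope", 10)


class TestFixtureDirectory:
    def test_full_simulation_is_deterministic(self, tmp_path):
        cfg = SimulationConfig(seed=9)
        paths_a = write_simulation(cfg, tmp_path / "a")
        paths_b = write_simulation(cfg, tmp_path / "b")
        for name in paths_a:
            assert paths_a[name].read_bytes() == paths_b[name].read_bytes(), name
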