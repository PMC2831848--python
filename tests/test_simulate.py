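"""Simulation harness: neutral scenarios, sweep engine, grids, trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from hacsweep._engine import RecombinationMap, sweep_trajectory
from hacsweep.core import build_marh, hac_variance, split_by_allele
from hacsweep.simulate import (
    Bottleneck,
    ConfigError,
    Expansion,
    ScenarioConfig,
    Selection,
    scenario_grid,
    simulate_neutral,
    simulate_sweep,
    watterson_expected_sites,
)


def pairwise_diversity(window) -> float:
    n = window.n
    d = window.alleles.sum(axis=0)
    return float(np.sum(2.0 * d * (n - d) / (n * (n - 1))))


class TestNeutral:
    def test_segregating_sites_match_watterson(self, neutral_reps):
        counts = np.array([w.S for w in neutral_reps.replicates], dtype=float)
        expect = watterson_expected_sites(50, 223.0)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - expect) < 3 * se

    def test_selection_config_rejected(self):
        cfg = ScenarioConfig(selection=Selection(s=0.1, f=0.5))
        with pytest.raises(ConfigError):
            simulate_neutral(cfg, 2)

    def test_regenerable_bit_identical(self):
        cfg = ScenarioConfig(theta=40.0, seed=99)
        a = simulate_neutral(cfg, 3)
        b = simulate_neutral(cfg, 3)
        for wa, wb in zip(a.replicates, b.replicates):
            assert np.array_equal(wa.alleles, wb.alleles)
            assert np.array_equal(wa.positions, wb.positions)

    def test_no_recombination_passes_four_gamete_check(self):
        cfg = ScenarioConfig(theta=60.0, seed=3)
        reps = simulate_neutral(cfg, 5)
        for rep in reps.replicates:
            a = rep.alleles
            # sample site pairs; with one genealogy at most 3 gametes exist
            rng = np.random.default_rng(0)
            for _ in range(200):
                i, j = rng.integers(rep.S, size=2)
                if i == j:
                    continue
                gametes = {tuple(g) for g in a[:, [i, j]]}
                assert len(gametes) <= 3

    def test_bottleneck_reduces_diversity(self):
        n_reps = 150
        base = ScenarioConfig(theta=60.0, seed=77)
        bott = ScenarioConfig(theta=60.0, seed=78, demography=Bottleneck())
        pi_base = np.mean(
            [pairwise_diversity(w) for w in simulate_neutral(base, n_reps).replicates]
        )
        pi_bott = np.mean(
            [pairwise_diversity(w) for w in simulate_neutral(bott, n_reps).replicates]
        )
        assert pi_bott < pi_base

    def test_expansion_scenario_runs(self):
        cfg = ScenarioConfig(theta=30.0, seed=5, demography=Expansion())
        reps = simulate_neutral(cfg, 3)
        assert all(w.S > 0 for w in reps.replicates)

    def test_min_flank_regeneration(self):
        cfg = ScenarioConfig(theta=8.0, seed=13)  # ~35 SNPs: thin flanks common
        reps = simulate_neutral(cfg, 10, min_flank=12)
        for w in reps.replicates:
            k = w.evaluated_index
            assert k >= 12 and w.S - 1 - k >= 12


class TestSweep:
    def test_regenerable_bit_identical(self):
        cfg = ScenarioConfig(theta=40.0, seed=21, selection=Selection(s=0.2, f=0.7))
        a = simulate_sweep(cfg, 3)
        b = simulate_sweep(cfg, 3)
        for wa, wb in zip(a.replicates, b.replicates):
            assert np.array_equal(wa.alleles, wb.alleles)
            assert wa.evaluated_index == wb.evaluated_index

    def test_selected_site_central_and_frequency_conditioned(self, sweep_reps):
        freqs = []
        for w in sweep_reps.replicates:
            k = w.evaluated_index
            pos = w.positions[k]
            assert abs(pos - 25000.0) < 1.0  # selected site at the locus centre
            freqs.append(w.alleles[:, k].mean())
        freqs = np.asarray(freqs)
        # sample counts are Binomial(50, 0.75) draws
        se = np.sqrt(0.75 * 0.25 / 50 / freqs.size)
        assert abs(freqs.mean() - 0.75) < 4 * se

    def test_strong_sweep_compresses_selected_class_variance(self):
        cfg = ScenarioConfig(seed=31, selection=Selection(s=0.5, f=0.9))
        reps = simulate_sweep(cfg, 40, min_flank=26)
        diffs = []
        for w in reps.replicates:
            ref = build_marh(w)
            major, minor = split_by_allele(w, w.evaluated_index, ref)
            if major.shape[0] < 2 or minor.shape[0] < 2:
                continue
            h_major = np.count_nonzero(major != ref.alleles[None, :], axis=1)
            h_minor = np.count_nonzero(minor != ref.alleles[None, :], axis=1)
            diffs.append(hac_variance(h_minor) - hac_variance(h_major))
        assert np.mean(diffs) > 0  # carriers of the selected allele are tighter

    def test_sweep_reduces_diversity_vs_conditioned_null(
        self, sweep_reps, conditioned_null_reps
    ):
        pi_alt = np.mean([pairwise_diversity(w) for w in sweep_reps.replicates])
        pi_null = np.mean(
            [pairwise_diversity(w) for w in conditioned_null_reps.replicates]
        )
        assert pi_alt < pi_null

    def test_s_zero_is_frequency_conditioned_neutral(self, conditioned_null_reps):
        freqs = [
            w.alleles[:, w.evaluated_index].mean()
            for w in conditioned_null_reps.replicates
        ]
        assert abs(np.mean(freqs) - 0.75) < 0.05

    def test_demography_with_selection_unsupported(self):
        cfg = ScenarioConfig(
            selection=Selection(s=0.1, f=0.6), demography=Bottleneck()
        )
        with pytest.raises(ConfigError):
            simulate_sweep(cfg, 1)


class TestTrajectory:
    def test_deterministic_logistic_endpoints(self, rng):
        x, dt = sweep_trajectory(rng, f=0.75, s=0.15, N=1000.0, stochastic=False)
        assert x[0] == pytest.approx(0.75)
        assert x[-1] >= 1.0 / 2000.0
        assert np.all(np.diff(x) <= 0)  # monotone decline backwards

    def test_stochastic_starts_at_f_and_absorbs(self, rng):
        for _ in range(5):
            x, dt = sweep_trajectory(rng, f=0.75, s=0.15, N=1000.0)
            assert x[0] == pytest.approx(0.75)
            assert np.all((x > 0) & (x < 1))

    def test_stronger_selection_shortens_sweep(self, rng):
        dur = {}
        for s in (0.05, 0.5):
            lens = [
                sweep_trajectory(rng, 0.75, s, 1000.0)[1]
                * len(sweep_trajectory(rng, 0.75, s, 1000.0)[0])
                for _ in range(10)
            ]
            dur[s] = np.mean(lens)
        assert dur[0.5] < dur[0.05]


class TestGridAndConfig:
    def test_grid_cartesian(self):
        base = ScenarioConfig(seed=1)
        grid = scenario_grid(base, [0.6, 0.7, 0.75, 0.8, 0.9], [0.05, 0.15, 0.5])
        assert len(grid) == 15
        seeds = {cfg.seed for cfg in grid}
        assert len(seeds) == 15
        pairs = {(cfg.selection.f, cfg.selection.s) for cfg in grid}
        assert len(pairs) == 15

    def test_empty_grid(self):
        assert scenario_grid(ScenarioConfig(seed=1), [0.6], []) == []

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            ScenarioConfig(theta=0.0)
        with pytest.raises(ConfigError):
            ScenarioConfig(n=1)
        with pytest.raises(ConfigError):
            Selection(s=0.1, f=1.5)
        with pytest.raises(ConfigError):
            ScenarioConfig(hotspots=((1000.0, 0.5),))

    def test_matched_null_keeps_frequency(self):
        cfg = ScenarioConfig(selection=Selection(s=0.15, f=0.75), seed=4)
        null = cfg.matched_null()
        assert null.selection.s == 0.0
        assert null.selection.f == 0.75
        assert null.theta == cfg.theta


class TestRecombinationMap:
    def test_uniform_total(self):
        rm = RecombinationMap.uniform_with_hotspots(111.5, 1000.0, 50000.0)
        assert rm.total == pytest.approx(111.5 / 4000.0)
        assert rm.map_length(0, 25000.0) == pytest.approx(rm.total / 2)

    def test_hotspot_multiplies_local_rate(self):
        rm = RecombinationMap.uniform_with_hotspots(
            111.5, 1000.0, 50000.0, hotspots=((27000.0, 10.0),), hotspot_width=2000.0
        )
        base = 111.5 / 4000.0 / 50000.0
        inside = rm.map_length(27000.0, 29000.0)
        outside = rm.map_length(10000.0, 12000.0)
        assert inside == pytest.approx(10 * outside)
        assert outside == pytest.approx(base * 2000.0)

    def test_breakpoint_sampling_respects_map(self):
        rm = RecombinationMap.uniform_with_hotspots(
            100.0, 1000.0, 50000.0, hotspots=((27000.0, 100.0),), hotspot_width=2000.0
        )
        rng = np.random.default_rng(0)
        bps = np.array(
            [rm.sample_breakpoint(0.0, 50000.0, rng.random()) for _ in range(4000)]
        )
        frac_in_hotspot = np.mean((bps >= 27000.0) & (bps < 29000.0))
        expect = rm.map_length(27000.0, 29000.0) / rm.total
        assert abs(frac_in_hotspot - expect) < 0.03
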