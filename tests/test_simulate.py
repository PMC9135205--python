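import numpy as np
import pytest

from phagevolve import (
    GenomeArchitecture,
    RegulatoryElement,
    SimulationConfig,
    make_starting_genome,
    simulate,
    simulate_replicates,
)
from phagevolve.genome import RNASE_SITE, TERMINATOR


class TestConfig:
    def test_grid(self):
        cfg = SimulationConfig(horizon=60.0, sample_interval=5.0)
        assert cfg.sample_times.size == 13
        assert cfg.sample_times[-1] == 60.0

    def test_validation(self):
        with pytest.raises(ValueError, match="divide"):
            SimulationConfig(horizon=100.0, sample_interval=7.0)
        with pytest.raises(ValueError, match="horizon"):
            SimulationConfig(horizon=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_polymerases=0)

    def test_translation_hook_disabled(self):
        with pytest.raises(NotImplementedError):
            SimulationConfig(translation=True)


class TestDegenerateGenomes:
    def test_no_promoter_no_expression(self, start3):
        bare = GenomeArchitecture(genes=start3.genes)
        tc = simulate(bare, seed=0)
        assert tc.values.sum() == 0.0

    def test_certain_termination_blocks_downstream(self, start3):
        g = start3.with_element(RegulatoryElement(TERMINATOR, 1, 1.0))
        tc = simulate(g, seed=1)
        assert tc.values[:, 1:].sum() == 0.0
        assert tc.values[-1, 0] > 0


class TestDeterminism:
    def test_identical_seeds_identical_trajectories(self, control_arch):
        a = simulate(control_arch, seed=42)
        b = simulate(control_arch, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_different_seeds_differ(self, control_arch):
        a = simulate(control_arch, seed=1)
        b = simulate(control_arch, seed=2)
        assert not np.array_equal(a.values, b.values)

    def test_replicate_mean_deterministic(self, control_arch, fast_sim):
        a = simulate_replicates(control_arch, fast_sim, n=4, seed=3)
        b = simulate_replicates(control_arch, fast_sim, n=4, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_single_replicate_matches_derived_seed(self, control_arch, fast_sim):
        mean = simulate_replicates(control_arch, fast_sim, n=1, seed=11)
        child = np.random.SeedSequence(11).spawn(1)[0]
        single = simulate(control_arch, fast_sim, seed=np.random.default_rng(child))
        np.testing.assert_array_equal(mean.values, single.values)

    def test_replicate_count_validation(self, control_arch, fast_sim):
        with pytest.raises(ValueError):
            simulate_replicates(control_arch, fast_sim, n=0)


class TestInvariants:
    def test_polymerase_conservation_and_exclusion(self, control_arch):
        cfg = SimulationConfig()
        log: list = []
        simulate(control_arch, cfg, seed=7, event_log=log)
        pol_records = [rec for rec in log if rec[1] == "pol"]
        assert pol_records, "expected polymerase movement in the trajectory"
        for _, _, positions, free in pol_records:
            assert free + len(positions) == cfg.n_polymerases
            for lead, trail in zip(positions, positions[1:]):
                assert lead - trail >= cfg.pol_footprint

    def test_monotone_without_degradation(self, start3):
        cfg = SimulationConfig(k_deg_nascent=0.0)
        for seed in range(5):
            tc = simulate(start3, cfg, seed=seed)
            assert np.all(np.diff(tc.values, axis=0) >= 0)


class TestKinetics:
    def test_birth_process_mean(self, start3):
        """With one weak promoter and no decay, gene-1 abundance at the
        horizon matches the constant-rate birth process with the elongation
        delay: rate * (horizon - delay)."""
        cfg = SimulationConfig(binding_scale=2.5e-10, k_deg_nascent=0.0)
        promoter = start3.elements[0]
        p = start3.element_position(promoter)
        rate = promoter.strength * cfg.n_polymerases * cfg.binding_scale
        delay = (start3.genes[0].end - p) / cfg.pol_speed
        expected = rate * (cfg.horizon - delay)

        n_rep = 4000
        rngs = np.random.SeedSequence(2024).spawn(n_rep)
        total = 0.0
        for child in rngs:
            tc = simulate(start3, cfg, seed=np.random.default_rng(child))
            total += tc.values[-1, 0]
        mean = total / n_rep
        se = np.sqrt(expected / n_rep)  # Poisson-like spread per replicate
        assert mean == pytest.approx(expected, abs=4 * se)

    def test_replicate_mean_variance_shrinks(self, start3):
        """Var of the n-replicate mean scales like 1/n."""
        cfg = SimulationConfig(horizon=100.0)
        ns = (5, 20, 80)
        n_master = 40
        log_vars = []
        for n in ns:
            finals = [
                simulate_replicates(start3, cfg, n=n, seed=1000 * n + i).values[-1, 0]
                for i in range(n_master)
            ]
            log_vars.append(np.log(np.var(finals, ddof=1)))
        slope = np.polyfit(np.log(ns), log_vars, 1)[0]
        assert -1.5 < slope < -0.6

    def test_terminator_dose_response(self, start3):
        """Gene-2 abundance is non-increasing in the strength of a
        terminator placed between genes 1 and 2."""
        means = []
        for strength in (0.0, 0.25, 0.5, 0.75, 1.0):
            g = start3
            if strength > 0:
                g = g.with_element(RegulatoryElement(TERMINATOR, 1, strength))
            tc = simulate_replicates(g, n=100, seed=17)
            means.append(tc.values[-1, 1])
        assert means[0] > means[-1]
        for a, b in zip(means, means[1:]):
            assert b <= a + 0.5  # Monte-Carlo slack on ~100-replicate means

    def test_plateau_requires_cleavage_site(self, start3):
        """A strong cleavage site downstream of the promoter drives gene 1
        to a steady state; without the site it grows throughout."""
        with_site = start3.with_element(RegulatoryElement(RNASE_SITE, 0, 0.5))
        late = slice(-21, None)  # final 100 s

        def late_slope(genome):
            tc = simulate_replicates(genome, n=50, seed=23)
            return np.polyfit(tc.times[late], tc.values[late, 0], 1)[0]

        s_without = late_slope(start3)
        s_with = late_slope(with_site)
        assert s_without > 0.02
        assert abs(s_with) < 0.25 * s_without
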