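import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phagevolve import (
    AnnealingSchedule,
    EvolutionConfig,
    FitnessSpec,
    GenomeArchitecture,
    RegulatoryElement,
    acceptance_probability,
    draw_modify_multiplier,
    enumerate_mutations,
    evolve,
    make_positive_control,
    make_starting_genome,
    propose,
)
from phagevolve.evolve import ADD, MODIFY, REMOVE, Mutation, apply_mutation
from phagevolve.genome import ELEMENT_KINDS, PROMOTER, TERMINATOR


class TestAnnealingSchedule:
    def test_canonical_5000_generation_values(self):
        sched = AnnealingSchedule(total_generations=5000)
        assert sched.beta(1) == pytest.approx(1e-3)
        assert sched.beta(500) == pytest.approx(1e-3)
        assert sched.beta(4500) == pytest.approx(1.1)
        assert sched.beta(5000) == pytest.approx(1.3)

    def test_proportional_scaling(self):
        sched = AnnealingSchedule(total_generations=1000)
        assert sched.phase_boundaries == (100, 900)
        assert sched.beta(100) == pytest.approx(1e-3)
        assert sched.beta(900) == pytest.approx(1.1)
        assert sched.beta(1000) == pytest.approx(1.3)

    @settings(derandomize=True, max_examples=50)
    @given(total=st.integers(10, 20000))
    def test_non_decreasing_piecewise_linear(self, total):
        sched = AnnealingSchedule(total_generations=total)
        betas = [sched.beta(g) for g in range(total + 1)]
        assert all(b2 >= b1 for b1, b2 in zip(betas, betas[1:]))
        assert betas[-1] == pytest.approx(1.3)


class TestEnumeration:
    def test_starting_genome(self, start3):
        # 4 regions x 3 kinds = 12 slots, one promoter present:
        # 11 adds + 1 remove + 1 modify
        mutations = enumerate_mutations(start3)
        assert len(mutations) == 13
        assert sum(m.action == ADD for m in mutations) == 11
        assert sum(m.action == REMOVE for m in mutations) == 1
        assert sum(m.action == MODIFY for m in mutations) == 1

    def test_saturated_genome(self, start3):
        g = start3
        for region in range(g.n_regions):
            for kind in ELEMENT_KINDS:
                if g.get(kind, region) is None:
                    g = g.with_element(
                        RegulatoryElement(kind, region, g.defaults.insertion[kind])
                    )
        mutations = enumerate_mutations(g)
        assert sum(m.action == ADD for m in mutations) == 0
        assert sum(m.action == REMOVE for m in mutations) == 12
        assert sum(m.action == MODIFY for m in mutations) == 12

    def test_bare_genome(self, start3):
        bare = dataclasses.replace(start3, elements=())
        mutations = enumerate_mutations(bare)
        assert all(m.action == ADD for m in mutations)
        assert len(mutations) == 12


class TestProposal:
    def test_modify_multiplier_applied(self, start3):
        g = start3.with_element(RegulatoryElement(TERMINATOR, 1, 0.2))
        m = Mutation(MODIFY, TERMINATOR, 1, multiplier=1.1)
        assert apply_mutation(g, m).get(TERMINATOR, 1).strength == pytest.approx(0.22)
        m1 = Mutation(MODIFY, TERMINATOR, 1, multiplier=1.0)
        assert apply_mutation(g, m1).get(TERMINATOR, 1).strength == pytest.approx(0.2)

    def test_add_uses_insertion_default(self, start3):
        mutated = apply_mutation(start3, Mutation(ADD, TERMINATOR, 2))
        assert mutated.get(TERMINATOR, 2).strength == pytest.approx(0.2)

    def test_out_of_bounds_multiplier_redrawn(self):
        class ScriptedRng:
            def __init__(self, values):
                self.values = list(values)
                self.calls = 0

            def normal(self, mean, sd):
                self.calls += 1
                return self.values.pop(0)

        rng = ScriptedRng([1.05, 0.98])  # 0.99 * 1.05 > 1 -> discard, redraw
        factor = draw_modify_multiplier(rng, 0.99, (0.0, 1.0))
        assert factor == pytest.approx(0.98)
        assert rng.calls == 2

    def test_uniform_over_enumeration(self, start3):
        """With selection off, proposals match the uniform-over-enumeration
        law (chi-square on 10^4 proposals against a frozen genome)."""
        rng = np.random.default_rng(99)
        labels = [
            (m.action, m.kind, m.region) for m in enumerate_mutations(start3)
        ]
        counts = dict.fromkeys(labels, 0)
        n = 10_000
        for _ in range(n):
            _, mut = propose(start3, rng)
            counts[(mut.action, mut.kind, mut.region)] += 1
        observed = np.array([counts[lab] for lab in labels])
        _, p = stats.chisquare(observed)
        assert p > 1e-3


class TestAcceptanceProbability:
    def test_neutral_and_beneficial_fix(self):
        assert acceptance_probability(0.3, 0.3, 1000) == 1.0
        assert acceptance_probability(0.3, 0.4, 1000) == 1.0

    def test_slightly_deleterious(self):
        # (0.4999/0.5)^2000 = exp(2000 ln 0.9998) ~ 0.6703
        p = acceptance_probability(0.5, 0.4999, 1000)
        assert p == pytest.approx(0.6703, abs=1e-4)

    def test_monotone_in_mutant_fitness(self):
        ps = [acceptance_probability(0.5, f, 50) for f in (0.2, 0.3, 0.4, 0.5)]
        assert all(b > a for a, b in zip(ps, ps[1:]) if b != 1.0 or a != 1.0)
        assert all(0 < p <= 1 for p in ps)

    def test_validation(self):
        with pytest.raises(ValueError):
            acceptance_probability(0.5, 0.4, 0)
        with pytest.raises(ValueError, match="positive fitness"):
            acceptance_probability(-0.1, -0.2, 10)


class TestEvolve:
    @pytest.fixture
    def small_target(self, control_arch, fast_sim):
        return make_positive_control(control_arch, fast_sim, n_replicates=2, seed=1)

    def test_zero_generations_is_noop(self, small_target, fast_sim):
        config = EvolutionConfig(generations=0, replicates=2, sim=fast_sim, seed=4)
        state = evolve(small_target, config)
        assert state.generation == 0
        assert state.trajectory == []
        assert state.best_rmse == state.resident_rmse >= 0
        assert state.resident == make_starting_genome(3)

    def test_seed_determinism(self, small_target, fast_sim):
        config = EvolutionConfig(generations=30, replicates=2, sim=fast_sim, seed=8)
        a = evolve(small_target, config)
        b = evolve(small_target, config)
        assert a.trajectory_frame().equals(b.trajectory_frame())
        assert a.resident == b.resident
        assert a.best_rmse == b.best_rmse

    def test_best_ever_tracks_minimum(self, small_target, fast_sim):
        config = EvolutionConfig(generations=40, replicates=2, sim=fast_sim, seed=9)
        state = evolve(small_target, config)
        frame = state.trajectory_frame()
        assert state.best_rmse <= frame["rmse_norm"].min()
        assert state.best_rmse <= state.resident_rmse
        assert frame.shape[0] == 40
        assert set(frame["action"]).issubset({ADD, REMOVE, MODIFY})

    def test_neutral_selection_accepts_everything(self, small_target, fast_sim):
        flat = AnnealingSchedule(
            total_generations=15, beta_initial=0.0, beta_mid=0.0, beta_final=0.0
        )
        config = EvolutionConfig(
            generations=15, replicates=1, sim=fast_sim, schedule=flat, seed=2
        )
        state = evolve(small_target, config)
        assert state.trajectory_frame()["accepted"].all()

    def test_gene_name_mismatch_rejected(self, small_target, fast_sim):
        config = EvolutionConfig(generations=1, replicates=1, sim=fast_sim, seed=0)
        with pytest.raises(ValueError, match="gene names"):
            evolve(small_target, config, start=make_starting_genome(4))

    def test_linear_fitness_runs(self, small_target, fast_sim):
        config = EvolutionConfig(
            generations=10, replicates=1, sim=fast_sim, seed=3,
            fitness=FitnessSpec("linear"),
        )
        state = evolve(small_target, config)
        assert state.generation == 10
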