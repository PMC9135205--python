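"""Origin–fixation evolution of genome architectures under annealing.

The population is represented by a single resident genotype.  Every
generation, exactly one mutation is proposed — drawn uniformly from the
complete enumeration of possibilities (add an element to any empty
(kind, region) slot, remove or modify any existing element) — the mutant is
evaluated by replicate-averaged simulation against the target, and it
replaces the resident with probability::

    P_accept = 1                 if f' >= f
             = (f'/f)^(2*Ne)     if f' <  f

so beneficial mutations fix unconditionally while deleterious ones fix with
a probability shrinking in the fitness deficit and the effective population
size ``Ne``.  Selection strength ``beta`` follows a simulated-annealing
schedule: flat and weak for the first 10% of generations, rising linearly
to 1.1 through the middle 80%, then to 1.3 over the final 10% (the
500 / 4000 / 500 split for a 5000-generation run, scaled proportionally
otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fitness import FitnessSpec, fitness_of, normalized_rmse
from .genome import ELEMENT_KINDS, GenomeArchitecture, RegulatoryElement, make_starting_genome
from .simulate import SimulationConfig, simulate_replicates
from .timecourse import TargetPattern

__all__ = [
    "Mutation",
    "AnnealingSchedule",
    "EvolutionConfig",
    "EvolutionState",
    "enumerate_mutations",
    "draw_modify_multiplier",
    "propose",
    "acceptance_probability",
    "evolve",
]

ADD, REMOVE, MODIFY = "add", "remove", "modify"


@dataclass(frozen=True)
class Mutation:
    """One proposed architectural change."""

    action: str  # add | remove | modify
    kind: str
    region: int
    multiplier: float | None = None  # modify only: factor applied to the strength


@dataclass(frozen=True)
class AnnealingSchedule:
    """Piecewise-linear selection-strength schedule beta(g).

    ``beta`` stays at ``beta_initial`` for the first tenth of the run, rises
    linearly to ``beta_mid`` through the middle eight tenths, and to
    ``beta_final`` over the last tenth.  For 5000 generations the phase
    boundaries are generations 500 and 4500.
    """

    total_generations: int = 5000
    beta_initial: float = 1e-3
    beta_mid: float = 1.1
    beta_final: float = 1.3

    def __post_init__(self) -> None:
        if self.total_generations < 1:
            raise ValueError("total_generations must be >= 1")
        if not (0 <= self.beta_initial <= self.beta_mid <= self.beta_final):
            raise ValueError("betas must satisfy 0 <= initial <= mid <= final")

    @property
    def phase_boundaries(self) -> tuple[int, int]:
        g = self.total_generations
        return int(round(0.1 * g)), int(round(0.9 * g))

    def beta(self, generation: int) -> float:
        g1, g2 = self.phase_boundaries
        g, gt = generation, self.total_generations
        if g <= g1:
            return self.beta_initial
        if g <= g2:
            frac = (g - g1) / (g2 - g1)
            return self.beta_initial + frac * (self.beta_mid - self.beta_initial)
        frac = (g - g2) / (gt - g2)
        return self.beta_mid + frac * (self.beta_final - self.beta_mid)

    __call__ = beta


def enumerate_mutations(genome: GenomeArchitecture) -> list[Mutation]:
    """Every possible mutation of the current genome, in deterministic order.

    One *add* per empty (kind, region) slot, one *remove* and one *modify*
    per existing element.  Modify multipliers are drawn only at proposal
    time.
    """
    mutations: list[Mutation] = []
    for region in range(genome.n_regions):
        for kind in ELEMENT_KINDS:
            if genome.get(kind, region) is None:
                mutations.append(Mutation(ADD, kind, region))
    for el in genome.elements:
        mutations.append(Mutation(REMOVE, el.kind, el.region))
    for el in genome.elements:
        mutations.append(Mutation(MODIFY, el.kind, el.region))
    return mutations


def draw_modify_multiplier(
    rng: np.random.Generator,
    strength: float,
    bounds: tuple[float, float],
    mean: float = 1.0,
    sd: float = 0.1,
) -> float:
    """Draw the multiplicative factor for a strength modification.

    Normal(mean, sd) draws are repeated until ``strength * factor`` falls
    inside ``bounds``; out-of-bounds draws are discarded.
    """
    lo, hi = bounds
    while True:
        factor = rng.normal(mean, sd)
        if lo <= strength * factor <= hi:
            return factor


def apply_mutation(
    genome: GenomeArchitecture, mutation: Mutation
) -> GenomeArchitecture:
    """Apply a fully specified mutation (multiplier already drawn)."""
    if mutation.action == ADD:
        strength = genome.defaults.insertion[mutation.kind]
        return genome.with_element(
            RegulatoryElement(mutation.kind, mutation.region, strength)
        )
    if mutation.action == REMOVE:
        return genome.without_element(mutation.kind, mutation.region)
    el = genome.get(mutation.kind, mutation.region)
    return genome.with_strength(
        mutation.kind, mutation.region, el.strength * mutation.multiplier
    )


def propose(
    genome: GenomeArchitecture, rng: np.random.Generator
) -> tuple[GenomeArchitecture, Mutation]:
    """Draw one mutation uniformly from the enumeration and apply it.

    Added elements start at their kind's insertion-default strength;
    modifications multiply the existing strength by an in-bounds draw from
    Normal(1, 0.1).
    """
    mutations = enumerate_mutations(genome)
    mutation = mutations[int(rng.integers(len(mutations)))]
    if mutation.action == MODIFY:
        el = genome.get(mutation.kind, mutation.region)
        factor = draw_modify_multiplier(
            rng, el.strength, genome.defaults.bounds[mutation.kind]
        )
        mutation = replace(mutation, multiplier=factor)
    return apply_mutation(genome, mutation), mutation


def acceptance_probability(f: float, f_prime: float, ne: int) -> float:
    """Origin–fixation acceptance probability (beneficial always fixes)."""
    if ne < 1:
        raise ValueError("Ne must be >= 1")
    if f_prime >= f:
        return 1.0
    if f <= 0:
        raise ValueError(
            "ratio form needs positive fitness; shift linear fitness first"
        )
    return float((f_prime / f) ** (2 * ne))


@dataclass(frozen=True)
class EvolutionConfig:
    """Everything one evolutionary run needs besides the target."""

    generations: int = 5000
    replicates: int = 10  # simulations averaged per fitness evaluation
    ne: int = 1000  # effective population size
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    schedule: AnnealingSchedule | None = None  # default: scaled to generations
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int | None = None
    #: When True, the resident is re-simulated every generation instead of
    #: reusing its cached evaluation.
    re_evaluate_resident: bool = False

    def __post_init__(self) -> None:
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.ne < 1:
            raise ValueError("ne must be >= 1")

    def resolved_schedule(self) -> AnnealingSchedule:
        if self.schedule is not None:
            return self.schedule
        return AnnealingSchedule(total_generations=max(self.generations, 1))


@dataclass
class EvolutionState:
    """Resident genotype, best-ever genotype, and the full trajectory log."""

    resident: GenomeArchitecture
    resident_rmse: float
    resident_fitness: float
    best: GenomeArchitecture
    best_rmse: float
    generation: int
    ne: int
    trajectory: list = field(default_factory=list)

    def trajectory_frame(self) -> pd.DataFrame:
        cols = [
            "generation", "beta", "action", "kind", "region",
            "rmse_norm", "fitness", "accepted",
        ]
        return pd.DataFrame(self.trajectory, columns=cols)


def _shifted(f: float, spec: FitnessSpec) -> float:
    # linear fitness is <= 0; shift it into positive territory so the
    # origin-fixation ratio stays defined (monotone, so ordering preserved)
    if spec.function == "linear":
        return f + spec.linear_offset
    return f


def evolve(
    target: TargetPattern,
    config: EvolutionConfig,
    start: GenomeArchitecture | None = None,
) -> EvolutionState:
    """Run the full origin–fixation loop against a target pattern.

    Per generation: set ``beta`` from the annealing schedule, propose one
    mutation, evaluate the mutant as the replicate-averaged normalized RMSE,
    map both genotypes' distances to fitness at the current ``beta``, accept
    with the origin–fixation probability (one uniform draw per generation,
    consumed even when acceptance is certain), and log.  Fully reproducible
    from the master seed.
    """
    if start is None:
        start = make_starting_genome(target.n_genes)
    if start.gene_names() != target.genes:
        raise ValueError("start genome gene names must match the target's")
    schedule = config.resolved_schedule()
    spec = config.fitness

    root = np.random.SeedSequence(config.seed)
    mut_ss, eval_ss = root.spawn(2)
    rng = np.random.default_rng(mut_ss)

    def evaluate(genome: GenomeArchitecture) -> float:
        child = eval_ss.spawn(1)[0]
        sim = simulate_replicates(genome, config.sim, n=config.replicates, seed=child)
        return normalized_rmse(sim, target)

    resident = start
    resident_rmse = evaluate(resident)
    best, best_rmse = resident, resident_rmse
    trajectory: list = []
    beta = schedule.beta(0) if config.generations == 0 else None

    for g in range(1, config.generations + 1):
        beta = schedule.beta(g)
        spec_g = replace(spec, beta=beta)
        mutant, mutation = propose(resident, rng)
        if config.re_evaluate_resident:
            resident_rmse = evaluate(resident)
        mutant_rmse = evaluate(mutant)
        f = _shifted(fitness_of(resident_rmse, spec_g), spec_g)
        f_prime = _shifted(fitness_of(mutant_rmse, spec_g), spec_g)
        p = acceptance_probability(f, f_prime, config.ne)
        accepted = bool(rng.random() < p)  # one draw every generation
        if accepted:
            resident, resident_rmse = mutant, mutant_rmse
        if mutant_rmse < best_rmse:
            best, best_rmse = mutant, mutant_rmse
        trajectory.append(
            (
                g, beta, mutation.action, mutation.kind, mutation.region,
                mutant_rmse, fitness_of(mutant_rmse, spec_g), accepted,
            )
        )

    final_beta = schedule.beta(config.generations)
    return EvolutionState(
        resident=resident,
        resident_rmse=resident_rmse,
        resident_fitness=fitness_of(resident_rmse, replace(spec, beta=final_beta)),
        best=best,
        best_rmse=best_rmse,
        generation=config.generations,
        ne=config.ne,
        trajectory=trajectory,
    )
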