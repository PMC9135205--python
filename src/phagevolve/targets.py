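"""Target gene-expression patterns for the design loop.

Three families cover the qualitative classes a phage can realise with
promoters, terminators and cleavage sites alone: linear ramps at differing
rates, ramp-then-plateau trajectories (steady states from the
production/degradation balance), and cross-overs where the relative
abundance ordering of genes changes over time.  A positive-control target
is produced by simulating a known architecture, guaranteeing at least one
exact solution exists.

Ten named presets (``PRESETS``) give a small library of such shapes for
three-gene genomes; they are approximate, parametric stand-ins for the kind
of patterns studied with this method, not measured data.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .genome import (
    PROMOTER,
    RNASE_SITE,
    TERMINATOR,
    ElementDefaults,
    GenomeArchitecture,
    RegulatoryElement,
    make_starting_genome,
)
from .simulate import SimulationConfig, simulate_replicates
from .timecourse import TargetPattern

__all__ = [
    "make_linear_pattern",
    "make_plateau_pattern",
    "make_positive_control",
    "make_preset",
    "positive_control_architecture",
    "PRESETS",
]


def positive_control_architecture(
    defaults: ElementDefaults | None = None,
) -> GenomeArchitecture:
    """An arbitrarily chosen three-gene architecture with a known output.

    Promoters in regions 0 and 1, terminators in regions 2 and 3, and an
    RNase cleavage site in region 1 (between the region-1 promoter and gene
    2), all at insertion-default strengths.  Simulating it yields a target
    for which at least one exact solution is guaranteed to exist.
    """
    defaults = defaults or ElementDefaults()
    base = make_starting_genome(3, defaults)
    ins = defaults.insertion
    for el in (
        RegulatoryElement(PROMOTER, 1, ins[PROMOTER]),
        RegulatoryElement(RNASE_SITE, 1, ins[RNASE_SITE]),
        RegulatoryElement(TERMINATOR, 2, ins[TERMINATOR]),
        RegulatoryElement(TERMINATOR, 3, ins[TERMINATOR]),
    ):
        base = base.with_element(el)
    return base


def _grid(grid: Sequence[float]) -> np.ndarray:
    times = np.asarray(grid, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("grid must be a 1-D array of at least two times")
    return times


def _names(n: int, genes: Sequence[str] | None) -> tuple[str, ...]:
    if genes is not None:
        if len(genes) != n:
            raise ValueError("gene name count does not match slope count")
        return tuple(genes)
    return tuple(f"gene{i + 1}" for i in range(n))


def make_linear_pattern(
    slopes: Sequence[float],
    grid: Sequence[float],
    genes: Sequence[str] | None = None,
) -> TargetPattern:
    """Per-gene linear ramps: Y_k(t) = slope_k * t.

    All slopes must be non-negative and at least one positive (a gene with
    zero mean target abundance would make the normalized RMSE undefined).
    """
    times = _grid(grid)
    slopes = np.asarray(slopes, dtype=float)
    if np.any(slopes < 0):
        raise ValueError("slopes must be >= 0")
    if np.all(slopes == 0):
        raise ValueError("at least one slope must be positive")
    values = np.outer(times, slopes)
    return TargetPattern(times, values, _names(slopes.size, genes))


def make_plateau_pattern(
    slopes: Sequence[float],
    breakpoints: Sequence[float | None],
    grid: Sequence[float],
    genes: Sequence[str] | None = None,
) -> TargetPattern:
    """Ramp-then-plateau per gene: Y_k rises at slope_k until its breakpoint,
    then stays constant.  A ``None`` (or beyond-horizon) breakpoint gives a
    pure ramp; differing (slope, breakpoint) pairs produce cross-overs."""
    times = _grid(grid)
    slopes = np.asarray(slopes, dtype=float)
    if len(breakpoints) != slopes.size:
        raise ValueError("need one breakpoint (or None) per gene")
    cols = []
    for slope, brk in zip(slopes, breakpoints):
        if brk is None:
            brk = np.inf
        if brk < 0:
            raise ValueError("breakpoints must be >= 0")
        cols.append(slope * np.minimum(times, brk))
    values = np.column_stack(cols)
    if np.any(values.mean(axis=0) <= 0):
        raise ValueError("every gene needs a positive mean target abundance")
    return TargetPattern(times, values, _names(slopes.size, genes))


def make_positive_control(
    genome: GenomeArchitecture,
    config: SimulationConfig | None = None,
    n_replicates: int = 10,
    seed: int | None = None,
) -> TargetPattern:
    """Replicate-mean simulator output of a known architecture, as a target."""
    config = config or SimulationConfig()
    tc = simulate_replicates(genome, config, n=n_replicates, seed=seed)
    if np.any(tc.values.mean(axis=0) <= 0):
        raise ValueError(
            "architecture produced no expression for at least one gene; "
            "a positive-control target needs positive mean abundance per gene"
        )
    return tc


#: Approximate three-gene preset shapes: (slopes in transcripts/s, breakpoints
#: in s), sized for the tens-of-transcripts regime of a 300 s simulation.
#: Ramps at differing rates, plateaus at differing levels, and cross-overs.
PRESETS: dict[str, tuple[tuple[float, ...], tuple[float | None, ...]]] = {
    "ramps-equal": ((0.10, 0.10, 0.10), (None, None, None)),
    "ramps-graded": ((0.15, 0.10, 0.05), (None, None, None)),
    "ramps-steep": ((0.20, 0.10, 0.05), (None, None, None)),
    "plateau-one": ((0.15, 0.10, 0.10), (100.0, None, None)),
    "plateau-two": ((0.15, 0.10, 0.05), (100.0, 150.0, None)),
    "plateau-all": ((0.15, 0.10, 0.05), (100.0, 150.0, 200.0)),
    "plateau-staggered": ((0.20, 0.10, 0.05), (75.0, 150.0, None)),
    "crossover-single": ((0.20, 0.05, 0.10), (100.0, None, None)),
    "crossover-double": ((0.25, 0.10, 0.05), (75.0, 200.0, None)),
    "crossover-late": ((0.30, 0.08, 0.04), (60.0, None, None)),
}


def make_preset(
    name: str,
    grid: Sequence[float] | None = None,
    scale: float = 1.0,
    genes: Sequence[str] | None = None,
) -> TargetPattern:
    """Build one of the named approximate preset patterns on a grid
    (default 0..300 s every 5 s); ``scale`` multiplies all abundances."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    if grid is None:
        grid = np.linspace(0.0, 300.0, 61)
    slopes, breaks = PRESETS[name]
    pattern = make_plateau_pattern(slopes, breaks, grid, genes)
    return TargetPattern(pattern.times, pattern.values * scale, pattern.genes)
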