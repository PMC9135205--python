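"""Distance between simulated and target expression, and fitness maps.

The distance is a normalized root-mean-square error: per-gene RMSE across
the time grid, each divided by ``M`` times that gene's mean target
abundance, summed over the ``M`` genes::

    RMSE_k    = sqrt( sum_t [y_k(t) - Y_k(t)]^2 / T )
    RMSE_norm = sum_k RMSE_k / (M * Ybar_k),   Ybar_k = sum_t Y_k(t) / T

Fitness maps RMSE_norm to a scalar via one of three monotone-decreasing
functions controlled by the selection-strength parameter ``beta``:

* ``fermi``:       f = 1 / (exp(beta * r) + 1)   (f = 1/2 at r = 0)
* ``exponential``: f = exp(-beta * r)
* ``linear``:      f = -beta * r

A design is deemed *successful* when RMSE_norm <= 0.1 (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timecourse import TimeCourse

__all__ = [
    "FitnessSpec",
    "SUCCESS_THRESHOLD",
    "rmse_per_gene",
    "normalized_rmse",
    "fitness_of",
    "is_successful",
]

SUCCESS_THRESHOLD = 0.1

_FUNCTIONS = ("fermi", "exponential", "linear")


@dataclass(frozen=True)
class FitnessSpec:
    """Which fitness function to use, and the selection strength beta."""

    function: str = "fermi"
    beta: float = 1.0
    #: Positive shift applied to linear fitness before forming the
    #: origin-fixation ratio (linear fitness is <= 0, so the ratio form
    #: needs a monotone positive transform).
    linear_offset: float = 2.0

    def __post_init__(self) -> None:
        if self.function not in _FUNCTIONS:
            raise ValueError(
                f"unknown fitness function {self.function!r}; choose from {_FUNCTIONS}"
            )
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


def _check_grids(observed: TimeCourse, target: TimeCourse) -> None:
    if not observed.same_grid(target):
        raise ValueError(
            "observed and target time-courses must share gene set and time grid"
        )


def rmse_per_gene(observed: TimeCourse, target: TimeCourse, gene: str) -> float:
    """Root-mean-square error of one gene's trajectory against its target."""
    _check_grids(observed, target)
    d = observed.column(gene) - target.column(gene)
    return float(np.sqrt(np.mean(d * d)))


def normalized_rmse(observed: TimeCourse, target: TimeCourse) -> float:
    """Per-gene RMSE normalized by M times the gene's mean target abundance,
    summed over genes.  Invariant under joint positive rescaling of both
    time-courses."""
    _check_grids(observed, target)
    m = target.n_genes
    ybar = target.values.mean(axis=0)
    if np.any(ybar <= 0):
        bad = [g for g, y in zip(target.genes, ybar) if y <= 0]
        raise ValueError(
            f"target mean abundance must be positive for every gene; zero for {bad}"
        )
    rmse = np.sqrt(np.mean((observed.values - target.values) ** 2, axis=0))
    return float(np.sum(rmse / (m * ybar)))


def fitness_of(rmse_norm: float, spec: FitnessSpec) -> float:
    """Map a normalized RMSE to fitness under the given spec."""
    if rmse_norm < 0:
        raise ValueError("rmse_norm must be >= 0")
    b = spec.beta
    if spec.function == "fermi":
        return 1.0 / (np.exp(b * rmse_norm) + 1.0)
    if spec.function == "exponential":
        return float(np.exp(-b * rmse_norm))
    return -b * rmse_norm


def is_successful(rmse_norm: float, threshold: float = SUCCESS_THRESHOLD) -> bool:
    """True iff the distance meets the success criterion (inclusive)."""
    return rmse_norm <= threshold
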