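"""Greedy removal of regulatory elements with negligible effect.

Strength mutations can drive an element's rate constant so low that it no
longer does anything; such passengers obscure comparisons between evolved
architectures.  Pruning removes, one at a time, the element whose removal
leaves the replicate-averaged normalized RMSE lowest while still at or
below the success threshold, and repeats until no element can be removed
without breaking success.  Epistasis between elements is deliberately
ignored (greedy, one element at a time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitness import SUCCESS_THRESHOLD, normalized_rmse
from .genome import GenomeArchitecture
from .simulate import SimulationConfig, simulate_replicates
from .timecourse import TargetPattern

__all__ = ["PruneRecord", "prune"]


@dataclass(frozen=True)
class PruneRecord:
    """One removal step: which element went, and the distance without it."""

    kind: str
    region: int
    rmse_norm: float


def prune(
    genome: GenomeArchitecture,
    target: TargetPattern,
    sim_config: SimulationConfig | None = None,
    replicates: int = 10,
    threshold: float = SUCCESS_THRESHOLD,
    seed: int | None = None,
    criterion: str = "post_removal_rmse",
) -> tuple[GenomeArchitecture, list[PruneRecord]]:
    """Greedily strip elements whose absence keeps the genome successful.

    The starting genome must itself evaluate at or below ``threshold``.
    Each candidate removal is scored by re-simulating the reduced genome
    (``replicates`` trajectories, fresh derived seeds); candidates keeping
    the normalized RMSE at or below ``threshold`` are eligible, and the one
    scoring best under ``criterion`` is removed:

    * ``"post_removal_rmse"`` (default): smallest distance after removal;
    * ``"delta_rmse"``: smallest absolute change from the current distance.

    Ties break by (region, kind) order.  Returns the pruned genome and the
    ordered removal log; re-running prune on the output removes nothing.
    """
    if criterion not in ("post_removal_rmse", "delta_rmse"):
        raise ValueError(f"unknown criterion {criterion!r}")
    sim_config = sim_config or SimulationConfig()
    root = np.random.SeedSequence(seed)

    def evaluate(g: GenomeArchitecture) -> float:
        child = root.spawn(1)[0]
        sim = simulate_replicates(g, sim_config, n=replicates, seed=child)
        return normalized_rmse(sim, target)

    current_rmse = evaluate(genome)
    if current_rmse > threshold:
        raise ValueError(
            f"genome is not successful (rmse_norm {current_rmse:.4f} > "
            f"{threshold}); pruning requires a successful starting point"
        )
    log: list[PruneRecord] = []
    while genome.elements:
        candidates = []
        for el in sorted(genome.elements, key=lambda e: (e.region, e.kind)):
            reduced = genome.without_element(el.kind, el.region)
            try:
                rmse = evaluate(reduced)
            except ValueError:
                continue  # e.g. removing the only promoter: no expression
            if rmse <= threshold:
                score = (
                    rmse
                    if criterion == "post_removal_rmse"
                    else abs(rmse - current_rmse)
                )
                candidates.append((score, el, rmse, reduced))
        if not candidates:
            break
        _, el, rmse, reduced = min(candidates, key=lambda c: c[0])
        genome, current_rmse = reduced, rmse
        log.append(PruneRecord(el.kind, el.region, rmse))
    return genome, log
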