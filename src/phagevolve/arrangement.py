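"""Gene-to-target arrangements.

Gene order matters in this model (transcription runs 5'→3' with stochastic
termination), so matching genome gene 1 to the most-expressed target gene is
a different problem from matching gene 3 to it.  When only the multiset of
expression trajectories matters, every assignment of genome genes to target
genes can be tried and the best kept.
"""

from __future__ import annotations

from itertools import permutations

from .timecourse import TimeCourse

__all__ = ["enumerate_arrangements", "apply_arrangement", "best_arrangement"]

#: Above this gene count, exhaustive permutation must be requested explicitly.
EXHAUSTIVE_LIMIT = 5


def enumerate_arrangements(n_genes: int, allow_large: bool = False) -> list[tuple[int, ...]]:
    """All assignments of genome gene slots to target genes, as permutations.

    Arrangement ``p`` means genome gene ``i`` is evaluated against target
    column ``p[i]``.  Deterministic (lexicographic) order; for more than
    ``EXHAUSTIVE_LIMIT`` genes the factorial blow-up must be opted into with
    ``allow_large=True``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_genes > EXHAUSTIVE_LIMIT and not allow_large:
        raise ValueError(
            f"{n_genes}! arrangements is impractical; pass allow_large=True to force, "
            "or use a fixed gene order"
        )
    return list(permutations(range(n_genes)))


def apply_arrangement(target: TimeCourse, arrangement: tuple[int, ...]) -> TimeCourse:
    """Relabel target columns so genome gene ``i`` is scored against target
    gene ``arrangement[i]``.  Pure column permutation; gene names keep the
    genome's order."""
    if sorted(arrangement) != list(range(target.n_genes)):
        raise ValueError(f"{arrangement} is not a permutation of the target genes")
    values = target.values[:, list(arrangement)]
    return TimeCourse(target.times, values, target.genes)


def best_arrangement(results: dict) -> tuple[tuple[int, ...], dict]:
    """Pick the arrangement minimizing mean final normalized RMSE.

    ``results`` maps arrangement tuples to sequences of final normalized-RMSE
    values from replicate evolution runs.  Ties break by enumeration
    (lexicographic) order.  Returns the winning arrangement and a summary
    table keyed by arrangement with mean rmse and replicate count.
    """
    if not results:
        raise ValueError("no arrangements evaluated")
    summary = {}
    for arr in sorted(results):
        vals = list(results[arr])
        if not vals:
            raise ValueError(f"arrangement {arr} has no replicate results")
        summary[arr] = {
            "mean_rmse_norm": sum(vals) / len(vals),
            "n_replicates": len(vals),
        }
    best = min(sorted(summary), key=lambda a: summary[a]["mean_rmse_norm"])
    return best, summary
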