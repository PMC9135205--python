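"""Per-gene transcript time-courses on a uniform sampling grid.

One container serves both roles in the design loop: simulator output (the
phenotype) and target patterns (the desired phenotype).  The on-disk format
is a CSV with a ``time`` column followed by one column per gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TimeCourse", "ExpressionTimeCourse", "TargetPattern"]


@dataclass(frozen=True)
class TimeCourse:
    """Times (seconds) by genes matrix of transcript abundances."""

    times: np.ndarray
    values: np.ndarray  # shape (T, M)
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape != (times.size, len(self.genes)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{times.size} times x {len(self.genes)} genes"
            )
        if times.size >= 2:
            steps = np.diff(times)
            if not np.allclose(steps, steps[0]):
                raise ValueError("time grid must be uniform")
        if np.any(values < 0):
            raise ValueError("abundances must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_times(self) -> int:
        return self.times.size

    def column(self, gene: str) -> np.ndarray:
        return self.values[:, self.genes.index(gene)]

    def same_grid(self, other: "TimeCourse") -> bool:
        return (
            self.genes == other.genes
            and self.times.shape == other.times.shape
            and bool(np.allclose(self.times, other.times))
        )

    def reorder(self, genes: tuple[str, ...]) -> "TimeCourse":
        """Return a copy with columns permuted into the given gene order."""
        idx = [self.genes.index(g) for g in genes]
        return TimeCourse(self.times, self.values[:, idx], tuple(genes))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.genes))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimeCourse":
        if "time" not in df.columns:
            raise ValueError("time-course CSV must have a 'time' column")
        genes = tuple(c for c in df.columns if c != "time")
        return cls(df["time"].to_numpy(float), df[list(genes)].to_numpy(float), genes)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeCourse":
        return cls.from_frame(pd.read_csv(path))


# Aliases naming the two roles a time-course plays.
ExpressionTimeCourse = TimeCourse
TargetPattern = TimeCourse
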