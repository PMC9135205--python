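"""Diversity of evolved genome architectures, measured as Shannon entropy.

Independently evolved solutions to the same target often differ in which
regulatory elements they carry.  We summarise a set of successful (and
pruned) genomes by the entropy of their architecture *fingerprints* —
presence/absence patterns of (kind, region) pairs, ignoring strengths::

    H = - sum_i (n_i / n) * log2(n_i / n)

in bits, where ``n_i`` counts solutions with the i-th unique fingerprint.
``H = 1`` means effectively 2 distinct architectures, ``H = 5`` effectively 32.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from scipy.stats import entropy as _entropy

from .genome import ArchitectureFingerprint, GenomeArchitecture, fingerprint

__all__ = ["ArchitectureCensus", "architecture_entropy"]


@dataclass(frozen=True)
class ArchitectureCensus:
    """Counts of unique architecture fingerprints among successful solutions."""

    counts: dict

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("census must contain at least one architecture")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("census counts must be >= 1")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    @classmethod
    def from_fingerprints(cls, fps: Iterable[ArchitectureFingerprint]) -> "ArchitectureCensus":
        return cls(dict(Counter(fps)))

    @classmethod
    def from_genomes(cls, genomes: Iterable[GenomeArchitecture]) -> "ArchitectureCensus":
        return cls.from_fingerprints(fingerprint(g) for g in genomes)


def architecture_entropy(census: ArchitectureCensus) -> float:
    """Shannon entropy of the census, in bits."""
    return float(_entropy(list(census.counts.values()), base=2))
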