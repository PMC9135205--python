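"""Genome architectures: genes plus regulatory elements with evolvable strengths.

A genome here is not a nucleotide sequence but an ordered list of
protein-coding genes interleaved with *regulatory regions*.  A genome with
``M`` genes has ``M + 1`` regions: region 0 lies upstream of gene 1, region
``i`` (``1 <= i < M``) lies between gene ``i`` and gene ``i + 1``, and region
``M`` lies downstream of the last gene.  Each region can hold at most one
element of each kind — promoter, terminator, or RNase cleavage site — and
each element carries a strength (a rate constant for promoters and cleavage
sites, a termination probability for terminators).

Within a region the fixed 5'→3' element order is terminator → promoter →
RNase site, so a terminator ends transcripts arriving from upstream before
they reach the co-located promoter, and the cleavage site sits inside
transcripts initiated at that promoter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "PROMOTER",
    "TERMINATOR",
    "RNASE_SITE",
    "ELEMENT_KINDS",
    "GeneFeature",
    "RegulatoryElement",
    "ElementDefaults",
    "GenomeArchitecture",
    "ArchitectureFingerprint",
    "SchemaError",
    "make_starting_genome",
    "read_architecture",
    "write_architecture",
    "fingerprint",
]

PROMOTER = "promoter"
TERMINATOR = "terminator"
RNASE_SITE = "rnase_site"

#: Canonical kind order; also the within-region 5'->3' placement order is
#: terminator -> promoter -> rnase_site (see module docstring).
ELEMENT_KINDS = (PROMOTER, TERMINATOR, RNASE_SITE)

#: Fraction of the spacer at which each kind sits, in 5'->3' order
#: terminator, promoter, rnase_site.
_REGION_OFFSETS = {TERMINATOR: 0.2, PROMOTER: 0.5, RNASE_SITE: 0.8}


class SchemaError(ValueError):
    """Raised when an architecture file or genome violates the schema."""


@dataclass(frozen=True)
class GeneFeature:
    """A protein-coding gene, located by its 1-based inclusive start."""

    name: str
    start: int
    length: int = 150

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise SchemaError(f"gene {self.name!r}: length must be > 0")
        if self.start < 1:
            raise SchemaError(f"gene {self.name!r}: start must be >= 1")

    @property
    def end(self) -> int:
        """1-based inclusive end coordinate."""
        return self.start + self.length - 1


@dataclass(frozen=True)
class RegulatoryElement:
    """A point regulatory element in a regulatory region.

    ``strength`` is a promoter binding-rate constant, a terminator
    termination probability, or an RNase cleavage-rate constant.
    """

    kind: str
    region: int
    strength: float

    def __post_init__(self) -> None:
        if self.kind not in ELEMENT_KINDS:
            raise SchemaError(f"unknown element kind {self.kind!r}")
        if self.region < 0:
            raise SchemaError(f"{self.kind}: region must be >= 0")


@dataclass(frozen=True)
class ElementDefaults:
    """Insertion strengths and (min, max) bounds per element kind."""

    insertion: dict = field(
        default_factory=lambda: {PROMOTER: 1e6, TERMINATOR: 0.2, RNASE_SITE: 5e-3}
    )
    bounds: dict = field(
        default_factory=lambda: {
            PROMOTER: (1e5, 1e13),
            TERMINATOR: (0.0, 1.0),
            RNASE_SITE: (0.0, 1.0),
        }
    )

    def check_strength(self, kind: str, strength: float) -> None:
        lo, hi = self.bounds[kind]
        if not (lo <= strength <= hi):
            raise SchemaError(
                f"{kind} strength {strength!r} outside bounds [{lo!r}, {hi!r}]"
            )

    def in_bounds(self, kind: str, strength: float) -> bool:
        lo, hi = self.bounds[kind]
        return lo <= strength <= hi


@dataclass(frozen=True)
class GenomeArchitecture:
    """The evolvable genotype: ordered genes plus regulatory elements.

    Genes are laid out left to right, separated by regulatory regions of
    ``spacer_length`` nucleotides; coordinates are 1-based inclusive and
    derived deterministically from gene lengths and the spacer.  Elements are
    point features that consume no spacer length.
    """

    genes: tuple[GeneFeature, ...]
    elements: tuple[RegulatoryElement, ...] = ()
    spacer_length: int = 50
    defaults: ElementDefaults = field(default_factory=ElementDefaults)

    def __post_init__(self) -> None:
        if not self.genes:
            raise SchemaError("genome must contain at least one gene")
        prev_end = 0
        for g in self.genes:
            if g.start <= prev_end:
                raise SchemaError(
                    f"gene {g.name!r} at {g.start} overlaps or precedes the previous gene"
                )
            prev_end = g.end
        m = len(self.genes)
        seen: set[tuple[str, int]] = set()
        for el in self.elements:
            if el.region > m:
                raise SchemaError(
                    f"{el.kind} in region {el.region}: genome has regions 0..{m}"
                )
            key = (el.kind, el.region)
            if key in seen:
                raise SchemaError(
                    f"duplicate {el.kind} in region {el.region}: only one of each "
                    "element kind is allowed per region"
                )
            seen.add(key)
            self.defaults.check_strength(el.kind, el.strength)
        # canonical element order: by (region, within-region 5'->3' kind order)
        order = {TERMINATOR: 0, PROMOTER: 1, RNASE_SITE: 2}
        object.__setattr__(
            self,
            "elements",
            tuple(sorted(self.elements, key=lambda e: (e.region, order[e.kind]))),
        )

    # -- geometry -----------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_regions(self) -> int:
        return len(self.genes) + 1

    @property
    def length(self) -> int:
        """Total genome length: last region's end."""
        return self.genes[-1].end + self.spacer_length

    def region_start(self, region: int) -> int:
        """1-based start coordinate of a regulatory region."""
        if region == 0:
            return 1
        return self.genes[region - 1].end + 1

    def element_position(self, el: RegulatoryElement) -> int:
        """Genome coordinate of a point element inside its region."""
        off = int(round(_REGION_OFFSETS[el.kind] * self.spacer_length))
        return self.region_start(el.region) + max(0, min(off, self.spacer_length - 1))

    # -- element access -----------------------------------------------------

    def get(self, kind: str, region: int) -> RegulatoryElement | None:
        for el in self.elements:
            if el.kind == kind and el.region == region:
                return el
        return None

    def of_kind(self, kind: str) -> tuple[RegulatoryElement, ...]:
        return tuple(el for el in self.elements if el.kind == kind)

    def with_element(self, element: RegulatoryElement) -> "GenomeArchitecture":
        """Return a copy with ``element`` added (its slot must be empty)."""
        return replace(self, elements=self.elements + (element,))

    def without_element(self, kind: str, region: int) -> "GenomeArchitecture":
        el = self.get(kind, region)
        if el is None:
            raise KeyError(f"no {kind} in region {region}")
        return replace(
            self, elements=tuple(e for e in self.elements if e is not el)
        )

    def with_strength(self, kind: str, region: int, strength: float) -> "GenomeArchitecture":
        el = self.get(kind, region)
        if el is None:
            raise KeyError(f"no {kind} in region {region}")
        new = RegulatoryElement(kind, region, strength)
        return replace(
            self,
            elements=tuple(new if e is el else e for e in self.elements),
        )

    def gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)


#: Presence/absence signature of a genome's elements; strengths are ignored.
#: Two genomes that differ only in element strengths share a fingerprint.
ArchitectureFingerprint = tuple


def fingerprint(genome: GenomeArchitecture) -> ArchitectureFingerprint:
    """Canonical hashable (kind, region) signature of a genome's elements."""
    return tuple(sorted((el.kind, el.region) for el in genome.elements))


def _layout_genes(names: Iterable[str], lengths: Iterable[int], spacer: int) -> tuple[GeneFeature, ...]:
    genes = []
    pos = spacer + 1
    for name, length in zip(names, lengths):
        genes.append(GeneFeature(name=name, start=pos, length=length))
        pos += length + spacer
    return tuple(genes)


def make_starting_genome(
    n_genes: int,
    defaults: ElementDefaults | None = None,
    gene_length: int = 150,
    spacer_length: int = 50,
    promoter_strength: float | None = None,
) -> GenomeArchitecture:
    """Build the canonical evolution starting point.

    ``n_genes`` coding sequences (150 nt each by default) with a single
    moderate-strength promoter upstream of the first gene, at the promoter
    insertion-default strength unless ``promoter_strength`` is given.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    defaults = defaults or ElementDefaults()
    strength = (
        promoter_strength
        if promoter_strength is not None
        else defaults.insertion[PROMOTER]
    )
    names = [f"gene{i + 1}" for i in range(n_genes)]
    genes = _layout_genes(names, [gene_length] * n_genes, spacer_length)
    return GenomeArchitecture(
        genes=genes,
        elements=(RegulatoryElement(PROMOTER, 0, strength),),
        spacer_length=spacer_length,
        defaults=defaults,
    )


# -- serialization ----------------------------------------------------------


def _to_dict(genome: GenomeArchitecture) -> dict:
    return {
        "genes": [{"name": g.name, "length": g.length} for g in genome.genes],
        "elements": [
            {"kind": el.kind, "region": el.region, "strength": float(el.strength)}
            for el in genome.elements
        ],
        "spacer_length": genome.spacer_length,
    }


def _from_dict(data: dict, defaults: ElementDefaults | None = None) -> GenomeArchitecture:
    if not isinstance(data, dict) or "genes" not in data:
        raise SchemaError("architecture file must define a 'genes' list")
    spacer = int(data.get("spacer_length", 50))
    names = [g["name"] for g in data["genes"]]
    lengths = [int(g.get("length", 150)) for g in data["genes"]]
    genes = _layout_genes(names, lengths, spacer)
    elements = tuple(
        RegulatoryElement(e["kind"], int(e["region"]), float(e["strength"]))
        for e in data.get("elements", [])
    )
    return GenomeArchitecture(
        genes=genes,
        elements=elements,
        spacer_length=spacer,
        defaults=defaults or ElementDefaults(),
    )


def write_architecture(genome: GenomeArchitecture, path: str | Path) -> None:
    """Write a genome to YAML (or JSON if the suffix is ``.json``).

    Serialization is bit-stable: writing the same genome twice yields
    identical files.
    """
    path = Path(path)
    data = _to_dict(genome)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def read_architecture(path: str | Path, defaults: ElementDefaults | None = None) -> GenomeArchitecture:
    """Read a genome architecture from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        return _from_dict(data, defaults)
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: malformed architecture file ({exc})") from exc
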