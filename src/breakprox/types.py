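"""Core domain types.

All genomic intervals are stored 0-based, half-open ``[begin, end)`` — the
convention of BED files and UCSC database tables.  Dialect adapters in
:mod:`breakprox.io` convert at the boundary where an input uses something
else.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional

STRAND_VALUES = {"+", "-", "."}

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def chrom_sort_key(chrom: str):
    """Natural chromosome ordering: chr1 < chr2 < ... < chr22 < chrX < chrY
    < chrM; unrecognized names sort after, alphabetically."""
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if body.isdigit():
        return (0, int(body), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if body.upper() in special:
        return (0, special[body.upper()], "")
    return (1, 0, body)


def normalize_name(name: str) -> str:
    """Normalize a gene/element name: trim, uppercase, strip ``.N`` version
    suffixes.  Name mismatch between expression studies and genome
    annotations is the dominant data-loss mode in cross-species expression
    work, so both sides of every match go through this single function."""
    return _VERSION_SUFFIX.sub("", name.strip().upper())


@dataclass(frozen=True, order=True)
class BreakpointRegion:
    """A lineage-labelled rearrangement breakpoint region (BPR).

    ``branch`` names the evolutionary branch (of the species phylogeny
    underlying the BPR table) on which the rearrangement happened.
    """

    chrom: str
    begin: int
    end: int
    branch: str

    def __post_init__(self) -> None:
        if self.begin < 0:
            raise ValueError(f"negative begin coordinate: {self.begin}")
        if self.begin > self.end:
            raise ValueError(
                f"begin > end for {self.chrom}:{self.begin}-{self.end}"
            )
        if not self.branch:
            raise ValueError("empty branch label")

    @property
    def width(self) -> int:
        return self.end - self.begin


@dataclass(frozen=True)
class GeneRecord:
    """A named gene interval.  ``strand`` is '+', '-' or '.' (unknown);
    distances ignore strand throughout."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"start > end for gene {self.name!r}: {self.start}-{self.end}"
            )
        if not self.name:
            raise ValueError("empty gene name")
        if self.strand not in STRAND_VALUES:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class ExpressionElement:
    """A genetic element from a differential-expression study: a gene
    symbol, an EST or a transcript id, possibly obsolete, with an optional
    direction and fold change.  ``matched_gene`` is filled in by
    :func:`breakprox.io.match_expression_to_genes`."""

    raw_name: str
    matched_gene: Optional[str] = None
    direction: str = "unknown"  # up / down / unknown
    fold_change: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.raw_name:
            raise ValueError("empty raw_name")


@dataclass(frozen=True)
class DistanceRecord:
    """Nearest-BPR result for one gene: ``x`` is the gap in nucleotides
    (0 when the gene overlaps the region), ``z = ln(max(x, 1))``."""

    gene: GeneRecord
    nearest: BreakpointRegion
    x: int
    z: float
    is_de: bool

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError("negative distance")
        if self.nearest.chrom != self.gene.chrom:
            raise ValueError("nearest BPR on a different chromosome")


def log_distance(x: float) -> float:
    """z = ln(max(x, 1)); the 1-nt floor keeps z >= 0 and matches the
    x ~ Uniform[1, u] convention of the null model."""
    return math.log(max(x, 1.0))


@dataclass(frozen=True)
class FlankingInterval:
    """The two breakpoint boundaries around a gene midpoint.

    ``a1``/``a2`` are the inner boundaries of the nearest regions to the
    left/right (chromosome start/end when there is none); ``u`` is the
    half-spacing ``|a1 - a2| / 2`` and ``U = ln(max(u, 1))`` is the
    truncation point of the log-distance null.  ``degenerate`` flags a
    midpoint that falls inside a region (u = 0).
    """

    a1: float
    a2: float
    u: float = field(init=False)
    U: float = field(init=False)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.a1 > self.a2:
            raise ValueError("a1 > a2")
        object.__setattr__(self, "u", abs(self.a2 - self.a1) / 2.0)
        object.__setattr__(self, "U", log_distance(self.u))
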