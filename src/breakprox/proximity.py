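"""Nearest-breakpoint distances and flanking-interval geometry.

The distance from a gene to a breakpoint region is the interval-to-interval
gap in nucleotides: 0 when the two overlap (the gene is disrupted),
otherwise the number of nucleotides between the closer pair of facing
boundaries.  A ``point_mode`` variant measures from the gene midpoint
instead, matching the point-gene idealization of the null model.

Regions within a chromosome are assumed non-overlapping (true of published
breakpoint sets and of the synthetic generator), which lets nearest-gap
queries run by bisection over the sorted boundary arrays; the exhaustive
scan remains available as a test oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .types import (
    BreakpointRegion,
    DistanceRecord,
    FlankingInterval,
    GeneRecord,
    log_distance,
)

logger = logging.getLogger(__name__)


class NoBreakpointOnChromosome(ValueError):
    """Raised when a nearest-distance query has no region to measure to."""


def group_by_chromosome(
    bprs: Sequence[BreakpointRegion],
) -> Dict[str, List[BreakpointRegion]]:
    """Group regions by chromosome, each group sorted by begin."""
    grouped: Dict[str, List[BreakpointRegion]] = {}
    for r in bprs:
        grouped.setdefault(r.chrom, []).append(r)
    for chrom in grouped:
        grouped[chrom].sort(key=lambda r: (r.begin, r.end))
    return grouped


def interval_gap(s1: float, e1: float, s2: float, e2: float) -> float:
    """Gap between half-open intervals [s1, e1) and [s2, e2); 0 on overlap."""
    if e1 <= s2:
        return s2 - e1
    if e2 <= s1:
        return s1 - e2
    return 0.0


def nearest_bpr_distance(
    gene: GeneRecord,
    bprs: Sequence[BreakpointRegion],
    point_mode: bool = False,
) -> Tuple[int, BreakpointRegion]:
    """Distance in nucleotides from a gene to its closest breakpoint region.

    ``bprs`` must be non-empty, on ``gene.chrom`` and sorted by begin.
    Ties break toward the lower-coordinate region.  With ``point_mode`` the
    gene is collapsed to its midpoint.
    """
    if not bprs:
        raise NoBreakpointOnChromosome(f"no breakpoint on {gene.chrom}")
    if point_mode:
        mid = gene.midpoint
        s1 = e1 = mid
    else:
        s1, e1 = gene.start, gene.end
    best_x: Optional[float] = None
    best: Optional[BreakpointRegion] = None
    for r in bprs:
        if r.chrom != gene.chrom:
            raise ValueError(f"region on {r.chrom}, gene on {gene.chrom}")
        g = interval_gap(s1, e1, r.begin, r.end)
        if best_x is None or g < best_x:
            best_x, best = g, r
    return int(best_x), best


@dataclass
class DistanceSummary:
    """Bookkeeping from :func:`compute_all_distances`."""

    n_genes_in: int = 0
    n_analysed: int = 0
    n_de: int = 0
    excluded_by_chrom: Dict[str, int] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return sum(self.excluded_by_chrom.values())


def compute_all_distances(
    genes: Sequence[GeneRecord],
    de_names: Set[str],
    bprs: Sequence[BreakpointRegion],
    point_mode: bool = False,
) -> Tuple[List[DistanceRecord], DistanceSummary]:
    """Nearest-breakpoint distance for every gene on a breakpoint-bearing
    chromosome.

    Genes on chromosomes without any retained breakpoint cannot be assigned
    a distance and are excluded (and counted per chromosome in the summary)
    rather than given an arbitrary value.  ``is_de`` is set by membership of
    the (normalized) gene name in ``de_names``.
    """
    grouped = group_by_chromosome(bprs)
    arrays = {
        chrom: (
            np.array([r.begin for r in lst], dtype=np.int64),
            np.array([r.end for r in lst], dtype=np.int64),
        )
        for chrom, lst in grouped.items()
    }
    records: List[DistanceRecord] = []
    summary = DistanceSummary(n_genes_in=len(genes))
    for gene in genes:
        lst = grouped.get(gene.chrom)
        if not lst:
            summary.excluded_by_chrom[gene.chrom] = (
                summary.excluded_by_chrom.get(gene.chrom, 0) + 1
            )
            continue
        begins, ends = arrays[gene.chrom]
        x, idx = _nearest_gap_sorted(gene, begins, ends, point_mode)
        is_de = gene.name in de_names
        records.append(
            DistanceRecord(gene=gene, nearest=lst[idx], x=int(x),
                           z=log_distance(x), is_de=is_de)
        )
    summary.n_analysed = len(records)
    summary.n_de = sum(r.is_de for r in records)
    if summary.excluded_by_chrom:
        logger.info("excluded %d genes on breakpoint-free chromosomes: %s",
                    summary.n_excluded, dict(sorted(summary.excluded_by_chrom.items())))
    return records, summary


def _nearest_gap_sorted(
    gene: GeneRecord,
    begins: np.ndarray,
    ends: np.ndarray,
    point_mode: bool,
) -> Tuple[int, int]:
    """(gap, index of nearest region) against sorted non-overlapping
    regions; ties toward the lower-coordinate region."""
    if point_mode:
        mid = gene.midpoint
        gs, ge = mid, mid
    else:
        gs, ge = gene.start, gene.end
    n = len(begins)
    # first region with begin >= gene end  /  count of regions fully left
    i = int(np.searchsorted(begins, ge, side="left"))
    j = int(np.searchsorted(ends, gs, side="right"))
    if i > j:  # some region overlaps the gene
        return 0, j
    candidates: List[Tuple[float, int]] = []
    if j >= 1:
        candidates.append((gs - ends[j - 1], j - 1))
    if i < n:
        candidates.append((begins[i] - ge, i))
    if not candidates:
        raise NoBreakpointOnChromosome(f"no breakpoint on {gene.chrom}")
    # min() keeps the first (lower-coordinate) entry on a tie
    gap, idx = min(candidates, key=lambda t: t[0])
    return int(gap), idx


def nearest_gaps_vectorized(
    gene_starts: np.ndarray,
    gene_ends: np.ndarray,
    begins: np.ndarray,
    ends: np.ndarray,
) -> np.ndarray:
    """Vectorized nearest-gap for many gene intervals against one sorted,
    non-overlapping region set.  Used by the Monte-Carlo resampler, where
    the same chromosome is queried tens of thousands of times."""
    n = len(begins)
    i = np.searchsorted(begins, gene_ends, side="left")
    j = np.searchsorted(ends, gene_starts, side="right")
    left = np.where(j >= 1, gene_starts - ends[np.clip(j - 1, 0, n - 1)], np.inf)
    right = np.where(i < n, begins[np.clip(i, 0, n - 1)] - gene_ends, np.inf)
    gaps = np.minimum(left, right)
    gaps[i > j] = 0.0  # overlap
    return gaps


def flanking_interval(
    gene: GeneRecord,
    bprs: Sequence[BreakpointRegion],
    chrom_length: int,
) -> FlankingInterval:
    """The breakpoint boundaries bracketing the gene midpoint.

    ``a1`` is the end of the rightmost region at or left of the midpoint
    (chromosome start, 0, if none); ``a2`` the begin of the leftmost region
    at or right of it (``chrom_length`` if none).  A midpoint inside a
    region yields a degenerate interval with u = 0, flagged.
    """
    if not bprs:
        raise NoBreakpointOnChromosome(f"no breakpoint on {gene.chrom}")
    mid = gene.midpoint
    if chrom_length < max(r.end for r in bprs):
        raise ValueError("chrom_length smaller than the largest region end")
    a1, a2 = 0.0, float(chrom_length)
    for r in bprs:
        if r.begin < mid < r.end:
            return FlankingInterval(a1=mid, a2=mid, degenerate=True)
        if r.end <= mid:
            a1 = max(a1, float(r.end))
        if r.begin >= mid:
            a2 = min(a2, float(r.begin))
    return FlankingInterval(a1=a1, a2=a2)


def flanking_intervals_vectorized(
    mids: np.ndarray,
    begins: np.ndarray,
    ends: np.ndarray,
    chrom_length: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(a1, a2, degenerate) arrays for many midpoints on one chromosome."""
    n = len(begins)
    k = np.searchsorted(ends, mids, side="right")  # regions with end <= mid
    a1 = np.where(k >= 1, ends[np.clip(k - 1, 0, n - 1)].astype(float), 0.0)
    m = np.searchsorted(begins, mids, side="left")  # first begin >= mid
    a2 = np.where(m < n, begins[np.clip(m, 0, n - 1)].astype(float), float(chrom_length))
    inside = (m >= 1) & (mids < ends[np.clip(m - 1, 0, n - 1)]) & (
        mids > begins[np.clip(m - 1, 0, n - 1)]
    )
    a1 = np.where(inside, mids, a1)
    a2 = np.where(inside, mids, a2)
    return a1, a2, inside
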