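"""Synthetic genomes for end-to-end testing of the proximity analysis.

The generator emulates the statistical structure the analysis assumes: a
few chromosomes of fixed length, non-overlapping breakpoint regions with
log-uniform widths (published mammalian breakpoint sets span roughly 1 nt
to ~2.9 Mb), lineage labels drawn from a configurable pool, genes scattered
uniformly with lognormal widths, and a differentially-expressed subset.  A
*planted proximity effect* optionally places a fraction of the DE genes
within a set radius of a breakpoint boundary, giving a known-positive
dataset for power checks; with ``effect_fraction = 0`` the DE flag is
independent of position and the dataset is an exact null.

Everything is reproducible from the single integer ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import yaml

from . import io as bpio
from .types import BreakpointRegion, GeneRecord

DEFAULT_CHROM_LENGTHS = {"chr1": 100_000_000, "chr2": 100_000_000, "chr3": 100_000_000}
DEFAULT_BRANCHES = ("human", "human-chimp", "macaque", "primates", "dog", "rat")


@dataclass
class SyntheticConfig:
    """Full parameterization of the generator.

    Defaults describe the reference study conditions used throughout the
    test-suite: three 100-Mb chromosomes, 5000 genes, 40 breakpoint
    regions and 250 DE genes, no planted effect.
    """

    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    n_genes: int = 5000
    gene_width_mean: float = 25_000.0   # lognormal, nt
    gene_width_sigma: float = 1.0       # lognormal sigma (geometric spread)
    n_bprs: int = 40
    bpr_width_min: float = 1.0
    bpr_width_max: float = 2_887_673.0  # log-uniform upper bound, nt
    branch_labels_pool: Tuple[str, ...] = DEFAULT_BRANCHES
    branch_probs: Tuple[float, ...] = ()
    n_de: int = 250
    effect_fraction: float = 0.0
    effect_radius: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must be in [0, 1]")
        if self.effect_radius < 0:
            raise ValueError("effect_radius must be >= 0")
        if not self.branch_probs:
            k = len(self.branch_labels_pool)
            self.branch_probs = tuple(1.0 / k for _ in range(k))
        if len(self.branch_probs) != len(self.branch_labels_pool):
            raise ValueError("branch_probs must match branch_labels_pool")
        if not math.isclose(sum(self.branch_probs), 1.0, abs_tol=1e-9):
            raise ValueError("branch_probs must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("branch_labels_pool", "branch_probs"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["branch_labels_pool"] = list(self.branch_labels_pool)
        data["branch_probs"] = list(self.branch_probs)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


class PlacementError(RuntimeError):
    """A chromosome is too crowded to place non-overlapping regions."""


def _place_nonoverlapping(
    rng: np.random.Generator,
    length: int,
    widths: Sequence[int],
    max_tries: int = 1000,
) -> List[Tuple[int, int]]:
    """Rejection-sample non-overlapping intervals of given widths on
    [0, length)."""
    placed: List[Tuple[int, int]] = []
    for w in widths:
        if w >= length:
            raise PlacementError(f"region width {w} exceeds chromosome length {length}")
        for _ in range(max_tries):
            start = int(rng.integers(0, length - w))
            end = start + w
            if all(end <= s or start >= e for s, e in placed):
                placed.append((start, end))
                break
        else:
            raise PlacementError(
                f"could not place a {w}-nt region after {max_tries} tries")
    placed.sort()
    return placed


def simulate_dataset(
    config: SyntheticConfig,
) -> Tuple[List[GeneRecord], List[BreakpointRegion], Set[str]]:
    """Generate ``(genes, bprs, de_names)`` for one synthetic genome.

    Chromosome assignment for regions and genes is multinomial in
    chromosome length; region widths are log-uniform on
    [bpr_width_min, bpr_width_max]; gene widths lognormal with the
    configured mean and geometric spread.  ``ceil(effect_fraction * n_de)``
    DE genes are re-placed so their nearer edge lies uniformly within
    ``effect_radius`` of a uniformly chosen breakpoint boundary; the rest
    of the DE set is an unbiased random sample of ordinary genes.
    """
    rng = np.random.default_rng(config.seed)
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    # --- breakpoint regions ---
    n_per_chrom = rng.multinomial(config.n_bprs, probs)
    bprs: List[BreakpointRegion] = []
    for c, n_c in zip(chroms, n_per_chrom):
        if n_c == 0:
            continue
        log_lo, log_hi = math.log(config.bpr_width_min), math.log(config.bpr_width_max)
        widths = np.exp(rng.uniform(log_lo, log_hi, size=n_c)).astype(np.int64)
        widths = np.maximum(widths, 1)
        spans = _place_nonoverlapping(rng, config.chrom_lengths[c], widths.tolist())
        labels = rng.choice(config.branch_labels_pool, size=n_c,
                            p=np.asarray(config.branch_probs))
        for (s, e), lab in zip(spans, labels):
            bprs.append(BreakpointRegion(c, int(s), int(e), str(lab)))
    bprs.sort(key=lambda r: (r.chrom, r.begin))

    # --- genes ---
    gene_chrom_idx = rng.choice(len(chroms), size=config.n_genes, p=probs)
    mu = math.log(config.gene_width_mean) - config.gene_width_sigma ** 2 / 2
    gwidths = np.exp(rng.normal(mu, config.gene_width_sigma, size=config.n_genes))
    gwidths = np.maximum(gwidths.astype(np.int64), 200)
    genes: List[GeneRecord] = []
    digits = len(str(config.n_genes))
    for i in range(config.n_genes):
        c = chroms[gene_chrom_idx[i]]
        L = config.chrom_lengths[c]
        w = int(min(gwidths[i], L - 1))
        start = int(rng.integers(0, L - w))
        genes.append(GeneRecord(f"GENE{i:0{digits}d}", c, start, start + w,
                                "+" if rng.random() < 0.5 else "-"))

    # --- DE subset with optional planted proximity effect ---
    de_idx = rng.choice(config.n_genes, size=config.n_de, replace=False)
    n_planted = math.ceil(config.effect_fraction * config.n_de)
    if n_planted and not bprs:
        raise PlacementError("cannot plant a proximity effect without regions")
    for k in range(n_planted):
        i = int(de_idx[k])
        g = genes[i]
        r = bprs[int(rng.integers(0, len(bprs)))]
        L = config.chrom_lengths[r.chrom]
        w = g.width
        gap = int(rng.integers(0, config.effect_radius + 1))
        if rng.random() < 0.5:  # left of the region's begin boundary
            end = r.begin - gap
            start = end - w
        else:                   # right of the region's end boundary
            start = r.end + gap
            end = start + w
        start = max(0, min(start, L - w))
        end = start + w
        genes[i] = GeneRecord(g.name, r.chrom, int(start), int(end), g.strand)
    de_names = {genes[int(i)].name for i in de_idx}
    return genes, bprs, de_names


def write_fixture(
    genes: Sequence[GeneRecord],
    bprs: Sequence[BreakpointRegion],
    de_names: Set[str],
    outdir,
) -> Dict[str, Path]:
    """Write a generated dataset as plain-text files readable by the
    package's own readers: genes as BED, regions in the four-column
    breakpoint dialect, DE names one per line."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.bed",
        "bprs": outdir / "bprs.tsv",
        "de_list": outdir / "de_list.tsv",
    }
    bpio.write_gene_table(genes, paths["genes"])
    bpio.write_bpr_table(bprs, paths["bprs"], dialect="table1_tsv")
    bpio.write_de_list(sorted(de_names), paths["de_list"])
    return paths
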