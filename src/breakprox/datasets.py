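"""Small bundled datasets.

``bpr_example.tsv`` is the published 13-row excerpt of the human
breakpoint-region database built from pairwise comparisons of the human
genome with dog, mouse, rat, macaque and chimpanzee; coordinates are
0-based half-open UCSC-table coordinates on hg17.  It is tiny but real,
and exercises every dialect feature (header, multiple chromosomes,
multiple branch labels, a 1-nt-scale region).

``mammal_phylogeny.nwk`` is a matching six-species phylogeny whose newick
node labels name the edge above each node, giving the branch-label
vocabulary used by lineage selection.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import List

from .io import read_bpr_table
from .types import BreakpointRegion


def _data_path(name: str) -> Path:
    return Path(resources.files("breakprox") / "data" / name)


def example_bpr_table_path() -> Path:
    return _data_path("bpr_example.tsv")


def example_bpr_table() -> List[BreakpointRegion]:
    """The 13-region example breakpoint table, parsed and sorted."""
    return read_bpr_table(example_bpr_table_path(), dialect="table1_tsv")


def example_phylogeny_path() -> Path:
    return _data_path("mammal_phylogeny.nwk")


def example_phylogeny():
    """The matching six-species phylogeny as a Bio.Phylo tree."""
    from .lineage import load_phylogeny

    return load_phylogeny(example_phylogeny_path())
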