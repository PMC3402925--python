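"""Lineage-aware breakpoint selection.

Only rearrangements on branches of the species phylogeny lying *between*
two compared species (on the path through their most recent common
ancestor) differentiate that pair; breakpoints on any other branch are
shared by both genomes, or by neither.  This module selects exactly those
records from a multi-species breakpoint table.

The phylogeny is pure configuration — a newick string whose node labels act
as the labels of the edges above them (leaf name for terminal edges,
internal-node label for internal edges), e.g.::

    ((human,chimp)human-chimp,macaque)root;

so the human-vs-macaque path carries the labels
{human, human-chimp, macaque}.  Label vocabularies differ between published
breakpoint tables, hence nothing is hard-coded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

from Bio import Phylo

from .types import BreakpointRegion

logger = logging.getLogger(__name__)


def _norm_label(label: str) -> str:
    return label.strip().lower()


@dataclass(frozen=True)
class BranchSelection:
    """The set of branch labels to retain, optionally recording the species
    pair it was derived from."""

    branch_labels: FrozenSet[str]
    species_a: str = ""
    species_b: str = ""

    def __post_init__(self) -> None:
        if not self.branch_labels:
            raise ValueError("branch_labels must be non-empty")
        object.__setattr__(
            self, "branch_labels", frozenset(_norm_label(b) for b in self.branch_labels)
        )

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "BranchSelection":
        return cls(frozenset(labels))


def select_breakpoints(
    bprs: Sequence[BreakpointRegion],
    selection: BranchSelection,
) -> List[BreakpointRegion]:
    """Retain exactly the records whose branch label is in the selection.

    Labels are compared case-insensitively after trimming; input order is
    preserved and records are never mutated.  A per-label retained/discarded
    summary is logged; a selected label never observed in the table only
    warns.
    """
    wanted = selection.branch_labels
    retained: List[BreakpointRegion] = []
    kept_counts: Dict[str, int] = {}
    dropped_counts: Dict[str, int] = {}
    for r in bprs:
        label = _norm_label(r.branch)
        if label in wanted:
            retained.append(r)
            kept_counts[label] = kept_counts.get(label, 0) + 1
        else:
            dropped_counts[label] = dropped_counts.get(label, 0) + 1
    missing = wanted - set(kept_counts)
    if missing:
        logger.warning("selected branch labels never observed: %s", sorted(missing))
    logger.info(
        "breakpoint selection: retained %d (%s), discarded %d (%s)",
        len(retained), dict(sorted(kept_counts.items())),
        len(bprs) - len(retained), dict(sorted(dropped_counts.items())),
    )
    return retained


def selection_summary(
    bprs: Sequence[BreakpointRegion],
    selection: BranchSelection,
) -> Tuple[Dict[str, int], Dict[str, int]]:
    """(retained-per-label, discarded-per-label) counts, for run reports."""
    kept: Dict[str, int] = {}
    dropped: Dict[str, int] = {}
    for r in bprs:
        label = _norm_label(r.branch)
        target = kept if label in selection.branch_labels else dropped
        target[label] = target.get(label, 0) + 1
    return kept, dropped


def load_phylogeny(source):
    """Load a newick phylogeny from a path or a newick string."""
    text = None
    if isinstance(source, str) and source.lstrip().startswith("("):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    return Phylo.read(StringIO(text), "newick")


def branches_on_path(tree, species_a: str, species_b: str) -> Set[str]:
    """Labels of the edges on the unique path between two leaves.

    Each edge is named by its child node (newick node-label-as-edge-label
    convention); the label of the most recent common ancestor itself is the
    edge *above* the MCA and is therefore excluded.  Symmetric in its
    arguments; the same-species query yields the empty set.
    """
    clades = {}
    for leaf in tree.get_terminals():
        if leaf.name:
            clades[_norm_label(leaf.name)] = leaf
    try:
        a = clades[_norm_label(species_a)]
        b = clades[_norm_label(species_b)]
    except KeyError as exc:
        raise ValueError(f"unknown species {exc.args[0]!r} in phylogeny") from None
    if a is b:
        return set()
    root = tree.root
    path_a = [root] + root.get_path(a)
    path_b = [root] + root.get_path(b)
    common = 0
    while (common < min(len(path_a), len(path_b))
           and path_a[common] is path_b[common]):
        common += 1
    on_path = path_a[common:] + path_b[common:]
    labels = {_norm_label(c.name) for c in on_path if c.name}
    return labels
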