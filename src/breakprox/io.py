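"""Readers and writers for breakpoint tables, gene annotations, DE lists and
alias maps, plus the name-matching step that links expression elements to
annotated genes.

Supported dialects
------------------
``table1_tsv``
    Four tab-separated columns ``chromosome  begin  end  branch``, an
    optional header.  Coordinates are taken as 0-based half-open, the
    convention of UCSC database tables from which published breakpoint
    sets are typically exported.  Pass ``one_based=True`` for a table in
    1-based fully-closed browser-display coordinates.
``bed``
    Standard BED; for genes column 4 is the name, column 6 the strand; for
    breakpoint regions column 4 carries the branch label.
``name_tsv``
    ``name  chrom  start  end  [strand]`` for gene annotations.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .types import (
    BreakpointRegion,
    ExpressionElement,
    GeneRecord,
    chrom_sort_key,
    normalize_name,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed input row; carries the path and 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


class AliasCycleError(ValueError):
    """The alias map contains a cycle (e.g. A -> B -> A)."""


def _data_lines(path) -> Iterable[Tuple[int, List[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _is_header(fields: Sequence[str]) -> bool:
    # Header auto-detection: a non-numeric second column marks a header row.
    if len(fields) < 2:
        return False
    try:
        int(fields[1])
    except ValueError:
        return True
    return False


def _parse_int(value: str, path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {what}: {value!r}") from None


def read_bpr_table(
    path,
    dialect: str = "table1_tsv",
    one_based: bool = False,
) -> List[BreakpointRegion]:
    """Read a breakpoint-region table into a sorted list.

    Parameters
    ----------
    path : path-like
    dialect : {"table1_tsv", "bed"}
    one_based : bool
        For ``table1_tsv`` only: treat coordinates as 1-based fully-closed
        and convert (begin - 1, end) to the internal 0-based half-open
        convention.

    Returns records sorted by ``(chrom, begin)``.  An empty file yields an
    empty list with a warning.
    """
    if dialect not in ("table1_tsv", "bed"):
        raise ValueError(f"unknown BPR dialect {dialect!r}")
    records: List[BreakpointRegion] = []
    seen = set()
    first = True
    for lineno, fields in _data_lines(path):
        if first and _is_header(fields):
            first = False
            continue
        first = False
        if len(fields) < 4:
            raise ParseError(path, lineno, f"expected 4 columns, got {len(fields)}")
        chrom = fields[0].strip()
        begin = _parse_int(fields[1], path, lineno, "begin")
        end = _parse_int(fields[2], path, lineno, "end")
        branch = fields[3].strip()
        if one_based and dialect == "table1_tsv":
            begin -= 1
        if begin > end:
            raise ParseError(path, lineno, f"begin > end ({begin} > {end})")
        if begin < 0:
            raise ParseError(path, lineno, f"negative coordinate {begin}")
        if not branch:
            raise ParseError(path, lineno, "empty branch label")
        key = (chrom, begin, end)
        if key in seen:
            raise ParseError(path, lineno, f"duplicate region {chrom}:{begin}-{end}")
        seen.add(key)
        records.append(BreakpointRegion(chrom, begin, end, branch))
    if not records:
        warnings.warn(f"no breakpoint regions read from {path}", stacklevel=2)
    records.sort(key=lambda r: (chrom_sort_key(r.chrom), r.begin, r.end))
    return records


def write_bpr_table(
    bprs: Sequence[BreakpointRegion],
    path,
    dialect: str = "table1_tsv",
    header: bool = True,
) -> None:
    """Write breakpoint regions; the table1_tsv dialect round-trips
    losslessly through :func:`read_bpr_table`."""
    with open(path, "w") as fh:
        if dialect == "table1_tsv":
            if header:
                fh.write("Chromosome\tBegin\tEnd\tEvolutionary branch\n")
            for r in bprs:
                fh.write(f"{r.chrom}\t{r.begin}\t{r.end}\t{r.branch}\n")
        elif dialect == "bed":
            for r in bprs:
                fh.write(f"{r.chrom}\t{r.begin}\t{r.end}\t{r.branch}\n")
        else:
            raise ValueError(f"unknown BPR dialect {dialect!r}")


def read_gene_table(
    path,
    dialect: str = "bed",
) -> Tuple[List[GeneRecord], List[str]]:
    """Read a gene annotation table.

    Returns ``(genes, duplicate_names)``: duplicate names (multi-locus
    genes) are all retained but reported, since downstream distance
    computation treats each locus independently.
    """
    if dialect not in ("bed", "name_tsv"):
        raise ValueError(f"unknown gene dialect {dialect!r}")
    genes: List[GeneRecord] = []
    counts: Dict[str, int] = {}
    # Header probe: the first integer-bearing column is #2 for BED,
    # #3 for name_tsv.
    coord_col = 1 if dialect == "bed" else 2
    first = True
    for lineno, fields in _data_lines(path):
        if first:
            first = False
            if len(fields) > coord_col and not fields[coord_col].lstrip("-").isdigit():
                continue
        if dialect == "bed":
            if len(fields) < 4:
                raise ParseError(path, lineno, f"expected >= 4 columns, got {len(fields)}")
            chrom = fields[0].strip()
            start = _parse_int(fields[1], path, lineno, "start")
            end = _parse_int(fields[2], path, lineno, "end")
            name = normalize_name(fields[3])
            strand = fields[5].strip() if len(fields) >= 6 and fields[5].strip() in "+-" else "."
        else:
            if len(fields) < 4:
                raise ParseError(path, lineno, f"expected >= 4 columns, got {len(fields)}")
            name = normalize_name(fields[0])
            chrom = fields[1].strip()
            start = _parse_int(fields[2], path, lineno, "start")
            end = _parse_int(fields[3], path, lineno, "end")
            strand = fields[4].strip() if len(fields) >= 5 and fields[4].strip() in "+-" else "."
        if start > end:
            raise ParseError(path, lineno, f"start > end ({start} > {end})")
        if not name:
            raise ParseError(path, lineno, "empty gene name")
        genes.append(GeneRecord(name, chrom, start, end, strand))
        counts[name] = counts.get(name, 0) + 1
    duplicates = sorted(n for n, c in counts.items() if c > 1)
    if duplicates:
        logger.info("%d duplicated gene names (multi-locus), e.g. %s",
                    len(duplicates), duplicates[:5])
    return genes, duplicates


def write_gene_table(genes: Sequence[GeneRecord], path) -> None:
    """Write genes as 6-column BED."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand if g.strand != '.' else '.'}\n")


def read_de_list(path) -> List[ExpressionElement]:
    """Read a differential-expression element list: TSV with columns
    ``name [direction] [fold_change]``; header auto-detected on the
    fold-change column."""
    elements: List[ExpressionElement] = []
    first = True
    for lineno, fields in _data_lines(path):
        if first:
            first = False
            head = fields[0].strip().lower()
            numeric_third = True
            if len(fields) >= 3 and fields[2].strip():
                try:
                    float(fields[2])
                except ValueError:
                    numeric_third = False
            if head in ("name", "element", "gene", "raw_name") or not numeric_third:
                continue
        raw_name = fields[0].strip()
        if not raw_name:
            raise ParseError(path, lineno, "empty element name")
        direction = "unknown"
        fold_change = None
        if len(fields) >= 2 and fields[1].strip():
            d = fields[1].strip().lower()
            if d not in ("up", "down", "unknown"):
                raise ParseError(path, lineno, f"bad direction {d!r}")
            direction = d
        if len(fields) >= 3 and fields[2].strip():
            try:
                fold_change = float(fields[2])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric fold change {fields[2]!r}") from None
        elements.append(ExpressionElement(raw_name, direction=direction, fold_change=fold_change))
    return elements


def write_de_list(names: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for n in names:
            fh.write(f"{n}\n")


def read_alias_map(path) -> Dict[str, str]:
    """Read a two-column ``old_name  new_name`` alias map; names are
    normalized.  Cycles are detected at resolution time."""
    aliases: Dict[str, str] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(fields)}")
        old = normalize_name(fields[0])
        new = normalize_name(fields[1])
        if old in aliases and aliases[old] != new:
            raise ParseError(path, lineno, f"conflicting alias for {old!r}")
        aliases[old] = new
    return aliases


def resolve_alias(name: str, aliases: Mapping[str, str]) -> str:
    """Follow alias chains to a fixpoint; raises :class:`AliasCycleError`
    on a cycle."""
    seen = {name}
    current = name
    while current in aliases:
        current = aliases[current]
        if current in seen:
            raise AliasCycleError(f"alias cycle involving {name!r}")
        seen.add(current)
    return current


def match_expression_to_genes(
    elements: Sequence[ExpressionElement],
    genes: Sequence[GeneRecord],
    aliases: Optional[Mapping[str, str]] = None,
) -> Tuple[List[ExpressionElement], List[str]]:
    """Link expression-study elements to annotated genes by name.

    Matching order per element: exact normalized-symbol match against the
    annotation, then alias-map lookup (chains followed) and exact match of
    the resolved name.  Every element lands in exactly one of
    (matched, unmatched); an alias resolving to a symbol absent from the
    annotation leaves the element unmatched.

    Returns ``(matched_elements, unmatched_raw_names)``, both in input
    order.
    """
    aliases = dict(aliases or {})
    gene_names = {g.name for g in genes}
    matched: List[ExpressionElement] = []
    unmatched: List[str] = []
    for element in elements:
        name = normalize_name(element.raw_name)
        target = None
        if name in gene_names:
            target = name
        else:
            resolved = resolve_alias(name, aliases)
            if resolved != name and resolved in gene_names:
                target = resolved
        if target is None:
            unmatched.append(element.raw_name)
        else:
            element.matched_gene = target
            matched.append(element)
    return matched, unmatched


def write_drop_report(unmatched: Sequence[str], path, reason: str = "no annotation hit") -> None:
    """TSV report of expression elements dropped for lack of a genome hit."""
    with open(path, "w") as fh:
        fh.write("raw_name\treason\n")
        for name in unmatched:
            fh.write(f"{name}\t{reason}\n")


def write_distance_table(records, path) -> None:
    """TSV of per-gene nearest-BPR distances (one row per analysed gene)."""
    with open(path, "w") as fh:
        fh.write("gene\tchrom\tstart\tend\tis_de\tnearest_begin\tnearest_end\tnearest_branch\tx\tz\n")
        for r in records:
            g = r.gene
            fh.write(
                f"{g.name}\t{g.chrom}\t{g.start}\t{g.end}\t{int(r.is_de)}\t"
                f"{r.nearest.begin}\t{r.nearest.end}\t{r.nearest.branch}\t{r.x}\t{r.z:.6f}\n"
            )
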