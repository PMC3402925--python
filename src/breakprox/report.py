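"""End-to-end pipeline driver, log-scale histogram figures and
closest-gene tables.

The pipeline mirrors the linking protocol of breakpoint/expression
studies: read the three inputs, match expression elements to annotated
genes by name, select lineage-relevant breakpoints, compute nearest-
breakpoint distances for the full gene complement, run the formal tests,
and emit every intermediate as TSV plus the log-scale histogram figures.
All outputs are deterministic given identical inputs and seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import io as bpio
from .lineage import BranchSelection, select_breakpoints, selection_summary
from .nullmodel import MixtureNull, monte_carlo_test, two_sample_compare
from .proximity import compute_all_distances, flanking_interval, group_by_chromosome
from .simulate import SyntheticConfig, simulate_dataset, write_fixture
from .types import DistanceRecord

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage, with the original context."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def histogram_counts(
    z_values: Sequence[float],
) -> Tuple[np.ndarray, np.ndarray]:
    """Counts of z in unit-width natural-log bins with edges {0, 1, 2, ...}
    up to ceil(max z).  Returns (edges, counts)."""
    z = np.asarray(z_values, dtype=float)
    top = max(1, int(math.ceil(z.max()))) if z.size else 1
    edges = np.arange(0, top + 1, dtype=float)
    counts, _ = np.histogram(z, bins=edges)
    return edges, counts


def plot_log_histograms(
    records: Sequence[DistanceRecord],
    outpath,
    per_chromosome: bool = False,
    mixture: Optional[MixtureNull] = None,
    fmt: str = "png",
) -> List[Path]:
    """Paired density-normalized histograms of z = ln(distance) for the
    differentially expressed genes versus the rest of the complement.

    Bins are unit-width on the natural-log scale from 0 to ceil(max z).
    Density normalization keeps the two groups comparable despite the DE
    group being orders of magnitude smaller.  One genome-wide figure is
    always produced; ``per_chromosome`` adds one figure per chromosome
    (a group empty on some chromosome annotates the panel rather than
    dropping it).  Returns the written paths.
    """
    if not records:
        raise ValueError("no distance records to plot")
    outpath = Path(outpath)
    outpath.parent.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def _panel(ax, recs: Sequence[DistanceRecord], title: str) -> None:
        z_de = [r.z for r in recs if r.is_de]
        z_bg = [r.z for r in recs if not r.is_de]
        zmax = max((r.z for r in recs), default=1.0)
        edges = np.arange(0, max(1, int(math.ceil(zmax))) + 1, dtype=float)
        for sample, label, color in ((z_bg, "complement", "0.6"),
                                     (z_de, "differentially expressed", "C3")):
            if sample:
                ax.hist(sample, bins=edges, density=True, histtype="step",
                        lw=1.6, color=color, label=f"{label} (n={len(sample)})")
            else:
                ax.annotate(f"no {label} genes", xy=(0.5, 0.5),
                            xycoords="axes fraction", ha="center", color=color)
        if mixture is not None:
            grid = np.linspace(0, mixture.max_U, 400)
            ax.plot(grid, mixture.pdf(grid), "k--", lw=1.0, label="null mixture")
        ax.set_xlabel("z = ln(distance to nearest breakpoint, nt)")
        ax.set_ylabel("density")
        ax.set_title(title)
        ax.legend(fontsize=8)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    _panel(ax, records, "all chromosomes")
    fig.tight_layout()
    genome_path = outpath.with_suffix(f".{fmt}")
    fig.savefig(genome_path, dpi=120)
    plt.close(fig)
    written.append(genome_path)

    if per_chromosome:
        chroms = sorted({r.gene.chrom for r in records})
        for chrom in chroms:
            sub = [r for r in records if r.gene.chrom == chrom]
            fig, ax = plt.subplots(figsize=(7, 4.5))
            _panel(ax, sub, chrom)
            fig.tight_layout()
            p = outpath.parent / f"{outpath.stem}.{chrom}.{fmt}"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
    return written


def closest_de_table(
    records: Sequence[DistanceRecord],
    k: Optional[int] = None,
    max_x: Optional[int] = None,
) -> pd.DataFrame:
    """The differentially expressed genes closest to a breakpoint.

    Rows are DE records sorted by ascending distance (ties broken by gene
    name, lexicographically, for reproducibility), truncated to the first
    ``k`` rows and/or to distances ``x <= max_x``.  An empty DE set yields
    an empty table with the header intact.
    """
    de = sorted((r for r in records if r.is_de), key=lambda r: (r.x, r.gene.name))
    if max_x is not None:
        de = [r for r in de if r.x <= max_x]
    if k is not None:
        de = de[:k]
    return pd.DataFrame(
        [
            {
                "gene": r.gene.name, "chrom": r.gene.chrom,
                "start": r.gene.start, "end": r.gene.end,
                "x": r.x, "z": round(r.z, 6),
                "bpr_begin": r.nearest.begin, "bpr_end": r.nearest.end,
                "bpr_branch": r.nearest.branch,
            }
            for r in de
        ],
        columns=["gene", "chrom", "start", "end", "x", "z",
                 "bpr_begin", "bpr_end", "bpr_branch"],
    )


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run.  Either the three input
    paths are given, or ``synthetic`` requests a generated dataset."""

    outdir: Path
    bpr_path: Optional[Path] = None
    gene_path: Optional[Path] = None
    de_path: Optional[Path] = None
    alias_path: Optional[Path] = None
    bpr_dialect: str = "table1_tsv"
    gene_dialect: str = "bed"
    branch_labels: Optional[Sequence[str]] = None
    species_pair: Optional[Tuple[str, str]] = None
    tree_path: Optional[Path] = None
    synthetic: Optional[SyntheticConfig] = None
    point_mode: bool = False
    n_sim: int = 200
    seed: int = 0
    per_chromosome_figures: bool = False
    closest_max_x: int = 100_000


@dataclass
class RunSummary:
    """Tallies, test results and artifact paths for one pipeline run."""

    counts: Dict[str, int] = field(default_factory=dict)
    retained_per_branch: Dict[str, int] = field(default_factory=dict)
    discarded_per_branch: Dict[str, int] = field(default_factory=dict)
    excluded_by_chrom: Dict[str, int] = field(default_factory=dict)
    ks_statistic: float = float("nan")
    ks_pvalue: float = float("nan")
    mc_observed_median_z: float = float("nan")
    mc_pvalue: float = float("nan")
    n_sim: int = 0
    seed: int = 0
    artifacts: Dict[str, str] = field(default_factory=dict)
    config_echo: Dict[str, str] = field(default_factory=dict)

    def reconciled(self) -> bool:
        c = self.counts
        ok = c.get("elements_matched", 0) + c.get("elements_dropped", 0) == c.get("elements_read", 0)
        ok &= c.get("genes_analysed", 0) + c.get("genes_excluded", 0) == c.get("genes_read", 0)
        return ok

    def to_json(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True, default=str)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Execute read -> match -> filter -> distances -> tests -> figures ->
    tables, writing every intermediate under ``config.outdir``.

    Idempotent: identical inputs and seed give byte-identical TSV outputs.
    Any stage failure aborts with the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(seed=config.seed, n_sim=config.n_sim)
    summary.config_echo = {
        "point_mode": str(config.point_mode),
        "bpr_dialect": config.bpr_dialect,
        "synthetic": str(config.synthetic is not None),
    }

    # --- stage: inputs ---
    @_stage("read_inputs")
    def _read():
        if config.synthetic is not None:
            genes, bprs, de_names = simulate_dataset(config.synthetic)
            paths = write_fixture(genes, bprs, de_names, outdir / "inputs")
            summary.artifacts.update({k: str(v) for k, v in paths.items()})
            elements = [bpio.ExpressionElement(n) for n in sorted(de_names)]
            return genes, [], bprs, elements, {}
        if not (config.bpr_path and config.gene_path and config.de_path):
            raise ValueError("bpr_path, gene_path and de_path are all required")
        bprs = bpio.read_bpr_table(config.bpr_path, dialect=config.bpr_dialect)
        genes, duplicates = bpio.read_gene_table(config.gene_path,
                                                 dialect=config.gene_dialect)
        elements = bpio.read_de_list(config.de_path)
        aliases = bpio.read_alias_map(config.alias_path) if config.alias_path else {}
        return genes, duplicates, bprs, elements, aliases

    genes, duplicates, bprs, elements, aliases = _read()
    summary.counts["genes_read"] = len(genes)
    summary.counts["elements_read"] = len(elements)
    summary.counts["bprs_read"] = len(bprs)
    summary.counts["duplicate_gene_names"] = len(duplicates)

    # --- stage: match ---
    @_stage("match_expression")
    def _match():
        matched, unmatched = bpio.match_expression_to_genes(elements, genes, aliases)
        drop_path = outdir / "dropped_elements.tsv"
        bpio.write_drop_report(unmatched, drop_path)
        summary.artifacts["drop_report"] = str(drop_path)
        return matched, unmatched

    matched, unmatched = _match()
    summary.counts["elements_matched"] = len(matched)
    summary.counts["elements_dropped"] = len(unmatched)
    de_names: Set[str] = {e.matched_gene for e in matched}

    # --- stage: lineage filter ---
    @_stage("lineage_filter")
    def _filter():
        if config.branch_labels:
            sel = BranchSelection.from_labels(config.branch_labels)
        elif config.species_pair and config.tree_path:
            from .lineage import branches_on_path, load_phylogeny
            tree = load_phylogeny(config.tree_path)
            labels = branches_on_path(tree, *config.species_pair)
            sel = BranchSelection(frozenset(labels),
                                  species_a=config.species_pair[0],
                                  species_b=config.species_pair[1])
        else:
            return bprs, {}, {}
        kept, dropped = selection_summary(bprs, sel)
        return select_breakpoints(bprs, sel), kept, dropped

    retained, kept_counts, dropped_counts = _filter()
    summary.retained_per_branch = kept_counts
    summary.discarded_per_branch = dropped_counts
    summary.counts["bprs_retained"] = len(retained)

    # --- stage: distances ---
    @_stage("distances")
    def _distances():
        records, dsummary = compute_all_distances(
            genes, de_names, retained, point_mode=config.point_mode)
        path = outdir / "distances.tsv"
        bpio.write_distance_table(records, path)
        summary.artifacts["distances"] = str(path)
        return records, dsummary

    records, dsummary = _distances()
    summary.counts["genes_analysed"] = dsummary.n_analysed
    summary.counts["genes_excluded"] = dsummary.n_excluded
    summary.counts["de_genes_analysed"] = dsummary.n_de
    summary.excluded_by_chrom = dsummary.excluded_by_chrom

    # --- stage: tests ---
    @_stage("tests")
    def _tests():
        z_de = [r.z for r in records if r.is_de]
        z_bg = [r.z for r in records if not r.is_de]
        ks = two_sample_compare(z_de, z_bg) if z_de and z_bg else None
        chrom_lengths = (dict(config.synthetic.chrom_lengths)
                         if config.synthetic is not None else None)
        mc = monte_carlo_test(
            genes, de_names, retained, n_sim=config.n_sim, seed=config.seed,
            point_mode=config.point_mode, chrom_lengths=chrom_lengths,
        ) if z_de else None
        path = outdir / "test_results.tsv"
        with open(path, "w") as fh:
            fh.write("test\tstatistic\tpvalue\tn_de\tn_rest\tn_sim\tseed\n")
            if ks is not None:
                fh.write(f"ks_two_sample\t{ks.statistic:.6f}\t{ks.pvalue:.6g}\t"
                         f"{ks.n_de}\t{ks.n_rest}\t\t\n")
            if mc is not None:
                fh.write(f"monte_carlo_median_z\t{mc.observed_stat:.6f}\t"
                         f"{mc.pvalue:.6g}\t{mc.n_de}\t\t{mc.n_sim}\t{config.seed}\n")
        summary.artifacts["test_results"] = str(path)
        return ks, mc

    ks, mc = _tests()
    if ks is not None:
        summary.ks_statistic, summary.ks_pvalue = ks.statistic, ks.pvalue
    if mc is not None:
        summary.mc_observed_median_z = mc.observed_stat
        summary.mc_pvalue = mc.pvalue

    # --- stage: figures & tables ---
    @_stage("report")
    def _report():
        fig_paths = plot_log_histograms(
            records, outdir / "log_distance_hist",
            per_chromosome=config.per_chromosome_figures)
        for p in fig_paths:
            summary.artifacts[f"figure:{p.stem}"] = str(p)
        table = closest_de_table(records, max_x=config.closest_max_x)
        tpath = outdir / "closest_de.tsv"
        table.to_csv(tpath, sep="\t", index=False)
        summary.artifacts["closest_de"] = str(tpath)

    _report()
    summary.to_json(outdir / "run_summary.json")
    summary.artifacts["run_summary"] = str(outdir / "run_summary.json")
    if not summary.reconciled():
        logger.warning("run summary counts do not reconcile: %s", summary.counts)
    return summary
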