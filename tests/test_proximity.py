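"""Nearest-breakpoint distances and flanking-interval geometry."""

import math

import numpy as np
import pytest

import breakprox as bp
from breakprox.proximity import (
    NoBreakpointOnChromosome,
    group_by_chromosome,
    nearest_gaps_vectorized,
)


def brute_force_nearest(gene, bprs, point_mode=False):
    """Exhaustive O(n*m) oracle with an independently written gap formula:
    gap(A, B) = max(0, max(startA, startB) - min(endA, endB)) for half-open
    intervals."""
    if point_mode:
        gs = ge = gene.midpoint
    else:
        gs, ge = gene.start, gene.end
    best = None
    for r in bprs:
        gap = max(0, max(gs, r.begin) - min(ge, r.end))
        if best is None or gap < best[0]:
            best = (gap, r)
    return int(best[0]), best[1]


class TestNearestDistance:
    def test_worked_example_on_published_excerpt(self, excerpt_bprs, toy_genes):
        chr3 = [r for r in excerpt_bprs if r.chrom == "chr3"]
        gene = toy_genes[0]  # chr3:127500000-127501000
        x, nearest = bp.nearest_bpr_distance(gene, chr3)
        assert x == 292184
        assert (nearest.begin, nearest.end) == (126855424, 127207816)
        # the two candidate gaps, by hand
        from breakprox.proximity import interval_gap
        assert interval_gap(gene.start, gene.end, chr3[0].begin, chr3[0].end) == 292184
        assert interval_gap(gene.start, gene.end, chr3[1].begin, chr3[1].end) == 786101

    def test_overlap_gives_zero(self, excerpt_bprs, toy_genes):
        chr1 = [r for r in excerpt_bprs if r.chrom == "chr1"]
        x, nearest = bp.nearest_bpr_distance(toy_genes[1], chr1)
        assert x == 0
        assert nearest.begin == 10382322

    def test_tie_breaks_toward_lower_coordinate(self):
        bprs = [
            bp.BreakpointRegion("chr1", 0, 100, "dog"),
            bp.BreakpointRegion("chr1", 300, 400, "dog"),
        ]
        gene = bp.GeneRecord("G", "chr1", 150, 250)  # 50 nt to both
        x, nearest = bp.nearest_bpr_distance(gene, bprs)
        assert x == 50 and nearest.begin == 0

    def test_empty_region_list_errors(self):
        with pytest.raises(NoBreakpointOnChromosome):
            bp.nearest_bpr_distance(bp.GeneRecord("G", "chr1", 0, 10), [])

    def test_invariant_under_input_shuffle(self, rng, excerpt_bprs):
        chr1 = [r for r in excerpt_bprs if r.chrom == "chr1"]
        gene = bp.GeneRecord("G", "chr1", 120_000_000, 120_010_000)
        expected = bp.nearest_bpr_distance(gene, chr1)
        for _ in range(10):
            perm = [chr1[i] for i in rng.permutation(len(chr1))]
            perm.sort(key=lambda r: r.begin)
            assert bp.nearest_bpr_distance(gene, perm) == expected

    @pytest.mark.parametrize("point_mode", [False, True])
    def test_matches_exhaustive_oracle_on_random_instances(self, point_mode):
        """Bisection path vs the exhaustive-scan oracle on >= 1000 random
        gene x region instances, overlap and tie cases included."""
        rng = np.random.default_rng(777)
        n_cases = 0
        for trial in range(25):
            n_bpr = int(rng.integers(1, 15))
            # small coordinate space on purpose: forces overlaps and ties
            starts = np.sort(rng.choice(2000, size=n_bpr, replace=False))
            widths = rng.integers(1, 60, size=n_bpr)
            bprs, last_end = [], -1
            for s, w in zip(starts, widths):
                s = max(int(s), last_end)
                e = int(s + w)
                bprs.append(bp.BreakpointRegion("chrT", s, e, "dog"))
                last_end = e
            for _ in range(40):
                gs = int(rng.integers(0, 2100))
                ge = gs + int(rng.integers(0, 80))
                gene = bp.GeneRecord("G", "chrT", gs, ge)
                got_x, got_r = bp.nearest_bpr_distance(gene, bprs, point_mode=point_mode)
                exp_x, _ = brute_force_nearest(gene, bprs, point_mode=point_mode)
                assert got_x == exp_x, (gene, bprs)
                n_cases += 1
        assert n_cases >= 1000

    def test_vectorized_gaps_agree_with_scalar_path(self):
        rng = np.random.default_rng(31)
        starts = np.sort(rng.choice(100_000, size=20, replace=False))
        bprs, last = [], -1
        for s in starts:
            s = max(int(s), last)
            e = s + int(rng.integers(1, 500))
            bprs.append(bp.BreakpointRegion("chrV", s, e, "dog"))
            last = e
        begins = np.array([r.begin for r in bprs])
        ends = np.array([r.end for r in bprs])
        gs = rng.integers(0, 101_000, size=500)
        ge = gs + rng.integers(0, 1000, size=500)
        gaps = nearest_gaps_vectorized(gs.astype(float), ge.astype(float), begins, ends)
        for i in range(500):
            gene = bp.GeneRecord("G", "chrV", int(gs[i]), int(ge[i]))
            exp, _ = brute_force_nearest(gene, bprs)
            assert gaps[i] == exp


class TestComputeAllDistances:
    def test_bpr_free_chromosomes_excluded_and_counted(
            self, excerpt_bprs, toy_genes):
        records, summary = bp.compute_all_distances(
            toy_genes, set(), excerpt_bprs)
        assert {r.gene.chrom for r in records} == {"chr1", "chr3"}
        assert summary.excluded_by_chrom == {"chr9": 1}
        assert summary.n_analysed + summary.n_excluded == summary.n_genes_in

    def test_de_flags(self, excerpt_bprs, toy_genes):
        records, _ = bp.compute_all_distances(
            toy_genes, {"GENEA"}, excerpt_bprs)
        flags = {r.gene.name: r.is_de for r in records}
        assert flags == {"GENEA": True, "GENEB": False}
        records0, _ = bp.compute_all_distances(toy_genes, set(), excerpt_bprs)
        assert not any(r.is_de for r in records0)

    def test_log_distance_definition(self):
        assert bp.log_distance(1) == 0.0
        assert bp.log_distance(0) == 0.0
        x = round(math.exp(16))
        assert bp.log_distance(x) == pytest.approx(16.0, abs=1e-6)


class TestFlankingInterval:
    def test_worked_example_on_published_excerpt(self, excerpt_bprs, toy_genes):
        chr3 = [r for r in excerpt_bprs if r.chrom == "chr3"]
        fl = bp.flanking_interval(toy_genes[0], chr3, 199_000_000)
        assert fl.a1 == 127207816
        assert fl.a2 == 128287101
        assert fl.a2 - fl.a1 == 1079285
        assert fl.u == pytest.approx(539642.5)
        assert fl.U == pytest.approx(math.log(539642.5))
        assert not fl.degenerate

    def test_gene_left_of_all_regions_uses_chromosome_start(self, excerpt_bprs):
        chr3 = [r for r in excerpt_bprs if r.chrom == "chr3"]
        gene = bp.GeneRecord("G", "chr3", 1000, 2000)
        fl = bp.flanking_interval(gene, chr3, 199_000_000)
        assert fl.a1 == 0
        assert fl.a2 == 126855424

    def test_gene_right_of_all_regions_uses_chromosome_end(self, excerpt_bprs):
        chr3 = [r for r in excerpt_bprs if r.chrom == "chr3"]
        gene = bp.GeneRecord("G", "chr3", 150_000_000, 150_001_000)
        fl = bp.flanking_interval(gene, chr3, 199_000_000)
        assert fl.a2 == 199_000_000

    def test_midpoint_inside_region_is_degenerate(self, excerpt_bprs):
        chr3 = [r for r in excerpt_bprs if r.chrom == "chr3"]
        gene = bp.GeneRecord("G", "chr3", 127_000_000, 127_000_100)
        fl = bp.flanking_interval(gene, chr3, 199_000_000)
        assert fl.degenerate and fl.u == 0.0

    def test_geometry_bound_x_le_u_plus_half_width(self, rng):
        """When both flanks are true regions, the nearest distance cannot
        exceed the half-spacing plus half the gene width."""
        bprs = []
        last = 0
        for _ in range(30):
            s = last + int(rng.integers(1000, 100_000))
            e = s + int(rng.integers(1, 5000))
            bprs.append(bp.BreakpointRegion("chrG", s, e, "dog"))
            last = e
        lo, hi = bprs[0].end, bprs[-1].begin
        for _ in range(300):
            gs = int(rng.integers(lo, hi))
            ge = gs + int(rng.integers(0, 2000))
            gene = bp.GeneRecord("G", "chrG", gs, ge)
            if not (lo < gene.midpoint < hi):
                continue  # flank would be a chromosome end, not a region
            fl = bp.flanking_interval(gene, bprs, last + 10_000)
            if fl.degenerate:
                continue
            x, _ = bp.nearest_bpr_distance(gene, bprs)
            assert x <= fl.u + gene.width / 2 + 1e-9
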