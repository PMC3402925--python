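"""Distances against the bundled published breakpoint excerpt.

The package ships a 13-region excerpt of a human breakpoint-region table
(pairwise comparisons of human with dog, mouse, rat, macaque and chimp).
This script selects the branches separating human from macaque, then
computes the nearest-breakpoint distance and flanking interval for a gene
on chromosome 3.
"""

import breakprox as bp

bprs = bp.example_bpr_table()
print(f"regions in the excerpt: {len(bprs)}")

tree = bp.example_phylogeny()
labels = bp.branches_on_path(tree, "human", "macaque")
print(f"branches on the human-macaque path: {sorted(labels)}")
kept = bp.select_breakpoints(bprs, bp.BranchSelection(frozenset(labels)))
print(f"lineage-relevant regions retained: {len(kept)}")

# Only chimp/macaque labels occur in the excerpt itself:
kept2 = bp.select_breakpoints(bprs, bp.BranchSelection.from_labels(["chimp", "macaque"]))
print(f"retained with labels {{chimp, macaque}}: {len(kept2)}")

gene = bp.GeneRecord("GENEA", "chr3", 127_500_000, 127_501_000, "+")
chr3 = [r for r in bprs if r.chrom == "chr3"]
x, nearest = bp.nearest_bpr_distance(gene, chr3)
print(f"{gene.name} -> nearest region {nearest.chrom}:{nearest.begin}-{nearest.end} "
      f"({nearest.branch}), gap x = {x} nt")

fl = bp.flanking_interval(gene, chr3, 199_000_000)
print(f"flanking boundaries a1={fl.a1:.0f}, a2={fl.a2:.0f}; "
      f"half-spacing u = {fl.u} nt, U = ln u = {fl.U:.3f}")
# x is the nucleotide gap to the closest region (0 would mean the gene is
# disrupted); u sets the truncation point of this gene's null component.
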