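# Methods

## Question and design

The analysis asks whether genes that change expression between two species
lie closer to the rearrangement breakpoints separating those species than
the gene complement at large.  Three inputs are linked by name and
position: a breakpoint-region (BPR) table with one evolutionary-branch
label per region, a gene annotation, and a list of differentially
expressed (DE) elements from a cross-species expression study.  The
pipeline matches DE elements to annotated genes, retains only breakpoints
on the phylogeny branches between the two species, computes each gene's
distance to its nearest retained breakpoint, and compares the DE and
background distance distributions.

## Coordinates and distances

All intervals are stored 0-based half-open, the convention of BED files
and UCSC database tables.  The four-column BPR dialect is read natively in
those coordinates (UCSC *table* exports are 0-based half-open even though
the browser displays 1-based closed positions); an explicit
`one_based=True` flag converts a 1-based fully-closed table instead, so
the choice is visible and reversible rather than baked in.

The gene-to-breakpoint distance is the interval-to-interval gap in
nucleotides: 0 when gene and region overlap (the gene is disrupted),
otherwise the separation of the closer pair of facing boundaries.  Ties
break toward the lower-coordinate region.  A `point_mode` variant measures
from the gene midpoint, matching the point-gene idealization of the null
derivation; both are exposed because either convention is defensible for
extended genes.  Distances never cross chromosomes, and strand is ignored.
Genes on chromosomes carrying no retained breakpoint have no defined
distance and are excluded (and counted), not imputed.

Nearest-gap queries use bisection over the sorted region boundaries,
which is valid because regions within a chromosome never overlap (true of
published BPR sets and enforced by the generator); the exhaustive
O(n·m) scan is kept as the test oracle.

## The null model

Let a₁ < a₂ be the breakpoint boundaries flanking a gene and
u = |a₁ − a₂|/2.  Under the null the gene's position is uniform in
[a₁, a₂], so the distance x to the closer boundary is uniform on [0, u].
We adopt the x ∈ [1, u] convention so that z = ln x ≥ 0; then

    p(z) = e^(z − U) on [0, U],   U = ln u,
    F(z) = (e^z − 1) / (e^U − 1).

The density form integrates to 1 − e^(−U): the e^(−U) deficit is the
probability of sub-nucleotide distances under the un-floored model, about
1e-7 at genomic spacings (U ≈ 16), and is documented rather than hidden
by renormalization.  Distances are floored at 1 nt (z = ln max(x, 1)) for
the same reason.  Natural logarithms are used throughout.

Each gene has its own u, so the genome-wide prediction is a mixture with
one component per gene.  Weights are equal by default (one gene, one
draw); length-proportional weights are available but change the meaning
to "per nucleotide" rather than "per gene".  Components with u < 1 nt
(midpoint inside a region, or adjacent regions) carry no log-scale
information and are dropped with a warning.

Chromosome ends are treated as pseudo-boundaries when a gene has no
breakpoint on one side, so every gene on a breakpoint-bearing chromosome
has a defined flanking interval; such genes still use their true
nearest-breakpoint x.  This keeps the mixture defined for all genes at
the cost of a mild edge approximation, which the calibration tests show
is negligible at the default densities.

## Tests

The original comparison of DE and background histograms was visual; this
package adds two quantitative formalizations, clearly labelled as its own
extensions.

**Two-sample KS.**  `two_sample_compare` applies the standard two-sample
Kolmogorov–Smirnov test to the DE and background z samples
(`scipy.stats.ks_2samp`).  Samples below size 5 trigger a warning rather
than an error.

**Monte-Carlo position resampling.**  `monte_carlo_test` redraws each DE
gene uniformly within its flanking interval (width preserved, clamped
inside; degenerate intervals leave the gene in place), recomputes its
nearest-breakpoint distance against the full region set of its
chromosome, and records the median z over DE genes.  The one-sided
empirical p-value is (1 + #{simulated medians ≤ observed}) / (n_sim + 1),
which is exact-valid for any n_sim.  The median was chosen as the default
statistic because it is robust and scale-free; the mean is available by
flag.  The resampler is vectorised per chromosome, so 200 simulations of
250 DE genes cost milliseconds.

## Synthetic data

The generator emulates the structure the analysis assumes, not any
particular genome.  Defaults — the reference study conditions used by the
calibration and power tests — are three 100-Mb chromosomes, 5000 genes,
40 BPRs, 250 DE genes, seed-deterministic throughout:

- **BPRs**: counts multinomial in chromosome length; widths log-uniform
  on [1, 2,887,673] nt, echoing the span of published mammalian BPR sets
  (which report a 1 nt – 2.9 Mb range but not a full size distribution);
  placement by rejection sampling with a bounded retry budget, so regions
  never overlap.  Branch labels drawn from a configurable pool.
- **Genes**: positions uniform, widths lognormal with mean 25 kb and
  log-sd 1 (floored at 200 nt) — the order of magnitude of mammalian
  gene lengths.
- **DE subset**: a uniform sample of `n_de` genes.  With a planted
  effect, ⌈effect_fraction · n_de⌉ of them are re-placed so their nearer
  edge lies uniformly within `effect_radius` of a uniformly chosen region
  boundary (measuring from the boundary matches the gap definition of the
  distance engine).  `effect_fraction = 0` gives an exact null: the DE
  flag is independent of position.

What the generator does **not** emulate: gene clustering and gene-rich /
gene-poor regions, the co-occurrence of breakpoints with duplications and
GC-rich regions, realistic per-chromosome breakpoint counts, or
expression magnitudes (only the DE/non-DE partition is consumed).
Passing calibration on this generator therefore demonstrates correctness
of the statistical machinery under the stated null, not robustness to
every correlation structure of real genomes.

## Numerical and design choices

- `expm1`/`log1p` forms for the CDF and sampler avoid cancellation at
  small U.
- Header detection in readers keys on a non-numeric coordinate column;
  malformed rows fail with the file and 1-based line number.
- Gene/element names are matched after trimming, uppercasing and removal
  of trailing `.N` version suffixes, since name drift is the dominant
  loss mode when linking expression studies to annotations; alias chains
  are followed to a fixpoint with cycle detection.
- Duplicate gene names (multi-locus genes) are all retained and reported;
  each locus contributes its own distance.
- The phylogeny-to-label mapping is configuration (newick with node
  labels naming the edge above each node), never hard-coded, because
  label vocabularies differ between BPR tables — the bundled excerpt, for
  instance, labels regions `chimp`/`macaque`/`primates` while a
  human–macaque path query yields `human`/`human-chimp`/`macaque`; the
  selection API warns on labels it never observes instead of guessing.
- Tables of closest DE genes break distance ties by gene name,
  lexicographically, for reproducibility; histograms use unit-width
  natural-log bins from 0 and density normalization (the DE group is
  orders of magnitude smaller than the complement).
- One integer seed controls every stochastic component; pipeline reruns
  with the same inputs and seed are byte-identical in all TSV outputs.

## Problem sizes

The calibration suite uses 200 replicate genomes at the default study
conditions with 200 Monte-Carlo simulations each, and the power suite 50
planted-effect genomes — about 25 s total on one CPU, thanks to the
vectorised resampler.  Larger n_sim sharpens the attainable minimum
p-value (1/(n_sim+1)) but changes nothing qualitatively; the consistency
test checks n_sim = 100 vs 1000 agree within Monte-Carlo error.

## Limitations

- The flanking-interval null conditions on the observed breakpoint
  spacing around each gene; it does not model breakpoint placement
  itself.
- Distances to the *nearest* breakpoint ignore the second-nearest and
  farther regions, as in the original protocol.
- The mixture is a prediction, not a fit: no parameters are estimated
  from the observed histogram, and no goodness-of-fit machinery beyond
  the tests described is provided.
- Single-comparison design: no multiple-testing correction across
  tissues or species pairs.
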