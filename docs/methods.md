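# Methods

This note documents the models, algorithms and numerical choices behind
`karyograph`, and what its synthetic-data generators do and do not emulate.

## Coordinates and containers

All internal coordinates are 0-based half-open. GFF3 (1-based closed) is
converted on read and back on write; BED is consumed natively. Gene order on
a chromosome ("rank") sorts by start coordinate, with ties broken by end
coordinate and then gene id, so ordinals are reproducible. A gene's position
for all ordering purposes is its start; strand is recorded but never used —
none of the synteny computations condition on orientation. Every sequence in
an annotation is treated as a chromosome, so scaffold-level assemblies are
handled uniformly.

## Karyotype-evolution simulator

`simulate_clade` evolves an ancestral genome of `n_ancestral_chromosomes`
chromosomes × `genes_per_chromosome` genes along a rooted newick tree. Per
branch, event counts are drawn Poisson(rate × branch length); a branch
without a stated length gets length 1. Events, applied in a fixed type
order:

- **fusion** — two uniformly chosen chromosomes joined end-to-end, the order
  of the partners uniform (recorded in the log); skipped and logged when one
  chromosome remains.
- **fission** — one chromosome split at a uniform internal gene boundary;
  1-gene chromosomes are resampled.
- **translocation** — reciprocal exchange of suffixes between two
  chromosomes, one uniform cut point each.
- **transposition** — a single gene moved to a uniform position on its own
  chromosome (this is what scrambles gene order without touching
  chromosome-level linkage).
- **loss / duplication** — a uniform gene deleted, or copied to a uniform
  position on a uniform chromosome.

Randomness derives from one root seed by stable hashing of (seed, branch,
event type), so adding one event type or branch does not perturb the streams
of the others, and the same config always reproduces the identical clade.
Every extant gene traces to one ancestral gene; orthogroups are the
descendant sets of each ancestral gene, and the true ancestral-linkage-group
(ALG) label of an orthogroup is its founder's ancestral chromosome.

Defaults are the package's reference study condition: an 18-chromosome
ancestor, 150 genes per chromosome, six extant species, expected 2 fusions +
2 fissions + 0.5 translocations per branch and heavy transposition (expected
200 gene moves per branch), no loss or duplication. The default topology is
a six-leaf star with unit branches: rearrangements are then lineage-private,
which is the regime the cross-species linkage filter (below) is built for.
On deeper trees, fusions on internal branches are inherited by whole
subtrees and are genuinely indistinguishable from ancestral linkage — the
method then correctly reports the karyotype of a more recent ancestor, and
recovery of the root karyotype degrades. That is a property of the problem,
not of the implementation.

What the simulator does **not** emulate: nucleotide-level evolution,
whole-genome duplication, inversions (strand is ignored downstream), rate
heterogeneity across lineages, and assembly artefacts (chimeric scaffolds,
collapsed repeats). Passing tests therefore demonstrate algorithmic
correctness and statistical behaviour under the stated generative model, not
robustness to real-data artefacts.

## ALG inference

Orthogroups are placed per species on the chromosome holding a strict
plurality of their member genes (ties → unplaced). The linkage graph joins
two orthogroups with weight equal to the number of species in which they are
co-placed on one chromosome; edges below `min_support = 2` are dropped, so
every edge reflects cross-species agreement and lineage-private fusions
cannot link two ancestral groups.

Communities are found by consensus clustering around the Leiden algorithm
optimizing weighted modularity

    Q = Σ_c [ W_c/W − γ (S_c / 2W)² ]

with resolution multiplier γ. `n_runs` independent Leiden optimizations
(distinct derived seeds) are summarized in a co-assignment frequency matrix;
frequencies ≥ 0.5 define a consensus graph on which Leiden is re-applied,
iterating until two consecutive iterations give the identical partition
(error after 50 iterations). The run ensemble alternates the optimiser's
node-move strategy between the greedy default and stochastic
neighbour-community selection; the stochastic runs escape local optima that
every greedy trajectory gets stuck in, which matters on small dense graphs.
As a safeguard, if the converged consensus scores lower resolution-scaled
modularity than the best individual run, the best run is returned —
consensus is meant to stabilize, never to degrade, the solution.

Reported per partition: plain (γ=1) modularity on the original graph;
stability, defined as the probability that two independent runs agree on a
random node pair (computed from the first-round co-assignment frequencies);
and the ALG count, which excludes communities smaller than 1% of nodes
(tiny remnants are reported in the assignment but not counted as ALGs).
`scenario_sweep` produces one consensus partition per resolution and selects
the max-modularity scenario, ties toward fewer ALGs.

## Macrosynteny

Oxford tables use single-copy orthologous pairs by default (multi-copy
orthogroups contribute only on request, as full cross-products). Chromosome
correspondence uses joint thresholds — a partner chromosome is significant
when it shares ≥ `min_count` (5) pairs and ≥ `min_fraction` (5%) of the
chromosome's pairs — rather than a statistical test, matching how such
correspondences are reported descriptively; at the defaults, uniform
background scatter over a 15×15 karyotype at n≈8000 pairs produces no
spurious partner. ALG projection calls a fusion when ≥2 ALGs exceed both a
count (10) and fraction (10%) threshold on one chromosome, and a fission
when one ALG does so on ≥2 chromosomes. Ancestor-to-ancestor maps weight an
edge by the fraction of the parent ALG's orthogroups found in the child ALG;
weights strictly above 0.8 are flagged near one-to-one.

## Microsynteny

A block is a colinear chain of orthologous gene pairs: strictly increasing
rank in species A, strictly monotone (either direction) in B, with at most
`max_intervening` non-member genes between consecutive members in each
species counted independently — a gene whose orthogroup is absent in the
partner species counts as intervening. Extraction is greedy longest-first:
the longest chain (ties broken by the lexicographically smallest sequence of
rank pairs) is selected, its genes consumed, and the search repeats, so each
gene instance is used at most once per species pair. The per-selection
longest chain is found by dynamic programming over valid successor pairs;
the test suite checks it against exhaustive recursive enumeration of maximal
chains.

Blocks in which a strict majority (> 50%) of members share one orthogroup id
are removed as paralog-composed (tandem-array self-synteny). The threshold
is a strict majority, not ≥ 50%, deliberately: a 2-gene block of two
distinct orthogroups splits 50/50 and must survive for a census of 2-gene
blocks to exist at all.

Block counts are monotone non-increasing in the minimum block length (the
greedy selection order does not depend on it). They are **not** monotone in
the intervening-gene budget: a larger budget can merge two blocks into one
and lower the count. The census therefore reports counts per
(budget, min-length) cell without asserting cross-budget ordering.

## Ultraconserved elements

Per HSP, identity is scored per alignment column with gap columns counting
as mismatches. Windows of 20 columns with identity ≥ 0.95 seed candidate
intervals, each extended rightward one column at a time while the cumulative
identity from the seed start stays ≥ 0.95; overlapping survivors are merged,
flanking mismatch columns trimmed (an element starts and ends on a match),
and intervals shorter than the window or — after a merge — below the
threshold are discarded (a failed merge falls back to its constituent
intervals, kept disjoint). The window length and extension rule are this
package's concretization; only the 95% level is canonical. Column spans are
mapped to both genomes' coordinates skipping gap columns, respecting subject
strand.

Multi-mapping elements (A-spans overlapping ≥ 50% of the shorter span,
single linkage) reduce to the pair with maximal summed length in both
genomes, ties to the lowest coordinate. Elements > 50% covered by CDS are
removed; survivors are intronic if > 50% inside an intron, else non-coding.
Recurrent (repeat-like) elements are single-linkage clusters over
element-vs-element hits covering ≥ 90% of either element.

The planted-element generator flanks each planted 100%-identity segment
with a 3-column forced-mismatch guard. Without guards, background matches
adjacent to an element make its "true" span ill-defined under any
identity-extension rule; with them, the planted span is exactly the interval
the scan reports, making exact-recovery a meaningful test. At background
identity 0.7 a 20-column background window still passes the threshold with
probability ≈ 0.8%, so background scans do produce short spurious elements;
every reported element nonetheless satisfies identity ≥ 0.95 by
construction, and recovery tests score exact planted-span recovery, not
false-positive absence.

## Hi-C insulation and boundary strength

The insulation score of bin *i* is the mean contact in the w×w square
crossing the diagonal at *i* (bins i−w..i−1 × i+1..i+w; the diagonal bin
itself is excluded, Crane-style). The default window is 10 bins (1 Mb at
100 kb bins) and is exposed as a flag — only the bin size, not the window,
is canonical. Scores are log2-normalized by the chromosome mean over defined
bins, making the track invariant to global matrix scaling; bins whose square
is all zeros, and the w bins at each edge, are undefined and skipped (never
zero-filled).

Extrema are called on defined bins with endpoints excluded, plateaus
collapsed to their centre bin, and prominence < 0.1 discarded. Each valley's
boundary delta is the insulation drop to the nearest flanking peak on each
side, aggregated by mean over the existing sides (min available via flag;
the mean is the default where the aggregation rule is ambiguous). Two
delta samples are compared by a two-sided Mann–Whitney U test: exact by the
standard no-tie recursion when tie-free and n·m ≤ 10 000; exact by full
enumeration of pooled assignments when ties are present and C(n+m, n) is
small enough; otherwise the normal approximation with tie and continuity
corrections.

Contact decay reports P(s), the mean contact at bin distance s, and the
log–log slope of P(s) against (1+s) over a stated fit range — matching the
generator's expected contact c·(1+s)^(−α), so a noiseless α=1 map fits
slope −1 exactly. The synthetic generator produces this power law,
optionally multiplied by a TAD enrichment factor for bin pairs inside the
same inter-boundary block, with multiplicative log-normal noise; it does
not emulate A/B compartments, loops, mappability gaps or balancing
artefacts.

## ATAC peak-to-gene distances

Peaks overlapping any repeat or any gene are excluded; the distance is the
minimum gap between a peak edge and the nearest gene edge — transcription
unit start or end, not TSS-only and not midpoints — on the same chromosome.
Abutting peaks (gap 0) count as overlapping, so all distances are ≥ 1.
Outliers are removed by Tukey fences (1.5×IQR beyond the quartiles) with
type-7 (linear interpolation) quantiles, the most common default, as no
quantile rule is canonical. The regression of mean distance on genome size
(sum of chromosome lengths) is ordinary least squares with a t-based 95% CI
on the slope and a pointwise confidence band for the fitted line.

The synthetic peak generator anchors each peak at an exponential offset from
a uniformly chosen gene boundary. Mean-distance fidelity requires intergenic
space much larger than the target mean (otherwise rejection against gene
overlap truncates the exponential); the reference ATAC test condition uses
four species of 50–800 Mb built with 50 kb gene spacing, sizes spaced
linearly. With multiplicative sampling noise, linear size spacing keeps the
OLS slope CI near nominal coverage, whereas strongly geometric spacing makes
the largest genome dominate and the t-interval anti-conservative.

## Problem sizes in the reference checks

The shipped end-to-end checks run: ALG recovery on 10 (tests) or 5 (script)
simulated clades at the default study condition with a 3-point resolution
sweep and 10 runs per consensus; exhaustive-modularity agreement on 50/30
random ≤8-node graphs with 50-run consensus; microsynteny oracle agreement
on 200/60 random genome pairs of ≤60 genes across budgets {0,1,5} and
minimum lengths {2,3,4}; planted-element recovery on 50 HSPs of 2 kb;
boundary-strength discrimination on ten 500-bin map pairs; and slope
recovery over ten 4-species regressions. These sizes keep the full suite in
a few minutes on one CPU while leaving every check statistically
well-powered.

## Known limitations

- The ALG method is tree-free; it cannot separate an ancestral linkage from
  a fusion shared by most sampled lineages.
- Greedy longest-first block extraction is deterministic but not globally
  optimal as a maximum-coverage chain packing; the brute-force oracle
  implements the same greedy contract, not an optimal packing.
- The UCE scan's rightward-extension is asymmetric by construction (seeds
  are left-anchored); merging plus trimming makes the output symmetric in
  practice but a pathological alignment could be reported with a one-column
  left bias relative to a symmetric extension rule.
- Insulation tracks treat gaps of undefined bins as adjacent when calling
  extrema across them; chromosomes with large unmappable blocks should be
  analysed per defined segment.
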