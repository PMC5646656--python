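# Methods

## Scope and data

The package reimplements a karyotype-based phylogeny pipeline for nine
cephalopod species: per-chromosome classification, karyotype summary
statistics, resemblance-near coefficients and evolutionary distances, UPGMA
clustering, and karyo-idiogram rendering.  Three small published tables are
packaged as plain text: the nine-species karyotype summaries (2n, FN,
formula, order-level grouping), the 30-pair measurement table for each of
the three octopods measured in the source study (means ± SE over at least
seven metaphase plates), and the published 9×9 dual matrix with evolutionary
distance De in the lower triangle and resemblance-near coefficient λ in the
upper triangle.  No network access is ever needed.

## Per-chromosome metrics and classification

Arm ratio AR = LA/SA and centromeric index CI = SA/(SA+LA)×100 follow the
standard definitions; CI = 100/(1+AR) holds identically whenever a short arm
exists, and the package enforces it to 1e-9 in tests.  Telocentric pairs are
encoded with SA = 0; their AR is infinite (serialized as the token `inf`)
and CI is 0.

Levan intervals are applied lower-inclusive — [1.0, 1.7) M, [1.7, 3.0) SM,
[3.0, 7.0) ST, [7.0, ∞] T — because the measured table types its AR = 1.70
pair as submetacentric and its AR = 1.00 pairs as metacentric.  On all 90
packaged pairs, classifying the printed AR mean reproduces the printed type
exactly.

Two AR sources are supported.  The default uses the printed per-pair AR mean
when present: that value is a mean of per-plate ratios, which is not the
ratio of the mean arms (the boundary pair has mean arms 1.85/3.14, ratio
1.697, but a printed plate-mean AR of 1.70 — and the published type SM
follows the plate mean).  `ar_source="recomputed"` forces LA/SA of the
stored means; `validate_measurements` flags pairs where the two disagree by
more than max(0.05, 2% of the printed value), or where the printed type
contradicts the printed AR.

The fundamental number is computed as FN = 2·(M+SM) + (ST+T) over diploid
chromosome counts.  Counting subtelocentrics as uniarmed is unconventional
(many authors count ST as biarmed), but it is the only rule that reproduces
all nine published FN values exactly (108, 76, 108, 104, 172, 164, 156, 160,
166), so it is the package's rule.

One published figure is not reproducible: the pooled subtelocentric
proportion recomputes to 102/700 = 14.57% where the source prints 14.5%
(its printed row sums to exactly 100.0, suggesting truncation).  The tests
assert the recomputed value.

## Length profiles, λ kernels and De

Each species' profile is its haploid vector of per-pair total lengths
(SA+LA) sorted descending across all classes (measured tables order within
class, so a global re-sort is required before rank pairing).  Normalization
modes: `none`, `max` (leading value 1) and `sum` (unit total).

Profiles of unequal haploid number (n = 30 vs 46 here) are zero-padded on
the right by default — a chromosome with no counterpart is treated as
maximally dissimilar — with truncation available for sensitivity analysis.

Three λ kernels are provided, all symmetric with range [0, 1] and λ(x,x)=1:

- `hamming` (default): λ = 1 − (1/n)·Σ|aᵢ−bᵢ| on max-normalized profiles —
  the classical fuzzy-nearness form associated with the −ln transform in
  numerical cytotaxonomy;
- `ratio`: mean of per-rank min/max on raw lengths (both-zero ranks
  contribute 1);
- `ruzicka`: Σmin/Σmax on raw lengths (weighted Jaccard).

The distance transform is De = −ln λ, strictly decreasing and exactly
invertible (λ = e^(−De)); the round trip is tested to 1e-12.

The kernel question is deliberately left open.  The λ formula used to
produce the published dual matrix appeared only in supplementary material
that is not part of the published text, and none of the three kernels
reproduces the published λ between the two closest octopods from the raw
measurements (hamming 0.810, ratio 0.829, ruzicka 0.806, versus 0.8184
printed).  The package therefore (a) documents the kernels as pluggable
defaults rather than reverse-engineering the original, and (b) ships the
published matrix verbatim, so all tree-level results are computed from the
published distances and do not depend on the kernel.  A `duality_audit`
checks |De + ln λ| cell by cell (default tolerance 1.6e-3, the level that
separates rounding noise from real inconsistency in 4-decimal tables):
33 of the 36 published pairs satisfy the duality; the three flagged pairs
— (S. lessoniana, P. edulis), (S. lessoniana, H. bleekeri),
(C. chinensis, H. bleekeri) — are mutually inconsistent as printed, most
likely typos, and are excluded from any quantitative claim.  Likewise the
published triangle means (De 0.6742, λ 0.5283) disagree with the means of
the printed cells (0.6850, 0.5175); the recomputed values are the tested
ones.

## UPGMA

Unweighted average linkage: d(C₁∪C₂, X) = (|C₁|·d(C₁,X) + |C₂|·d(C₂,X)) /
(|C₁|+|C₂|), node height = half the merge distance, branch length = height
difference to the parent.  Unweighted (not WPGMA) linkage is required: only
it reproduces the published internal branches 0.1612 and 0.1418 on the
packaged matrix.  Ties in the minimum distance are broken by the
lexicographically smallest (min id, max id) pair, ids numbering leaves in
input order then internal nodes by creation; the packaged matrix has no
ties, so this is a determinism contract only.  The implementation is the
naive O(n³) search, ample for the n ≤ 50 matrices this package targets;
scipy's average linkage and cophenet serve as an independent cross-check in
the tests (identical heights and cophenetic distances to 1e-12 on random
matrices).

Three published subgroup values (0.1429 for the decapod clade, 0.1338 and
0.0073 within it) are not reproduced by UPGMA on the published matrix
(recomputation gives 0.1499, 0.1301, 0.0216) and are treated as errors in
the published text; the reproducible branch values are 0.0249 (above the
closest octopod pair), 0.1612 (their node to the four-octopod ancestor) and
0.1418 (octopod clade to root).  The published text also attaches 0.1612 to
the third octopod's "sister group"; numerically it is the branch above the
three-octopod ancestor (that species' own terminal branch is 0.1256).

Newick export orders children by earliest leaf index, quotes labels
containing spaces, and round-trips through a standard parser with identical
topology and path lengths to 1e-9.  Cophenetic distances (2 × LCA height)
satisfy the ultrametric three-point condition in property tests.

## Idiogram rendering

Columns are laid out per pair: short arm above a common baseline (the
centromere, the diagram's zero point), long arm below, heights proportional
to relative lengths under one global scale; telocentrics have zero upper
extent.  Display order is class-major (M, SM, ST, T), size-descending within
class; totals are rounded to 6 decimals in the sort key so float summation
noise cannot reorder pairs of equal printed length, and the stable sort then
preserves table order.  SVG output is viewBox-based (resolution-independent),
deterministic byte-for-byte, one group element per pair, default blue short
arms / red long arms, and a triangular baseline notch for the centromere
(the exact glyph is a package choice; sources show only "a nick").
Mirrored homolog columns are optional and off by default.

## Synthetic measurement tables

`SyntheticTemplate` specifies pairs per class, a total relative length,
plate count k (default 7, matching careful practice), multiplicative
per-plate noise (default 0.02, i.e. 2% of arm length — SEs in measured
tables roughly scale with arm size), a boundary margin (default 0.05) that
keeps true ARs away from class edges, and a length-decay span (max/min total
length, default 5; measured complements span about 4.3–7.6×).

Generation: true ARs are drawn uniformly inside each class interval shrunk
by the margin (telocentrics get SA = 0 exactly); true totals decay
geometrically and are rescaled; arms follow from (total, AR).  Each plate
measures each arm as truth × (1 + N(0, noise_sd)); reported values are plate
means with SE = sd/√k, and the reported AR is the mean of per-plate ratios
(reproducing the convention of the packaged table).  All randomness flows
through numpy's PCG64, so a seed fully determines the output on any
platform.  With noise_sd = 0 the template is recovered exactly and the
validator reports zero violations.

`simulate_taxa` makes replicate taxa per template by scaling each pair's
true arms by exp(N(0, divergence)) before measurement — a crude stand-in
for length evolution that preserves each pair's class.  What the generator
does **not** emulate: chromosomal rearrangements (fissions/fusions that
change 2n along a lineage), correlated measurement error within a plate,
and non-geometric length distributions; passing recovery tests therefore
demonstrates the pipeline's arithmetic and robustness to measurement noise,
not performance on real evolutionary divergence.

For the clustering-recovery check, the two templates contrast the study's
two complement architectures — 30 pairs at the steep end of the observed
length-decay range versus 46 pairs at the shallow end — because template
separation must exceed the within-template divergence (0.15) for membership
to be recoverable at all; with order-level contrast, UPGMA on hamming-De
recovers the two template groups as the root's children in 97 of 100 seeds.

## Problem sizes and numerical choices

All published-data computations are tiny (90 pairs, a 9×9 matrix) and run in
well under a second.  Simulation-based checks use 200 seeds for formula
recovery and 100 seeds for clustering recovery (6 taxa × 30–46 pairs × 7
plates each), a few seconds in total.  Display rounding is 4 decimals for
λ/De and 2 for arm lengths, matching the published tables; all internal
arithmetic is double precision, with an optional JSON sidecar for lossless
dual-matrix round trips.  Matrix validation tolerances (symmetry 1e-12,
ultrametricity 1e-9) are far below any measurement precision.

## Command-line interface

`summarize`, `distance`, `tree`, `idiogram`, `simulate` and `reproduce` are
thin wrappers over the library; every run is a pure function of its inputs,
flags and seed, and logs go to stderr.  `reproduce` recomputes every
published value the packaged data can support and exits nonzero on any
disagreement; the inconsistent printed values listed above are excluded
from it by design.
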