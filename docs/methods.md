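# Methods

This note records the models and procedures the package implements, the
parameters that matter and where their defaults come from, the numerical
conventions, and what the synthetic data can and cannot show.

## Genome-size categorization

Genome sizes (kb) are smoothed with a plain Gaussian kernel of **fixed**
bandwidth (default 8 kb, evaluated on a 1 kb grid) rather than a
data-driven bandwidth, so that the detected boundaries are deterministic
and insensitive to sample size. Local maxima of the smoothed density are
retained as modes when their peak prominence exceeds 5% of the global
maximum; the global minimum of the density between each pair of adjacent
retained modes is a valley, and the valleys are the category boundaries.
On a trimodal size mixture with components (weight, mode, sd) =
(0.55, 50, 12), (0.33, 130, 20), (0.12, 230, 28) this places the upper
boundary within a few kb of the analytic minimum of the mixture density
(≈183 kb); the fixed 8 kb bandwidth biases the detected valley slightly
toward the sparse jumbo mode (detected ≈185–188 kb at n = 10,000), well
inside the ±10 kb band around the nominal 180 kb boundary. All three
knobs (bandwidth, grid step, prominence fraction) are exposed.

Fewer than 50 sizes are rejected: valley positions estimated from fewer
genomes are too unstable to serve as category boundaries.

## Protein-length statistics

The median uses the *lower* order statistic on even n so that the statistic
stays integer-valued for amino-acid lengths. Skewness is the population
moment coefficient g1 = m₃/m₂^{3/2} without small-sample bias correction;
constant input or n < 3 yields NaN (an "undefined" marker, not an
exception).

For heavy-tailed length distributions the raw g1 estimator is known to be
both biased low and noisy: for the calibrated lognormal below, at
n = 50,000 its sampling mean is ≈6.0 and its sampling SD ≈1.0, so single
samples scatter between roughly 5 and 8.5. The package therefore also
provides a distributional estimate, `fitted_lognormal_skewness`, which
estimates the lognormal shape σ̂ as the SD of log-lengths and converts it
with the closed form γ₁(σ) = (e^{σ²}+2)√(e^{σ²}−1). This estimates the same
population quantity and concentrates rapidly (SD ≈0.04 at n = 50,000); it
is the appropriate instrument for checking generator calibration, while
`length_stats` reports the conventional raw g1 for descriptive use.

## Family clustering

BLASTCLUST-style semantics: an edge between proteins q and s survives when
the best hit for the pair has bit-score density (bits per aligned position)
≥ S and alignment coverage ≥ L on both sequences (`coverage_mode="both"`;
"either" is available). Score density is used uniformly as bits/position.
Families are connected components of the surviving graph; singletons are
retained as one-member families, and the family id is the
lexicographically smallest member id, making the partition deterministic.
Defaults L = 0.6, S = 1.0 are free parameters exposed in the configuration;
the thresholds used for any given clustering round of a real dataset are a
user choice. Raising S or L can only refine the partition (tested
property). Dereplication ("purging of nearly identical sequences") is the
same machinery run at a percent-identity threshold with the longest member
kept as representative.

## Phyletic-pattern classification

Canberra distance with the 0/0-term-contributes-0 convention (the standard
statistical-computing resolution of the otherwise indeterminate term; on
the binary matrices of this pipeline, distance = number of families present
in exactly one of the two phages). The families × phages matrix is
restricted to families present in at least `min_phages` genomes (default
5) — the "wide representation" filter — before distances are computed on
either axis.

Agglomeration is implemented directly through the Lance–Williams
recurrence with Ward coefficients αᵢ = (nᵢ+nₖ)/(nᵢ+nⱼ+nₖ),
β = −nₖ/(nᵢ+nⱼ+nₖ), γ = 0. Two variants are provided because statistical
environments disagree on which "Ward" they implement: `ward_d2` (default)
applies the recurrence to squared distances and reports heights on the
original scale, matching the textbook minimum-increase-in-sum-of-squares
criterion when the input is Euclidean; `ward_d` applies it to raw
distances. Exact ties on the merge criterion are broken by the smallest
(cluster-a, cluster-b) index pair, giving platform-stable dendrograms.
Structure-similarity Z-score matrices are converted to distances as
max(z) − z with a forced zero diagonal and clustered by UPGMA with the same
machinery. Cutting a tree at k removes the k−1 highest merges; labels are
numbered by first leaf appearance so they are invariant to input order.

## Ordination

PCA scales each family variable by its population SD (ddof 0) after
centering — "unit variance" is under-specified and this choice is
documented rather than important. Constant variables (families present
everywhere or nowhere after filtering) carry no signal and are dropped with
a record, not an error, since binary matrices routinely contain them.
Eigenvector signs are fixed by making the largest-magnitude loading of each
component positive. Explained fractions are eigenvalues over the total
variance of the kept variables, so they sum to exactly 1 over all
components. Convex hulls use the monotone chain with strict turns
(collinear boundary points excluded); degenerate inputs return the natural
objects (a point, a segment).

## Gene neighborhoods

Gap convention: gap = start(next) − end(prev) − 1 under 1-based inclusive
coordinates, so adjacent genes have gap 0; overlapping genes (common in
operons) are clamped to gap 0. Around each anchor-family gene the window
(default 5 genes each side) is trimmed to the maximal run whose
consecutive gaps are ≤ 50 nt and, by default, whose strands match the
anchor — i.e. directionality is required of the anchor-containing run, not
of the whole window; the alternative (require it of all window genes) would
only shrink runs further. Signatures are ordered family tuples,
strand-normalized so the anchor reads left-to-right; reversing an entire
genome therefore leaves reported signatures unchanged (tested property). A
signature is conserved when ≥ 2 genes long and present in ≥ 2 distinct
taxa; the literal taxon "unknown" never counts toward that filter. For
phage cohorts the host phylum is the natural surrogate for the
more-than-one-phylum rule, and the taxon label's granularity is the
caller's choice.

## Synthetic cohort generator

The generator's defaults are the study conditions; they were fixed once
from the statistics the survey domain reports and are not tuning knobs:

| quantity | default | provenance |
|---|---|---|
| size mixture (w, mode, sd) | small (0.55, 50, 12); medium (0.33, 130, 20); jumbo (0.12, 230, 28) kb | small/jumbo modes observed; medium mode and the weights are free choices shaped to the reported relative abundances |
| coding density | Normal(1.5, 0.25) per kb | observed |
| protein lengths | lognormal, median 151 aa (jumbo) / 127 aa (non-jumbo), σ = 1.01806 | medians observed; σ solves (e^{σ²}+2)√(e^{σ²}−1) = 6.5, the center of the observed 6.4–6.8 skewness window |
| marker complements | per-subgroup family sets (multisubunit RNAP, divergent PolB/DnaB, PhiKZ-type MCP, tubulin, … for group 1; classic PolB, OB-fold SSB, UvsW, sigma factor, gp23 MCP, … for group 2; T7-type Pol vs PolIII-α defining subgroups 3.1/3.2) plus universal families (terminase, SbcC/SbcD, lysozyme) and a myovirus-only tail-sheath family | the groups' described gene complements |
| gain/loss noise ε | 0.05 marker flip probability | free choice: small enough that complements stay recognizable, large enough that patterns are patchy |
| background families | 120 families, presence probability 0.15 each | free choice emulating the patchy, group-uncorrelated fraction of families |
| tRNA counts | Poisson with means 4.5 / 7.1 / 18 / 22 per subgroup | observed; subgroup 3.2 (unreported) set to 12, between its neighbors |
| intergenic gaps | geometric, mean 100 nt | free choice in the typical prokaryotic range |

Randomness is hierarchical: one global seed spawns an independent stream
per phage index, so enlarging a cohort never perturbs earlier genomes
(tested property).

Layout: genes are placed left-to-right with geometric gaps. Nominal gene
footprints are 3 bp per aa, but because the length distribution is heavy
tailed this nominal extent can exceed the drawn genome length at density
1.5 genes/kb; footprints are then rescaled proportionally (minimum 30 bp)
to fit. Gene *content* statistics — density, sizes, protein lengths, family
complements — are unaffected by this approximation; only physical gene
extents are. Planted cassettes are placed by re-coordinating an interior
run of genes to exact intergenic gaps on the requested strand, isolated
from flanking genes by a 200 nt margin, and genomes remember planted gene
ids so successive plants never overwrite each other.

What the generator does **not** emulate: actual sequences (no nucleotide or
amino-acid strings), phylogeny-aware gain/loss (marker flips are i.i.d.,
so there is no within-subgroup tree structure), correlated background
families, horizontal exchange between groups, and genome rearrangement.
Passing tests therefore demonstrate that the pipeline's statistics and
clustering recover planted structure of the stated magnitudes under
realistic noise — not that any real phage collection has that structure.

## Problem sizes

The test suite and the analysis scripts run cohorts of 30–200 genomes
(the default analysis cohort is 40 phages per subgroup, matching the scale
of a curated jumbo-phage collection), 10,000 draws for size-distribution
work, and 50,000 draws for length-calibration checks; these sizes give
sampling errors comfortably below the tolerances being checked while
keeping any single analysis under a couple of minutes on one CPU.

## Known limitations

* Valley positions inherit an O(bandwidth) bias toward sparse modes; the
  default bandwidth is part of the reported category model and should be
  stated alongside any cutoff.
* `ward_d` heights are not guaranteed monotone for arbitrary dissimilarity
  input (a known property of that variant); `ward_d2` heights are.
* The PCA variance-explained of a synthetic cohort is not comparable to
  that of a curated real matrix: orphan-free curated matrices concentrate
  variance in far fewer components than matrices containing i.i.d.
  background families.
* Circular genomes are handled only as linear sequences; origin-spanning
  genes are rejected at parse time rather than wrapped.
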