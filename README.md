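# jumbophage

Comparative genomics of **jumbo phages** — tailed bacteriophages
(*Caudovirales*) whose genomes exceed the ~180 kb boundary that separates
them from small and medium-sized phages. The package implements, as a
tested and reusable pipeline, the quantitative analyses such a survey rests
on:

* **Objective genome-size categorization.** Instead of an arbitrary 200 kb
  cutoff, genome sizes are smoothed with a Gaussian kernel and category
  boundaries are placed at the *valleys* of the resulting trimodal density
  (modes near 50, 130 and 230 kb). The upper valley, near 180 kb, defines
  the jumbo category.
* **Protein families by single-linkage clustering.** Pairwise alignment
  hits are filtered by alignment coverage *L* and bit-score density *S*
  (bits per aligned position); families are the connected components of the
  surviving similarity graph.
* **Phyletic-pattern classification.** The binary families × phages
  presence/absence matrix is the central object. Distances between phage
  (or family) profile vectors use the Canberra distance,
  d(p, q) = Σᵢ |pᵢ − qᵢ| / (|pᵢ| + |qᵢ|),
  which for 0/1 vectors counts the coordinates present in exactly one of
  the two. Dendrograms come from Ward's minimum-variance agglomeration;
  ordination uses PCA with variables scaled to unit variance, with convex
  hulls bounding groups in score space. Structure-similarity Z-score
  matrices are clustered by average linkage (UPGMA).
* **Conserved gene neighborhoods.** Around each occurrence of an anchor
  family, flanking genes are trimmed to the maximal run with intergenic
  gaps ≤ 50 nt and consistent directionality; a neighborhood counts as
  conserved when the same ordered family signature recurs in more than one
  host phylum.
* **A calibrated synthetic cohort generator** that emulates the statistical
  structure of a real phage collection — trimodal sizes, coding density
  Normal(1.5, 0.25) per kb, right-skewed lognormal protein lengths (medians
  151 aa jumbo / 127 aa otherwise, moment skewness 6.5), three phage
  groups in five subgroups defined by marker-family complements with
  gain/loss noise, subgroup-specific tRNA counts, and planted gene
  neighborhoods — so every stage is testable without external data.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
200-genome cohort (40 phages in each of the five subgroups, seed 1):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_genome_stats.py
python analysis/03_protein_families.py
python analysis/04_phyletic_classification.py
python analysis/05_ordination.py
python analysis/06_gene_neighborhoods.py
```

Output of the chain (abridged):

```
coding density: mean 1.517 / sd 0.251 per kb
size model: modes [50.0, 130.0, 228.0] kb, cutoffs [88.0, 186.0] kb (3 categories)
protein lengths [jumbo]: n=6641 median=147 aa raw skew=5.69 fitted skew=6.45
jumbo vs non-jumbo lengths: Kruskal-Wallis H=113.9, p < 2.2e-16
proteome ~ genome size: slope 1.48 proteins/kb, r2 = 0.929
211236 hits -> 207095 filtered edges -> 22274 families (165 with >= 2 members)
family partition vs ground truth: ARI = 1.0000
matrix: 158 widely represented families x 200 phages
phage dendrogram cut k=3: ARI vs planted groups = 1.000
phage dendrogram cut k=5: ARI vs planted subgroups = 1.000
3 planted signatures, 3 reported; recall = 1.00, precision = 1.00
```

Reading the numbers: the per-genome coding density recovers the generator's
Normal(1.5, 0.25); valley detection places the upper category boundary at
186 kb, close to the analytic minimum of the size mixture (183 kb); the
Canberra + Ward classification of phyletic patterns recovers the three
planted groups and five subgroups exactly (Adjusted Rand Index 1.0); and
the neighborhood filters report all planted cassettes and nothing else.
Each script writes its tables under `results/`.

The same stages are available as subcommands of the `jumbophage` console
script (`simulate`, `stats`, `families`, `matrix`, `cluster`, `pca`,
`neighborhoods`, `run`) for use on real gene tables, GenBank files and
BLAST-style hit tables; see `jumbophage --help`.

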