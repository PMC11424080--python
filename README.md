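# stagediv

Analysis pipeline linking **gene duplication** to **divergent temporal
gene-expression patterns** across a complex life cycle (larva → pupa →
adult).  Organisms with complex life cycles express very different
phenotypes from one genome; that requires expression to be decoupled
between stages, and gene duplication is a leading mechanism for such
decoupling.  `stagediv` quantifies this link in bulk RNA-seq data from a
staged developmental design (e.g. five stages × two host plants × five
replicates in a holometabolous insect), and ships a synthetic-data
generator so the whole pipeline can be exercised and validated without any
external download.

## What it computes

Given a gene × sample TPM matrix, sample metadata (stage, host,
replicate), an all-vs-all protein-alignment hit table and per-group gene
trees:

1. **Homologous groups** — hits passing identity/coverage/E-value
   thresholds (strict: ≥30 % identity over ≥90 % of the target, E ≤ 1e-10;
   lenient: ≥20 %, ≥70 %, E ≤ 1e-5) become edges; connected components of
   size ≥ 2 are groups of *duplicate genes*, the rest are *singletons*.
2. **Expression profiles** — TPM → ln(x + 1) → per-stage medians (hosts
   and replicates pooled) → per-gene standardization to mean 0, sd 1
   across stages (denominator S − 1).
3. **Divergence (Mantel)** — per group, the patristic distance matrix
   d(i,j) = Σ branch lengths on the i→j path is correlated with the
   Euclidean distance matrix between standardized profiles;
   r = Pearson over the n(n−1)/2 pairs, p from 999 joint row/column
   permutations.  Across groups: one-sample t-test of the r distribution
   against 0 and the fraction of groups with r > 0.
4. **Diversity scaling** — per group, phylogenetic diversity D = Σ lᵢ of
   the gene tree vs expression-pattern diversity, the total branch length
   of the Ward dendrogram of its profiles (leaves at height 0); across
   groups, Spearman ρ, a linear-vs-quadratic SSE comparison, and per-size
   stratification.
5. **Stage specificity (τ)** — τ = Σᵢ(1 − xᵢ)/(N − 1) with
   xᵢ = vᵢ/max(v), computed on log stage medians; τ = 0 means uniform
   expression, τ = 1 single-stage expression.  Duplicates vs singletons
   compared by a two-sample Kolmogorov–Smirnov test.
6. **Whole-transcriptome stage divergence** — Manhattan distances between
   samples on raw TPM; one- and two-factor (stage + host) PERMANOVA with
   sequential sums of squares and 999 label permutations; pairwise
   adjacent-stage and larva-vs-adult contrasts with centroid L1 distances.

The synthetic generator builds Yule gene trees, evolves log-expression
profiles along them by Brownian motion (child = parent + N(0, σ²·l) per
stage), adds a one-hot stage boost to duplicates, samples replicate TPM as
exp(profile + noise), and derives a hit table from patristic distances —
so every downstream statistic has a known ground truth.

## Worked example

```sh
stagediv --seed 1 simulate --outdir demo/bundle --n-groups 100 --n-singletons 300
stagediv --seed 1 all --indir demo/bundle --outdir demo/results
```

prints

```
wrote synthetic bundle to demo/bundle (851 genes x 50 samples)
groups: 100  mean Mantel r: 0.4221  shift p: 3.9e-19
diversity Spearman rho: 0.6834 (p = 4.7e-15)
tau KS D: 0.9861 (p = 2.23e-308)
stage PERMANOVA F: 97.16 (p = 0.001)
```

Reading the output: the 100 simulated gene families are recovered exactly
from the hit table; within them, expression distance rises with
phylogenetic distance (mean Mantel r = 0.42, strongly shifted above 0);
more phylogenetically diverse families show more diverse expression
patterns (ρ = 0.68); duplicates are far more stage-specific than
singletons (KS D = 0.99 — the simulated boost is deliberately strong); and
expression varies massively by stage (pseudo-F = 97.2 at the minimum
permutation p of 0.001) but not by host plant (F = 0.84, p = 0.50), as
designed.  Full tables (per-group Mantel results, diversity pairs, τ per
gene, PERMANOVA and pairwise-stage tables) are written under
`demo/results/`.

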