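# Methods

## Scope and data model

`stagediv` analyses a staged bulk RNA-seq design: a gene × sample matrix
of TPM values with per-sample metadata (ordered developmental stage, host
plant, replicate), an all-vs-all protein-alignment hit table, and one
branch-length gene tree per homologous group.  Trees are consumed, never
inferred — alignment and maximum-likelihood inference are upstream of this
package, and the synthetic generator stands in for them during testing.
The stage order is always declared explicitly (config or CLI); it is never
inferred from a string sort, and at most falls back to first appearance in
the metadata file.

## Preprocessing

TPM values are transformed as ln(x + c) with pseudocount c = 1
(configurable).  Natural log with c = 1 maps TPM 0 to exactly 0, which
matters because genes silent in a stage (e.g. the non-feeding pupal
stage) are common and τ requires non-negative input.  Per-gene stage
profiles are the medians over all samples of a stage, pooling hosts and
replicates; hosts are pooled because the two-factor PERMANOVA provides the
host test separately and the default synthetic design has no host effect.
Standardized profiles use z = (m − mean)/sd with the sample standard
deviation (denominator S − 1); rows with zero across-stage variance cannot
be scaled and are dropped and reported, not silently discarded.

Note the median is taken on the log scale: for stages with an even number
of replicates this is the mean of the two middle log values, which differs
from the log of the TPM median.  All examples and tests follow the
log-scale convention.

## Homology

A gene pair is an edge when percent identity ≥ min_pident, alignment
length / target length ≥ min_target_coverage and E-value ≤ max_evalue
(all boundaries inclusive; "E-value of at least 1e-10" is read in the
standard significance direction, E ≤ 1e-10).  Coverage is measured
against the target sequence; the strict preset's 0.90 quantifies "across
the length of the target" and is configurable since no exact fraction is
canonical.  Groups are connected components (via networkx) of size ≥ 2,
ordered deterministically by smallest member id; everything else is a
singleton.  Loosening any threshold can only add edges, so groups can
only grow — a property the tests exercise.

## Statistics

* **Mantel test** (authored here; scikit-bio's implementation is used
  only as an independent cross-check in tests).  r is the Pearson
  correlation over the condensed upper triangles; the null permutes rows
  and columns of one matrix jointly; p = (#{r_perm ≥ r_obs} + 1)/(B + 1)
  with B = 999, one-sided "greater" by default since the scientific
  hypothesis is a positive association.  Groups with n < 3 usable genes
  (including all size-2 groups, which carry a single distance pair) are
  skipped with reason `too_small`; zero-variance triangles with
  `zero_variance`.  Each group receives an independent child seed from a
  spawned `SeedSequence`, so results do not depend on iteration order.
* **Shift test**: one-sample t-test of the Mantel coefficients against 0
  (df = n − 1), default alternative "greater"; the positive fraction is
  reported both over tested groups and over all groups (the denominator
  including skipped groups is ambiguous in general, so both are given).
* **Ward clustering** (authored here).  Lance–Williams recurrence on
  squared Euclidean distances with merge heights reported on the distance
  scale (the `ward.D2` convention), matching Euclidean-standardized
  profiles; the historical variant that applies the recurrence to
  unsquared dissimilarities is available as `variant="d"`.  Ties break on
  the smallest leaf index, making merges deterministic.  The O(n³) sweep
  is ample for gene-family sizes.  Dendrogram diversity treats leaves as
  height 0 and sums (parent height − child height) over all edges — the
  natural "sum of branch lengths" reading of a clustering tree.
* **Diversity comparison**: Spearman ρ with mid-ranks (scipy), OLS SSE
  comparison of y ~ x vs y ~ x + x² (the quadratic is nested, so
  SSE_quad ≤ SSE_lin always; the precondition is ≥ 3 distinct x, the
  minimum for a quadratic fit), and per-size stratification reported only
  for sizes with at least 5 groups (configurable).
* **τ**: Σ(1 − xᵢ)/(N − 1) on log stage medians; all-zero vectors are
  excluded with reason `no_expression`.  τ is scale-invariant and
  monotone under concentration of expression onto the maximal stage
  (property-tested).
* **KS test**: two-sided, asymptotic p (scipy `ks_2samp`,
  `method="asymp"`), with the D statistic verified in tests against a
  brute-force ECDF sweep.
* **PERMANOVA** (authored here).  One-factor uses the direct partition
  SS_total = (1/n)Σ_{i<j}d²ᵢⱼ, SS_within = Σ_g (1/n_g)Σ_{i<j∈g}d²ᵢⱼ,
  pseudo-F = (SS_between/(k−1))/(SS_within/(n−k)); two-factor uses
  sequential (type-I) sums of squares via the Gower-centered matrix and
  hat-matrix projections, each term tested against the full-model
  residual mean square.  Both use free permutation of sample identities,
  999 by default, p on the (B+1)-grid.  A degenerate SS_within = 0 yields
  pseudo-F = +inf with a still-valid permutation p.  PERMANOVA runs on
  raw TPM (magnitudes are the point of the Manhattan metric); pairwise
  stage contrasts additionally report the Manhattan distance between the
  two per-stage mean TPM vectors (`centroid_L1_distance`) as the headline
  distance, with the between-group SS also emitted since either reading
  of a "pairwise distance" may be wanted.  No multiple-testing correction
  is applied to the pairwise table by default.

## Synthetic data

The generator emulates the target study design: 5 stages × 2 hosts × 5
replicates (50 samples), 100 homologous groups with sizes uniform on
3–8, 300 singletons.  Per group, a pure-birth (Yule) tree with split rate
λ = 1 supplies branch lengths (waiting times Exponential(kλ); ultrametric
tips); per-stage root log-expression is base 3.0 (≈ 20 TPM) plus
N(0, root_profile_sd²) with sd 1.0, giving genuine stage structure; log
profiles evolve along the tree by Brownian motion with rate σ² = 0.5 per
unit branch length; duplicates receive a one-hot stage boost of 1.0 on a
random stage; observed TPM is exp(profile + N(0, 0.3²)) per replicate.
Host effects default to 0 (a `host_effect_sd` knob exists for power
studies).  The hit table maps patristic distance d to
pident = 20 + 80·e^(−0.2d), full target coverage, and
evalue = 10^(−50·e^(−0.2d)) — arbitrary monotone conventions, not
biology, chosen so the default thresholds reconstruct the true partition.
All draws flow from one seeded generator and regeneration is
byte-identical.

What the generator does *not* emulate: compositional coupling between
genes (TPM rows are generated independently, real TPM is a simplex),
count-level sampling noise (no length/library-size model), correlated
expression across stages beyond the root profile, paralog-specific rate
variation, and real tree shapes (pure-birth only).  Passing tests
therefore demonstrate that the statistics recover the structure they
claim to measure under a clean generative model — not that any particular
biological dataset will show that structure.

## Numerical choices and edge cases

Distance matrices are validated (symmetry 1e-8, zero diagonal, finite,
non-negative) and symmetrized exactly on construction.  Ward heights are
clipped to be monotone (the criterion is monotone analytically; clipping
only absorbs last-digit float noise).  Permutation p-values always
include the identity term (+1 in numerator and denominator) and therefore
never return 0.  Standardized-profile rows are asserted to mean 0 / sd 1
within 1e-9.  Mantel and pairwise-PERMANOVA seeds are spawned per
group/pair from the parent seed.

## Test design

Every statistic is checked against an independent oracle: exhaustive
permutation nulls (24 relabelings for Mantel at n = 4; 720 for PERMANOVA
at n = 6), brute-force path sums over the explicit edge graph for
patristic distances, a transitive-closure oracle for components, an ECDF
sweep for KS, scipy's Ward linkage via cophenetic matrices, and frozen
values from an independent sequential-SS PERMANOVA implementation for the
two-factor toy.  Parameter recovery runs the full default design at a
fixed seed; the null calibration re-runs all four tests over 200 seeds on
a scaled-down null design (40 size-matched groups of 4, 80 singletons,
σ² = 0, boost 0, stage-flat roots) and requires each rejection rate at
α = 0.05 to fall in the binomial 99% band.  The null uses size-matched
groups because both diversity statistics grow mechanically with member
count; with mixed sizes their correlation is real but purely
combinatorial, which is exactly the confound the size-stratified analysis
exists to address.

## Known limitations

Two-factor PERMANOVA assumes an additive model (no interaction term).
The asymptotic KS p is approximate for small samples.  The Mantel test
inherits the usual caveats on non-independence of distance pairs; no
phylogenetically independent contrasts or partial Mantel variants are
provided.  Transcript-to-gene collapse is not applied by default — each
target id is one analysis unit — since no single collapse rule is
canonical; `core_io.collapse_transcripts` sums TPM over a user-supplied
transcript→gene mapping when collapse is wanted.
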