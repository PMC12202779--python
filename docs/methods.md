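# Methods

## Problem and model

The package analyses trophic-niche differentiation among sympatric consumer
species from diet DNA-metabarcoding data: an OTU-by-sample count table of
plant (rbcL-style) amplicons from fecal samples, OTU taxonomic lineages, and
a sample-to-consumer mapping. All statistics operate on relative-abundance
diet profiles `p_g` built per consumer species at a taxonomic rank.

**Levins niche breadth.** `B = 1 / Σ_j P_j²`, where `P_j` is the proportion
of food item `j` in a species' diet. `B` ranges from 1 (complete
specialisation) to `n` (uniform use of `n` items). A variant of this formula
sometimes appears in print as a bare sum of proportions; that form is
identically 1 for any probability vector and cannot measure breadth, so the
package implements the standard inverse-Simpson form (Levins' measure, as
used by Hurlbert). Hurlbert's standardised breadth
`B_std = (B − 1)/(n − 1)` is reported alongside `B` because raw breadths at
ranks with different taxon counts are not comparable; for a single-taxon
axis `B_std` is reported as 0 (no scope for generalism).

**Pianka overlap.** `O_jk = Σ_i p_ij p_ik / √(Σ_i p_ij² Σ_i p_ik²)` on the
union of the two species' taxa with zero imputation (the index needs a
common resource axis). `O` is symmetric and lies in [0, 1] by
Cauchy–Schwarz. Interpretation follows Krebs' bands with strict
inequalities: `O > 0.3` significant overlap, `O > 0.6` highly significant.

**Diet profiles.** Default mode is *pooled* (sum a species' reads, then
normalise), matching composition computed over a species' pooled sequences;
*mean-of-proportions* (normalise each sample, then average) is available
because the two differ when read depths vary, and weights samples equally
rather than reads. Taxa without an assignment at the working rank are pooled
into an `Unassigned_<rank>` row during aggregation (conserving column sums)
but excluded from diet profiles by default, since composition is reported
over identified taxa.

## Screening

Raw OTU tables from fecal metabarcoding are dominated by non-diet sequences
(host, fungal, bacterial, unassignable). The plant screen retains OTUs whose
class-rank assignment falls in a configurable Viridiplantae class whitelist
(default: Magnoliopsida, Liliopsida, Bryopsida, Polypodiopsida, Pinopsida,
Ginkgoopsida). This is a reproducible proxy for the manual curation such
studies apply; there is no way to encode a curator's judgement exactly. A
separate abundance screen (default: within-sample relative abundance ≥ 1%
in ≥ 1 sample) generalises the common 1% reporting threshold and is applied
only on request.

## Diversity

Alpha metrics: observed features; bias-corrected Chao1
`S_obs + F1(F1−1)/(2(F2+1))` (robust when no doubletons; the classic
`F1²/2F2` by flag); Shannon in log base 2 (bits — a common amplicon-pipeline
default; natural log by flag); Gini–Simpson `1 − Σp²`. Values are delegated
to scikit-bio and cross-checked against hand formulas in the tests. Group
comparison uses Kruskal–Wallis with tie correction and the chi-square
approximation — the standard nonparametric choice for diversity indices
across ≥ 2 independent groups.

Rarefaction subsamples without replacement (multivariate hypergeometric);
curves report mean observed richness over replicate subsamples (default 10)
per depth. Beta diversity: Bray–Curtis on counts `Σ|x−y|/Σ(x+y)`, Jaccard on
presence/absence, and unweighted UniFrac (unique over total branch length,
via scikit-bio) given a tree over the OTUs.

## Ordination

**PCoA** is classical metric scaling: eigendecompose `−½ J D² J` with `J`
the centring matrix; coordinates are eigenvectors scaled by the square root
of positive eigenvalues. Negative eigenvalues (non-Euclidean input) are
reported and their axes dropped; proportion explained uses positive
eigenvalues only. Eigenvalues below `max|λ|·1e-12` are treated as zero.

**NMDS** minimises Kruskal stress-1
`√(Σ(d − d̂)² / Σd²)` by alternating (a) a pool-adjacent-violators isotonic
fit of configuration distances on the fixed dissimilarity ranks (disparities
rescaled to the current distance scale) with (b) a Guttman/SMACOF
configuration update. An update is accepted only while stress decreases, so
the per-run stress history is non-increasing by construction; runs stop when
the decrease falls below 1e-7 or after 300 iterations, and non-convergence
is flagged on the result rather than raised. Default k = 2 with the PCoA
configuration as the first start and seeded jittered restarts after it
(drivers use 8–20 restarts); the lowest-stress run wins. Because only
dissimilarity ranks enter the fit, stress is invariant under strictly
monotone transforms of the input.

## PERMANOVA

One-way PERMANOVA from the distance matrix alone:
`SS_total = Σ_{i<j} d²_ij / N`, `SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij`,
`pseudo-F = (SS_among/(g−1)) / (SS_within/(N−g))`. Significance by permuting
group labels with a seeded generator; `p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1)`
(ties counted with ≥ under a 1e-12 tolerance). When `n_perm` reaches the
number of distinct label orderings the test switches to exhaustive
enumeration (identity included), giving the exact permutation p. Pairwise
contrasts run on the restricted submatrices with per-pair child seeds split
from the master seed; multiplicity is adjusted with Benjamini–Hochberg.
Storey's q-value method is a natural alternative for such contrasts, but its
π₀ estimate is unstable on three p-values, so BH is used and labelled as
such in the output.

## Differential taxa

A deliberately simplified LEfSe-style screen: per taxon, Kruskal–Wallis on
within-sample relative abundances across groups at `alpha = 0.05`; for
survivors, the effect size is the log10 difference between the highest and
lowest group mean abundance on the counts-per-million scale, thresholded at
2.0 to mirror the conventional LDA-score cutoff. With taxa scored one at a
time the one-dimensional linear-discriminant axis coincides with the
abundance feature itself, so the projection step reduces away. Omitted
relative to the full LEfSe tool: the per-class Wilcoxon sub-test and the
bootstrap-averaged LDA; consequently effect sizes are comparable in scale
but not identical to LEfSe's. The screen controls the per-comparison error
rate at alpha under the null (verified by label-permutation simulation), not
an FDR.

## Synthetic data generator

The generator emulates a three-species fecal metabarcoding study:

- **Taxonomy**: a balanced product hierarchy, by default 3 classes × 3
  orders × 2 families × 2 genera × 2 OTUs = 72 plant OTUs, plus 356
  contaminant OTUs (unassigned or non-plant classes) for 428 raw OTUs —
  the scale at which most raw OTUs are screened away in real surveys. A
  balanced design cannot reproduce the ragged per-rank counts of a real
  flora; it preserves the nesting that matters for rank aggregation.
- **Diet profiles**: `p_g = α_g q + (1 − α_g) r_g` with `q` a shared base
  distribution over all plant OTUs and `r_g` private distributions on
  disjoint OTU blocks, both symmetric-Dirichlet draws (concentration 0.5,
  giving realistically uneven diets). `α` controls overlap monotonically:
  α = 0 gives disjoint diets (O = 0), α = 1 identical diets (O = 1). The
  default α = 0.4 was fixed by mapping α to mean true genus-level overlap
  over seeds (≈ 0.39, range ≈ 0.29–0.46), the regime reported for real
  sympatric detritivores.
- **Counts**: per sample, depth ~ lognormal (median `mean_depth`, log-sd
  0.3; study scale 1e5, quick default 5,000); contaminant reads ~
  Binomial(depth, 0.1) spread over contaminant OTUs with a shared Dirichlet
  profile; plant reads ~ Multinomial with composition ~ Dirichlet(θ·p_g),
  θ = 50 by default — substantial between-individual diet variation.
- **Truth**: exact `p_g` aggregated to each rank through the same rank
  membership used for counts, with true B and O computed by the niche
  module on those exact vectors. Truth is defined at OTU level and
  aggregated upward so rank-level truths are mutually consistent.

All randomness flows from one master seed via `SeedSequence.spawn`; every
output (including written files) is byte-reproducible.

What the generator does **not** emulate: primer/PCR amplification bias,
chimeras, taxonomy misassignment, sequencing error, phylogenetic signal in
diet choice (the tree is an independent random coalescent), or correlation
between contaminant load and sample condition. Passing recovery tests
therefore show the estimation chain is correct under
Dirichlet-multinomial sampling, not that field data meet those assumptions.

## Recovery behaviour and problem sizes

With 3 × 18 samples at θ = 50, a single dataset's genus-level breadth
estimate carries ≈ 10–15% stochastic relative error — the delta method gives
`var(Σp̂²) ≈ 4 Σp³ / ((θ+1)·n_samples)`, dominated by between-sample
overdispersion, not read depth. Recovery is therefore assessed across
seeds: at depth 1e5 the 10-seed mean absolute error of genus-level overlap
is ≈ 0.02 and the mean relative error of breadth ≈ 4%, and estimates at
depth 1e3 are strictly worse on average than at 1e5. The test suite and the
acceptance script use desk-scale problem sizes (depth 5,000 for unit tests,
1e5 for the study-scale runs; 500 null datasets × 199 permutations for
calibration; 100 spiked simulations for power), which complete in seconds
while leaving the statistical conclusions unchanged.

## Numerical choices

- Overlap values are clipped to [0, 1] against float drift past the
  Cauchy–Schwarz bound before banding.
- Aggregation uses first-appearance taxon order; all outputs are written
  with fixed float formatting so runs are byte-comparable.
- PERMANOVA compares permuted F to observed F with a 1e-12 tolerance so
  exact ties (e.g., partition-preserving permutations) count toward p.
- Degenerate inputs fail loudly with typed errors: empty profiles, all-zero
  samples, groups below the inferential minimum, rarefaction beyond depth.

## Known limitations

- The plant whitelist is a proxy for manual curation; OTUs assigned only
  below class rank are treated as non-plant.
- Bray–Curtis is not a metric (triangle inequality can fail); it is still
  the field's default abundance dissimilarity and is used as the primary
  distance for ordination and PERMANOVA.
- The differential screen is not LEfSe; effect sizes agree in convention
  (log10 scale on counts-per-million) but not in exact value.
- Weighted UniFrac, Faith's PD, Schoener/Morisita overlap, and null-model
  overlap testing are out of scope.
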