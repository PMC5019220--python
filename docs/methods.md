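# Methods

This note records the models implemented in hv2pop, the estimators and
conventions chosen where several are in common use, and what the
synthetic data generator does and does not emulate.

## Data model and conventions

The unit of analysis is an equal-length nucleotide alignment over
`{A,C,G,T,N,-}` with unique sample ids, a sample→population map, and
optionally per-population longitude/latitude.  Externally, coordinates are
1-based inclusive rCRS positions; internally sites are 0-based.  Region
extraction is inclusive on both ends (`extract_region(48, 342)` yields
342 − 48 + 1 = 295 columns).  Control-region fragment lengths are taken
from the data, never recomputed from printed position ranges, because
published descriptions of the HV2 window are not always internally
consistent at the one-position level.

Haplotype identity is exact string match after upper-casing; `N` is a
fifth state, so sequences differing only by an ambiguous base are kept as
distinct haplotypes.  This is stricter than the ambiguity handling of
some desktop packages but is deterministic and order-independent.  A site
is polymorphic if it carries ≥ 2 distinct A/C/G/T states; gaps and N
neither create nor destroy polymorphism.  Pairwise comparisons use
pairwise complete deletion: site pairs with a non-ACGT base in either
sequence are ignored for that pair.

## Diversity and neutrality

* Haplotype diversity: Nei's unbiased estimator
  h = n(1 − Σ p_i²)/(n − 1).
* k is the mean of raw (uncorrected) pairwise differences; π divides each
  pair by its comparable length and averages.  The K2P correction is
  deliberately *not* applied here — corrected distances enter only in
  differentiation — so diversity tables remain comparable with standard
  control-region reports.
* Tajima's D uses the standard a₁…e₂ constants.  The default p-value is
  two-sided and empirical: 10,000 neutral coalescent genealogies are
  simulated conditional on the sample size, exactly s mutations are
  dropped uniformly on each genealogy (branch-length weighted), and the
  observed D is located in the resulting null distribution with the
  (count + 1)/(N + 1) convention on both tails.  Conditioning on s rather
  than θ avoids having to estimate θ for the null and mirrors common
  practice in permutation-based packages.  Tajima's beta-distribution
  approximation is available as `method="beta"`; for very small n (≈ 4)
  the two can differ noticeably, which is expected — the beta density is
  an asymptotic device.  The simulated null is vectorised across
  replicates, so even n = 141 with 10,000 replicates takes ~2 s.

## Sudden-expansion model

For an instantaneous change θ₀ → θ₁ at τ mutational units before present,
the probability that a random pair differs at j sites is

    F_j = Fhat_j(θ₁) + e^{−τ(θ₁+1)/θ₁} Σ_{i≤j} τ^{j−i}/(j−i)! (Fhat_i(θ₀) − Fhat_i(θ₁)),

with Fhat_j(θ) = θ^j/(1+θ)^{j+1} the constant-size equilibrium.  The
implementation evaluates the convolution in log-space (stable for large τ
and j) and reduces to the geometric equilibrium at τ = 0 and to a point
mass when θ₁ = 0.

Fitting minimises the sum of squared deviations between observed and
model frequencies over j = 0..d_max (no tail renormalisation), via a
coarse vectorised grid over τ ∈ [0, 2 d_max], θ₀ ∈ [0, 20],
θ₁ ∈ [0.1, 10⁴] (plus the τ = 0 equilibrium candidates, so the fit can
never be worse than the best equilibrium fit) followed by Nelder–Mead
refinement constrained to the same box with θ₁ ≥ θ₀.  The θ₁ ≤ 10⁴ cap
reflects the flat likelihood ridge of this model: with near-complete
star-like genealogies θ₁ is effectively unidentifiable and runs to the
boundary, which is also the familiar behaviour of desktop mismatch
software.  A histogram concentrated at zero differences returns
τ = 0, θ₀ = 0 with a degeneracy flag rather than an error.

Goodness of fit and the τ confidence interval use a parametric bootstrap
(default 1000 replicates): coalescent samples of the same size are
simulated under the fitted model, mutations are scattered over the L
finite sites (recurrent hits possible, matching the generator), each
replicate is refitted with the same optimizer, and
p = P(statistic_sim ≥ statistic_obs) for SSD and raggedness, with the
2.5–97.5 percentile interval of the refitted τ̂ as CI.  Raggedness is the
sum of squared successive steps of the frequency profile with implicit
zeros flanking the observed range.

Dating: t = τ/(2 μ L) years, default μ = 0.32 × 10⁻⁶ per site per year, a
standard fast control-region rate; μ is configurable because published
rates for this fragment vary by more than the statistical error of τ̂.

## Differentiation

K2P distance d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q) over comparable sites;
saturation (non-positive log argument) raises rather than returning NaN.
For AMOVA-type sums the per-site distance is scaled by L so the entries
are on the pairwise-differences scale; Φ statistics are scale-invariant,
so this choice only affects reported variance components.

Pairwise Φ_ST is the one-level AMOVA fixation index σ²_a/(σ²_a + σ²_w)
computed from squared K2P distances, with
p = (#{perm ≥ obs} + 1)/(n_perms + 1) over permutations of individuals
between the two populations (default 10,000).  Small negative Φ_ST values
are reported as-is (they are ordinary sampling behaviour for undifferen-
tiated populations) but clamped to zero when the matrix feeds NJ,
ordination or barrier tracing.

The NJ tree is standard Saitou–Nei agglomeration (via scikit-bio) with
negative branch lengths clamped to zero.  Ordination defaults to metric
principal coordinates; non-metric MDS (isotonic regression on ranks,
SMACOF iterations, PCoA start) is available, and both report Kruskal
stress-1 computed the same way so the two modes are comparable.

## AMOVA

Three-level variance components (among groups σ²_a, among populations
within groups σ²_b, within populations σ²_c) come from the nested sums of
squared distances with the expected-mean-square coefficients for
unbalanced designs.  Degenerate designs degrade gracefully: one
population per group zeroes the middle stratum, a single group zeroes
σ²_a.  Negative components are retained in the Φ computations and
flagged.  Permutation schemes: individuals across the whole system for
Φ_ST, individuals among populations within groups for Φ_SC, whole
populations among groups for Φ_CT (default 1000 permutations).  With
few populations the Φ_CT permutation space is small (e.g. 20 distinct
splits of 6 populations into two trios), which bounds the attainable
p-value — a property of the design, not the implementation.

## Geography

Great-circle distances use the haversine formula with R = 6371 km.  The
Mantel statistic is the Pearson correlation of the lower triangles, with
rows/columns of one matrix permuted jointly; the default test is
one-tailed (positive association), matching the isolation-by-distance
hypothesis, with a two-sided option.  The Delaunay triangulation is built
on an equirectangular projection about the centroid latitude — adequate at
sub-continental extents, and the projection is isolated in one method so
it can be swapped.  Monmonier barriers seed at the highest-distance
uncrossed edge and grow from both ends across the locally
maximal-distance adjacent edge until they exit the convex hull or close a
loop; ties break toward the lexicographically smallest population pair
and are flagged.  Removing a barrier's crossed edges partitions the
population graph; when it separates the map, a two-group AMOVA across the
partition provides the barrier's significance.

## Synthetic data

Time is measured in mutational units so that a constant population of
scaled size θ has E[k] = θ and the generator's (θ₀, θ₁, τ) can be passed
straight to the mismatch machinery.  Mutations are Poisson on branches
and dropped on L = 294 finite sites with a 10:1 transition bias
(control-region-like), so recurrent hits occur and the K2P correction has
work to do.  Demographies: constant size, sudden expansion, and an
island-type split (K demes, symmetric migration, fusion into one ancestor
at the divergence time).  Under the panmictic demographies population
labels are exchangeable — useful as a null for permutation-test
calibration; real differentiation requires the split model.  Coordinates
are cluster centres plus Gaussian jitter; under a split model the demes
are separated along longitude so an imposed barrier axis exists.

The packaged fixture suite writes (a) a six-population survey-shaped
dataset (sample sizes 23/23/21/23/29/22, sudden expansion θ₀ = 0.5,
θ₁ = 50, τ = 5, Iranian-city coordinates with 0.15° jitter), (b) a
two-deme barrier dataset (θ = 2, divergence 2 mutational units, no
migration — between-deme Φ_ST ≈ 0.3–0.5), and (c) the four-sequence toy
worked example.  The same seed reproduces the files byte-identically.

What the generator does *not* emulate: site-rate heterogeneity beyond the
transition bias, hypermutable hotspots, insertion/deletion variation,
sequencing artefacts, haplogroup-structured genealogies, or sample sizes
in the hundreds per population.  Passing tests therefore demonstrate the
statistical machinery on idealised coalescent data, not robustness to
every property of empirical control-region alignments.

## Problem sizes in the test-suite

The suite chooses replicate counts that keep each stochastic check
well-resolved while the whole run stays interactive: Tajima calibration
uses 200 data replicates with 300-genealogy nulls, Mantel calibration 200
replicates of 99 permutations, barrier recovery 50 replicate landscapes,
and expansion-recovery coverage 50 simulated samples with 60-replicate
bootstraps.  Production defaults (10,000 Φ_ST permutations, 1000
bootstrap replicates, 10,000 Tajima null genealogies) remain the
package-level defaults.

## Known limitations

* The haplogroup caller is motif-table-driven and intentionally shallow:
  it scores diagnostic variants inside the analysed window only, skips
  indel motifs unless the alignment carries an explicit gapped column,
  and resolves mostly-reference sequences to a zero-variant fallback
  clade if the table defines one.  It is not a phylogenetic classifier.
* The mismatch model's θ₁ is weakly identified (boundary fits are
  common); interpret θ₁ qualitatively.
* The Mantel test inherits the usual caveats about autocorrelated
  distance matrices; it is reported with its permutation null only.
* Spherical geometry is approximated by one global projection per
  triangulation; continental-scale layouts spanning many tens of degrees
  of latitude deserve a proper spherical triangulation, which is out of
  scope.
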