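# Methods

This note records the model conventions, priors, numerical choices and
known limitations of `migscape`, in the order data flows through the
package.

## Panel preparation

`filter_variants` applies rules in a fixed order so that removal counts
are reproducible: non-autosomal and non-SNP records; strand-ambiguous A/T
and G/C pairs (unresolvable after merging data typed on different
strands); duplicated SNP ids (same alleles: first copy kept; conflicting
alternative alleles, as arise when merged sources disagree: all copies
dropped); a Hardy–Weinberg exact test; SNP then individual missingness
(defaults 1% and 5%).

The HWE test is **one-sided toward heterozygote excess**, with a mid-p
computed by enumerating the Levene distribution of heterozygote counts
given the allele counts. Rationale: strand flips and merge artifacts
inflate heterozygosity, which is the failure mode worth filtering, while
heterozygote *deficit* is expected under population structure (Wahlund
effect) and should not remove real signal. Default α = 10⁻⁵.

Relatedness pruning builds the standardized genotype cross-product matrix
(per-SNP mean-centred, variance-scaled, averaged over loci non-missing in
both individuals) and greedily removes, from the currently worst pair
above the cutoff (default 0.6), the member with more missing data (ties:
larger index) until no pair exceeds the cutoff.

PC-loading outlier pruning guards against structural variants: LD blocks
can dominate single PCs. Loadings on each of the first n_pcs PCs are
divided by their standard deviation; any SNP with |score| > 5 on any PC
marks a window on its chromosome and all SNPs inside marked windows are
dropped. The 200 kb window is interpreted as ±100 kb around the outlier
(configurable, since "a window around" is ambiguous between total and
half-width).

Locale downsampling caps every sampling locale (identical rounded
coordinates) at 50 individuals by seeded uniform subsampling, to prevent
dense cohorts from dominating the fit.

## Grids

Planar grids are regular triangular lattices (row offset spacing/2, row
height spacing·√3/2) clipped to a region polygon. Spherical grids are
class-I icosahedral geodesic subdivisions at the frequency whose mean edge
length is nearest the requested spacing; presets of 120/240/500 km match
typical continental-panel resolutions. Only the nominal spacing is
matched, not any particular tool's deme placement — placement details do
not enter the model's contracts. After clipping, only the largest
connected component is kept, because resistance distances are infinite
across disconnected fragments. Spherical distances are haversine on a
6371 km sphere. Samples are assigned to the nearest vertex
unconditionally; ties break to the lowest index.

## The surface model

Two independent Voronoi tessellations define piecewise-constant log₁₀
surfaces for migration m and diversity q (independent granularity: there
is no reason a diversity plateau should share boundaries with a migration
barrier). The migration mean is pinned at 0 because only *relative* rates
are identified — a global rescaling of all conductances trades off exactly
against σ² — while the diversity level μ_q is free.

Edge conductance is the geometric mean of the endpoint rates on the
natural scale, making a barrier vertex throttle all of its edges
symmetrically. Resistance distances come from the identity
L⁺ = (L + J/n)⁻¹ − J/n for connected graphs, which avoids an SVD per
likelihood evaluation; R(u,v) = L⁺_uu + L⁺_vv − 2 L⁺_uv.

The expected-dissimilarity constants — between-deme `Δ = q̄ + R/4`,
within-deme `Δ = q` — are fixed conventions of this artifact. σ² absorbs
the overall data scale but *not* the balance between the q-level and the
R-geometry, so the 1/4 is part of the model definition; it is validated
behaviourally (parameter recovery, likelihood oracles) rather than by
matching any external implementation. With q > 0 the contrast-projected
expectation is provably positive definite (the q-part contributes
½ C diag(q) Cᵀ ≻ 0 and the R-part is conditionally negative definite), so
−∞ likelihoods can arise only from numerically degenerate inputs.

The likelihood treats `S = −½ C D Cᵀ p` as Wishart(p, σ²M) with
`M = −½ C Δ* Cᵀ`, i.e. E[S] = p σ² M. The contrast basis C (rows
e₁ − e_{i+1}) is fixed; any other full-rank contrast shifts the
log-density by a constant that cancels in every MCMC ratio and Bayes
factor, and fixing it makes logged likelihoods reproducible. For two
individuals the density reduces to a 1-D gamma, which serves as an exact
oracle in the tests. The density requires p ≥ n; dense panels satisfy
this easily.

This is a composite-likelihood-style idealization: SNPs are treated as
independent (no LD), and the Wishart form is exact only for Gaussian
deviates. Both idealizations are shared with the model class this package
implements; the loading-outlier filter exists precisely to blunt the worst
LD violations.

## Priors, sampler and schedule

Defaults (all configurable in `McmcConfig`): tile counts K_m, K_q ~
zero-truncated Poisson(λ = 10); tile effects ~ Normal(0, ω²) truncated to
±2 log₁₀ units (surfaces spanning ~10⁻²–10² relative rate); ω² ~
Uniform(0, 1) per surface; seeds ~ Uniform over the region bounding box;
μ_q ~ Uniform(−6, 6); σ² ~ Inverse-Gamma(1, 1). Proposal scales: effect
steps sd 0.1, seed moves sd = grid spacing, σ² log-steps and μ_q steps use
a symmetric two-scale mixture (a coarse component that traverses the prior
and a 50× finer one that matches the sharply peaked posterior when n·p is
large — a fixed kernel, not adaptation).

Birth proposals draw the new tile from its prior and death removes a
uniformly chosen tile, giving acceptance ratios of likelihood ratio ×
λ/(K+1) for birth and × K/λ for death under the unordered-tile
convention; death from K = 1 is rejected (the zero-truncated prior puts no
mass on K = 0). Prior-recovery tests check the resulting K marginal
against the ZTP(10) mean λ/(1−e^(−λ)) ≈ 10.0005 and the effect/σ²
marginals against direct prior draws.

The run protocol mirrors panel-scale practice: several pilot chains from
independent seeds, the end state with the highest posterior density seeds
the final chain, burn-in is discarded and the remainder thinned. The
schedule scales from desk-size synthetic runs (10⁵ iterations, thin 200)
to panel-size ones (up to 8×10⁶ pilot iterations, 5×10⁵ burn-in, thin
2×10⁴) purely through configuration.

Posterior surfaces are rasterized on a fixed 100×100 cell lattice over the
region bounding box, each cell taking the rate of its nearest deme vertex
(the graph-Voronoi convention); rasters are reconstructed on demand from
per-draw vertex rates rather than stored. A cell is a **trough** if its
rate lies below that draw's across-cell mean in ≥95% of draws, a
**corridor** if above in ≥95%; the consensus is defined cell-wise, with
connected components of flagged cells forming the reported features.

Bayes factors against the uniform-migration model (migration tessellation
fixed at one tile, diversity free) use power posteriors on the ladder
t_k = (k/15)⁵ with 16 temperatures and trapezoidal thermodynamic
integration of the expected log-likelihood, chains warm-started up the
ladder. Power posteriors were chosen over harmonic-mean style estimators
for stability at desk scale; the ladder exponent 5 concentrates
temperatures near 0 where the integrand varies fastest.

## Synthetic data

The Wright–Fisher generator defines the package's study conditions. Per
generation, deme allele frequencies first mix deterministically through a
row-stochastic migration matrix (per-edge fraction `base_m` scaled by the
geometric-mean rate factor; an error is raised if any vertex's total
outflow exceeds the cap), then drift by binomial resampling of 2N
chromosomes — the standard migration-before-drift order. There is no
mutation; frequencies initialize at Uniform(0.1, 0.9) so the p loci are
exchangeable replicates. Genotypes are Hardy–Weinberg draws from the deme
frequency, and sample coordinates are the deme positions jittered by 1% of
the grid spacing (assignment tests stay non-trivial but unambiguous).

Defaults — 100 diploids per deme, 200 generations, per-edge migration
0.05, 5000 SNPs, 4 sampled individuals per deme — give neighbour-deme
differentiation of a few percent FST on a ~50-deme grid, the regime the
surface model is designed to resolve. The isolation-by-distance panel used
for the PCA fit comparison uses smaller demes (N = 30, 300 generations, 10
samples per deme), which yields panel-wide FST ≈ 0.07, comparable to a
continental-scale human panel; with much weaker structure the genotype PC
spectrum is nearly flat and median-based PC distances at high k are
noise-dominated, which is a property of the statistic, not a defect of the
fit.

What the generator does *not* emulate: linkage disequilibrium (loci are
independent), mutation, selection, long-range admixture pulses, and
spatially overlapping populations. Passing tests therefore demonstrate
correctness of the machinery and recoverability under the model's own
assumptions, not robustness to every violation found in real panels.

`simulate_model_exact` inverts the fitted likelihood: it draws
S ~ Wishart(p, σ²M) and back-transforms through the closed-form inverse of
the contrast projection (D₀ᵢ = Bᵢᵢ, Dᵢⱼ = −2Bᵢⱼ + Bᵢᵢ + Bⱼⱼ with
B = S/p), giving dissimilarity matrices with E[D] = σ²Δ exactly — the
basis for likelihood-consistency and posterior-fit oracles.

## Evaluation statistics

Observed dissimilarity is the mean squared allele-count difference over
pairwise-complete loci (a 0/2 homozygote pair contributes 4); the
convention is stated because no single standard exists. Genotype PCA
mean-imputes missing calls per SNP and centres without variance scaling
(the common choice for array data; a scaled variant is available), with a
deterministic sign rule (largest-magnitude loading positive). PCA-implied
population distances are squared Euclidean distances between per-population
coordinate-wise medians of the first k scores, k ∈ {2, 10, 100}; the
posterior-implied distance matrix averages σ²-scaled Δ over draws. Fit is
the Pearson correlation over the upper triangle, unweighted.

FST uses the Weir–Cockerham (1984) variance components in ratio-of-sums
form, skipping monomorphic loci. The stepping-stone prediction is
FST = 1/(1 + 4Mκ) with M the scaled mean migration rate. κ defaults to 1
(infinite-island approximation); `island_kappa(d) = (d/(d−1))²` provides
the finite-island correction, which for two demes gives the exact
quasi-equilibrium 1/(1 + 16Nm) for Wright's FST computed from the deme
frequencies. Note the estimator and the parameter diverge for very few
demes: Weir–Cockerham θ measures differentiation relative to an implied
metapopulation and for a fixed pair of demes converges to 2F/(1+F), not F;
the package's island-model checks therefore use ≥16 demes for θ and the
frequency-based definition for the two-deme case.

The partial Mantel statistic is the correlation of upper-triangle
residuals after regressing both the genetic and the language distance
matrix on geographic distance (equivalently, the partial correlation); the
null permutes rows and columns of the genetic matrix jointly, p one-sided
upper with the +1 convention. Permutation units are populations. Mantel
tests are known to be poorly calibrated under strong spatial
autocorrelation; p-values should be read as indicative.

## Numerical choices and degenerate inputs

Resistance computation requires a connected graph and strictly positive
conductances (errors otherwise). The Wishart density returns −∞ (flagged,
not raised) for non-positive-definite scale matrices so the sampler can
reject such proposals. Nearest-seed and nearest-vertex ties break to the
lowest index. Posterior sds use ddof = 1. Mixing frequencies are clipped
to [0, 1] after the matmul to absorb float rounding. All stochastic
components take explicit integer seeds or Generators and are reproducible
bit-for-bit; distinct subsystems derive independent streams via
`SeedSequence.spawn`.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic
data sized for a single core: recovery experiments use a 48-deme grid
with 192 individuals, 5000 SNPs and 10⁵ MCMC iterations; Bayes-factor
calibration uses a 14-deme grid, 2000 SNPs and a 16-temperature ladder
with 800 iterations per rung; island-model FST checks use 16 demes × 5000
SNPs. These sizes were chosen so the full validation cycle completes in
minutes while leaving every threshold meaningfully testable.

## Known limitations

The model is an equilibrium visualization device: surfaces summarize
present-day heterogeneous isolation by distance and say nothing about
*when* differentiation arose, nor can they represent spatially overlapping
but differentiated groups or long-distance admixture. The geodesic grid
matches nominal spacing only. The Bayes-factor estimator carries
Monte-Carlo error from the temperature ladder (a few log units at the
shipped settings), so small |log BF| values should not be over-read.
Troughs are defined relative to the map average, so a uniformly low-rate
map has no troughs by construction.
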