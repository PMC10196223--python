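# Methods

This note documents the models, estimators, numerical conventions and
design choices behind each stage of the pipeline, and what the synthetic
data do and do not establish.

## Synthetic world

**Genotypes.** A forward Wright–Fisher stepping-stone metapopulation:
`n_pops` demes (default 21) of `deme_size` diploids (default 100) in a
west→east chain, nearest-neighbour gamete migration at rate
`migration_rate` (default 0.05, split evenly between the two neighbours;
edge demes reflect), and stepwise microsatellite mutation at
`mutation_rate` (default 5.47 × 10⁻⁵ per generation, the rate also used in
the θ→N_e conversion) on a lattice of `repeat_unit` = 2 bp. Demes are
founded from cluster-specific perturbations of a 16-allele ancestral pool
with skewed (Dirichlet α = 0.4) frequencies; founder allelic richness
declines with longitude at `diversity_gradient` (default −1.5 alleles per
degree), encoding the serial-founder/colonization history that produces
the west→east decline in allelic richness and private alleles. After
`n_generations` = 50 generations of drift, migration and mutation,
`n_ind_per_pop` = 30 individuals are sampled per deme. Under these
defaults the world shows mean pairwise Weir–Cockerham θ ≈ 0.13–0.15, mean
A ≈ 6, a clear eastward A_r decline, and a handful of mostly-western
private alleles — the qualitative regime of the emulated system.
What the generator does **not** emulate: genotyping error, null alleles,
linkage between loci, selection, and realistic spatial autocorrelation of
deme sizes; tests passing on this world show estimator correctness and
calibration, not robustness to those artefacts.

**Climate.** Deterministic trend surfaces on a 0.1° grid over 41–48° E,
40.9–42.7° N: precipitation of the warmest/coldest quarter (bio18/bio19)
declines strictly monotonically west→east; temperature variables follow
elevation (two smooth mountain chains plus seeded roughness) and
longitude; derived evapotranspiration/aridity layers are recomputed from
the base layers, with the moisture index an exact affine image of the
aridity index (a designed perfect-collinearity case for the VIF filter).
Future stacks are the current stack plus additive per-variable scenario
shifts (ssp370: bio1 +2.3 °C, bio18 −60 mm, bio19 −70 mm; ssp585: +4.4,
−110, −130; chosen once as mid-range end-of-century anomalies for the
region) with a small deterministic per-GCM spread; an explicit `shift`
mapping overrides the scenario defaults exactly.

**Occurrences and ancestry.** 88 occurrence points are drawn with
probability ∝ sigmoid(bio19)³ × Gaussian(elevation), a sharply peaked
niche giving SDM AUC ≈ 0.85–0.9 on held-out points. Ancestry coefficients
use the quadratic band form: with climate axis d = effect·z and cluster
centres c_k evenly spaced on [−1, 1], logit_k = 2 d c_k − |effect| c_k².
This is linear in the covariates (hence exactly representable by the
multinomial-logit surrogate), gives uniform membership at zero effect,
and makes each cluster modal on its own segment of the gradient.

## Diversity and differentiation

A is the mean number of distinct alleles per locus; A_r is hypergeometric
rarefaction to `g` gene copies (default: the smallest per-population,
per-locus number of scored copies), Σ\_i [1 − C(n−n_i, g)/C(n, g)];
A_p counts (locus, size) alleles confined to one population over the full
dataset. Pairwise F_ST is the Weir–Cockerham (1984) θ with variance
components summed over alleles and loci (ratio of sums); loci with fewer
than two scored individuals in either population are skipped for that
pair, and negative estimates are preserved. The Slatkin linearization
F/(1−F) clamps negatives to 0 and values ≥ 1−10⁻⁶ to (1−ε)/ε with a
warning. The ancestry PCA is centered (not scaled; Q columns share a
scale), with the sign convention that each component's
largest-magnitude loading is positive.

## dbRDA and variance partitioning

The response distance matrix is Gower-centered; principal coordinates with
positive eigenvalues (relative tolerance 10⁻⁸) define the response space,
and total inertia is the sum of positive eigenvalues (no Lingoes
correction by default — the dominant convention for linearized-F_ST
responses; negative eigenvalues are ignored). Constraints are centered and
rank-pruned; with conditioning variables Z, both the principal coordinates
and X are residualized on Z first (columns annihilated by conditioning are
dropped as aliased). R² = constrained inertia / total inertia, matching
vegan's `capscale` to machine precision on shared test instances; F is the
pseudo-F with residual df n−1−m−q. Adjusted R² is Ezekiel's closed form;
for partial models it is adj(X∪Z) − adj(Z), both Ezekiel (vegan's partial
`RsquareAdj` computes R² with an inconsistent denominator when negative
eigenvalues exist; we use the positive-inertia denominator throughout, so
partial adjusted values can differ slightly from vegan's). Permutation
significance permutes response rows freely, or residuals of the reduced
model under conditioning; p = (#{F* ≥ F} + 1)/(nperm + 1).

Forward selection is greedy on adjusted-R² gain with a conditional
permutation test per candidate (ties broken lexicographically); a
candidate is added if significant, and selection stops once the
cumulative adjusted R² exceeds the global (all-candidate) model's — the
accept-then-stop reading of the two-part stopping rule, which keeps the
bound from vetoing a genuinely causal first pick. When the global model
is not estimable (more candidates than residual df) the bound is disabled
with a warning.

The variance partition fits the full model on all blocks and, per block,
the partial model conditioned on all other blocks; each pure row reports
explained (pure R²), unexplained (1 − full R², shared by all rows) and
confounded (full − pure), so rows close to 1 exactly. With
`cascade=True`, blocks with non-significant pure effects are removed one
at a time (largest p first) and the reduced full model refitted,
reproducing the model I → II → III reduction style. Population-level
climate is point-sampled at site coordinates (buffer means are a
documented alternative the data did not require); the orography block is
the first PCNM eigenvector of |TRI_i − TRI_j| (the minimal dissimilarity
for a scalar site attribute), with more axes available via `n_axes`.

## Effective size and bottlenecks

**LD method.** For every locus pair, individuals complete at both loci
define the sample S; alleles at frequency ≤ `maf_cutoff` (default 0.02)
are excluded; the Burrows composite disequilibrium Δ̂ (with the S/(S−1)
correction) over all remaining allele pairs gives r² = Δ̂²/(p(1−p)q(1−q)).
The mean r² weights locus pairs by their (K₁−1)(K₂−1) independent
comparisons; the sampling expectation (1/S + 3.19/S² for S ≥ 30, else the
small-S polynomial) is subtracted and the Waples piecewise inversion maps
the drift signal to N̂e. Negative estimates (sampling noise exceeding
drift) are reported verbatim; a non-positive drift signal maps to +∞. The
95 % CI is the parametric chi-square interval on the weighted mean r²
with the total comparison count as df (a jackknife alternative was out of
scope). On 200 Wright–Fisher replicates (true Ne = 50, S = 50, 20 loci)
the median estimate falls within [40, 62].

**θ→N_e.** Two conventions are implemented because the stated relation
θ = 4N_e μ (N_e = θ/4μ) and the published per-population values
(= 4θ/μ, verified against the two extreme populations) differ by exactly
16×; `table3` is the default for reproduction runs and the discrepancy is
asserted in tests rather than silently resolved.

**M-ratio.** Per locus M = k/(r+1) on the repeat lattice (monomorphic loci
give M = 1 and are included). The equilibrium null simulates a Kingman
coalescent genealogy (time in 2N units, mutation rate θ/2 per lineage)
with two-phase mutation — single step with probability 0.88, else a
geometric multistep of mean 2.8 (the recommended defaults; configurable)
— on an unbounded ladder. The test is a one-sided Wilcoxon signed-rank on
per-locus M_obs − M_eq (exact distribution up to 25 loci; zero
differences dropped; all-zero ⇒ p = 1). The null θ is taken from input
when available and otherwise estimated from expected heterozygosity under
SMM, θ = ((1/(1−He))² − 1)/2 — using the observed sample's own diversity,
as the standard implementations do; this is what gives the test its power
(a crashed sample is judged against the equilibrium expected at its own
reduced diversity). Power experiments use a moderate planted crash
(Ne 100 → 10 for 5 generations): deeper crashes drive per-locus M back
toward 1 (k and range collapse together), a known boundary of the
statistic that the experiments deliberately avoid.

## Niche modelling

The VIF filter drops the worst variable (> 10) one at a time, recomputing
after each drop, with infinite VIFs (exact collinearity) dropped first and
lexicographic tie-breaks. The suitability model is the maxnet-style
surrogate: linear + quadratic + pairwise-product features of
background-standardized predictors, L1-regularized logistic discrimination
of occurrence cells (cell-level deduplicated, 80/20 train/test split by
seed) against up to 10,000 random background cells, regularization
multiplier `reg` = 1. The logistic output is shifted so the median
training presence maps to suitability 0.5 (the MaxEnt logistic-output
convention; the shift is monotone and leaves AUC/TSS unchanged). Original
hinge/threshold features and the MaxEnt optimizer are intentionally not
reproduced. AUC is the presence-vs-background rank statistic; TSS the max
over thresholds of sensitivity + specificity − 1. Ensembles average
suitability cellwise (NODATA propagates). Areas sum cell areas
(111.32 km × cos φ × Δlon) × (110.57 km × Δlat) over cells at or above
the threshold; altitude statistics use the 15 % mask by default (a flag
switches to 70 %). TRI is the mean absolute elevation difference to the
available 8 neighbours. On the synthetic landscape the ≥ 70 % area is
small and can be zero at some seeds — the toy niche saturates near
suitability ~0.7 — so high-suitability accounting is exercised mainly by
constructed rasters in tests.

## Ancestry forecasting

The surrogate for Bayesian ancestry–environment clustering is a
multinomial-logit (softmax) regression of the population Q matrix on four
bioclimatic covariates (bio1, bio3, bio18, bio19 by default), minimizing
cross-entropy against the fractional memberships with an L2 ridge
(λ = 10⁻³) for identifiability, deterministic L-BFGS from zero
initialization, coefficients sum-centered across clusters. K is taken
from the input Q; no model selection is performed. Geographic coordinates
may be added as covariates but the default is climate-only. Projection
applies the fitted softmax per cell, masks cells below 15 % suitability
as NODATA, and for multi-GCM futures averages membership probabilities
cellwise before the argmax. The persistence report counts per-cluster
cells/areas; a cluster is lost when its future cell count is zero; the
Shannon entropy of cluster area shares indexes homogenization (a
sufficiently strong climate shift collapses the landscape into few bands
and lowers the entropy; the trajectory need not be monotone at small
shifts because the suitability mask and band boundaries move together).

## Prioritization

Reserve selection is greedy complementarity (largest uncovered-allele
gain, optional allele weights, label-order ties, 100-iteration cap)
followed by a redundancy-elimination pass that drops any selected
population whose alleles are covered by the rest; on 8-population
incidence matrices from the generator this matches the exhaustive minimum
set cover in ≥ 95 % of instances and never exceeds it by more than one.
F_c is the area-weighted mean forest fraction over cells whose centres
lie within a 20-km geodesic circle. The climate-shift factor is
C_l = √((1+ρ₁₈)(1+ρ₁₉)) with ρ_v = |future_v − current_v|/current_v — the
adopted concrete form of a "geometric mean between current and future
bioclimatic variables": it is 1 under no change and grows with the
projected shift, so larger shifts discount C_i = A_r F_c / C_l as
intended. Categories: the default `interval` method bins C_i into
unit-width integer-anchored intervals (category c ⇔ C_i ∈ [k−c, k−c+1),
open at the extremes), which reproduces the published category
memberships for an index spanning (0, k]; the `rank` method (equal-size
descending-C_i groups, larger groups first) is used in the synthetic
pipeline where C_i has no natural anchoring.

## Pipeline

Stages run in dependency order (simulate → metrics → landgen → ne → enm →
forecast → prioritize); disabling a dependency skips its dependents with
an explicit message; a non-empty output directory is refused without
`force`. Every output is checksummed into `manifest.json`; `report.json`
records the seed, parameters and stage timings. All randomness derives
from the single seed, and reruns are byte-identical on all CSV/ASC/GeoJSON
outputs. Default problem sizes (nperm = 999 for permutation tests,
999 for forward selection, 2000 coalescent simulations per population for
the M-ratio null, a 0.1° raster grid) keep a full synthetic run around
one to two minutes on a single core while leaving permutation p-value
granularity of 10⁻³.
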