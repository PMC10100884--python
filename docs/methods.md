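# Methods

This note documents the models, conventions and numerical choices behind
`plankton-assembly`, in the order the pipeline applies them.

## Input model and normalization

The canonical community object is a samples × ASVs nonnegative integer
matrix with unique identifiers on both axes. Taxonomy maps each ASV to a
plankton group (e.g. phytoplankton / microzooplankton), a phylum-level
lineage and optional genus/species; metadata carries a region label,
decimal-degree coordinates and a vector of real-valued environmental
variables per sample.

*Singleton filtering* removes ASVs whose **table-wide** total count is 1
(not per-sample singletons); an ASV observed once in each of two samples
is retained. The operation is idempotent.

*Rarefaction* subsamples each sample without replacement (multivariate
hypergeometric) to a common depth, by default the smallest sample total,
as a single seeded draw. The expected post-rarefaction count of ASV *j* in
sample *i* is depth·x<sub>ij</sub>/rowsum<sub>i</sub>, which the test
suite verifies empirically. A single draw (rather than averaging many)
keeps every downstream table integer-valued and bit-reproducible; the seed
is mandatory in pipeline mode.

## Diversity

Alpha indices follow the common ecology conventions: Shannon in natural
log; Chao1 in the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), which is
finite when doubletons are absent; Pielou evenness Shannon/ln(S_obs),
undefined for a single observed taxon; Faith's PD as the total branch
length connecting the present tips to the root (the path to the root is
included — the convention matters for single-tip samples and is fixed
here). Faith's PD and newick parsing are delegated to scikit-bio.

Bray-Curtis dissimilarity is Σ|x−y| / Σ(x+y) on counts. PCoA uses Gower
double-centering B = −½·J·D²·J and an `eigh` eigendecomposition;
coordinates are eigenvectors scaled by √λ with a deterministic sign
convention (largest-magnitude loading positive). Negative eigenvalues are
reported but not corrected (no Lingoes/Cailliez), and axis proportions are
taken over the positive-eigenvalue sum only.

PERMANOVA follows Anderson's one-way pseudo-F: SS_total = Σ_{i<j} d²/n,
SS_within from same-group pairs, F = (SS_between/(g−1))/(SS_within/(n−g)).
Permutations of the group labels are vectorized and seeded; p = (#{F_perm ≥
F_obs}+1)/(n_perm+1) with a 999-permutation default. The implementation is
cross-checked against scikit-bio's PERMANOVA in the test suite.

Two-group comparisons use Welch's t (Satterthwaite df) by default — the
unequal-variance behaviour of R's `t.test` — and the Wilcoxon rank-sum
test with exact enumeration when both groups have ≤ 10 tie-free values,
otherwise the tie-corrected normal approximation. Fully tied pooled data
return p = 1 by convention (no ordering information).

## Spatial and environmental structure

Geographic distances are haversine great circles with Earth radius
6371.0088 km. Environmental distances z-score each variable (sd with n−1)
across the included samples before Euclidean distance; zero-variance
variables are dropped with a warning.

*Distance-decay* regresses similarity (1 − Bray-Curtis) on the vectorized
upper triangle of a predictor distance matrix by OLS, with no log
transform. The reported p-value is the OLS slope t-test, mirroring a plain
`lm` fit on the n(n−1)/2 pairs. Pairs sharing a sample are not
independent, so this p-value is anticonservative: under a permuted-
predictor null its empirical rejection rate at α = 0.05 is ≈ 0.09–0.13
rather than 0.05. A Mantel permutation p over whole-sample-label
permutations (exact by construction; measured rejection ≈ 0.03–0.05) is
available via `mantel_permutations` and is the quantity the package's
calibration checks assert. Both are reported so users can mirror
legacy analyses while seeing the calibrated alternative.

*Spatial predictors* are PCNM/dbMEM eigenfunctions: distances above the
longest minimum-spanning-tree edge t are replaced by 4t, the truncated
matrix is double-centered and eigendecomposed, and eigenvectors with
positive eigenvalues (scaled by √λ) become predictors. The construction
reproduces `vegan::pcnm` exactly (verified against frozen vegan
eigenvalues in the tests). Note that the leading eigenfunction on a
regular transect is a low-frequency sinusoid — strongly rank-correlated
with position (|ρ| ≈ 0.8) but not monotone. Raw lat/lon can be used as
spatial predictors instead via the library API if preferred.

*Variation partitioning* Hellinger-transforms the counts (square root of
relative abundances, giving unit row sums of squares), computes each
predictor set's RDA R² = SS(fitted)/SS(total) by multivariate least
squares on column-centered matrices, Ezekiel-adjusts
R²_adj = 1 − (1−R²)(n−1)/(n−p−1) with p the column count, and applies the
standard inclusion–exclusion: a = R²adj(E∪S) − R²adj(S), c = R²adj(E∪S) −
R²adj(E), b = R²adj(E)+R²adj(S)−R²adj(E∪S), d = 1 − R²adj(E∪S). The four
fractions sum to 1 by algebra (asserted to 1e-10); negative fractions are
reported as-is with a warning — clipping is left to presentation. Fully
identical ENV and SPA matrices are legal (total confounding, everything in
b); any other rank deficiency is an error naming the collinear columns.
The pipeline caps the number of PCNM axes (default 3) so predictors stay
well below n − 1.

## Neutral community model

Sloan's model treats each local community of N individuals (here: reads
per sample after rarefaction) as drifting around a source metacommunity
with immigration rate m: a taxon at source relative abundance p has local
relative abundance π ~ Beta(Nmp, Nm(1−p)).

For the predicted occurrence frequency the package uses the **exact
zero-class form**: a sample of N reads misses the taxon with beta-binomial
probability E[(1−π)^N] = B(a, b+N)/B(a, b), so

  freq_pred(p) = 1 − B(Nmp, Nm(1−p)+N) / B(Nmp, Nm(1−p)).

The widely used approximation — the upper Beta tail above a hard detection
limit d = 1/N — is available as `detection="threshold"`. The two agree in
the continuum limit, but against data whose sampling process is explicit
(the package's own generator, and any real amplicon library) the threshold
form is biased: fitting it to exact-model occupancies inflates m̂ by
+20–31% at N = 5000. With the zero-class form, median recovery error
across m ∈ {0.05, 0.3, 0.7} is under 8%.

m is fitted by bounded nonlinear least squares on untransformed
frequencies (no weighting), multi-started from {0.01, 0.1, 0.5, 1.0} with
m ∈ [1e-6, 1]; the lowest-SSE start wins and the fitted objective is
verified against every start. R² = 1 − SS_res/SS_tot about the mean
observed frequency and may be negative for badly non-neutral data. ASVs
with zero post-rarefaction abundance are excluded; fits require ≥ 10 ASVs.
Fits are run separately per region × group, mirroring a two-region,
two-group survey design.

*Partitioning.* Each ASV is labelled above / neutral / below a Wilson
score interval at level 1−α (default 0.05) around its predicted frequency,
with the number of samples as the effective trial count (non-integer
"successes" allowed). Because observed frequencies are discrete (k/n, here
n ≈ 12–33), the comparison applies a half-step 1/(2n) continuity
correction: without it, a taxon present in every sample is labelled
"above" whenever the band's upper limit is numerically just below 1, which
misclassifies ~30% of taxa under the generating model itself. With the
correction, the median neutral fraction on neutral simulations is
0.93–0.99. Partition summaries report richness (ASV count) and abundance
(sequence sum) proportions per partition, overall and within each
phylum-level lineage; bootstrap confidence bands are out of scope.

## Niche breadth and dispersal

Levins' B for taxon j is 1/Σᵢ q²ᵢⱼ with qᵢⱼ the fraction of the taxon's
reads in sample i — the inverse Simpson concentration across habitats,
ranging from 1 (endemic) to the number of samples (even generalist); it is
invariant to rescaling a taxon's counts. Bcom is the unweighted mean of B
over the taxa present in a sample (abundance weighting is available but
off by default), and is computed within each region separately so B
reflects occupancy across that region's samples.

The dispersal proxy for a sample pair (s, u) is the symmetric mean of each
sample's read fraction belonging to jointly present taxa; a sample's score
is its mean over partners, in [0, 1] with 1 for identical compositions and
0 for disjoint ones. A min-based variant (Σ min read proportions, i.e.
1 − Bray-Curtis restricted to shared taxa) is available behind
`method="min_sum"`. The per-sample-pair reading is used (matching
per-community comparisons); a strictly per-taxon shared proportion would
be an alternative reading of "dispersal ability of each taxon" and is not
implemented.

## Synthetic generators

The neutral generator draws source abundances p from a normalized
lognormal (σ = 1.5 by default, a typical rank-abundance spread for
plankton metabarcoding), then per sample a composition from
Dirichlet(N·m·p) — whose marginals are exactly the Beta law the NCM
assumes — and finally counts from Multinomial(N). Parameter recovery is
therefore a well-posed estimation problem, not a model-mismatch exercise.
The niche generator gives each taxon a Gaussian response
exp(−(e−μⱼ)²/2σⱼ²) along an environmental gradient laid out on a spatial
transect (env and space collinear unless `spatial_noise` decouples them)
and samples multinomial reads from the normalized responses.

Default study sizes are S = 300 taxa, 30 samples, depth 5000 — chosen so a
full three-m recovery sweep with 20 seeds per condition runs in well under
a minute per sweep on one CPU. The two-region demo bundle uses 12 samples
per region at depth 3000 with 120 ASVs per group.

What the generators do **not** emulate: sequencing error and chimeras,
compositional biases of PCR, taxon-specific read-length or copy-number
effects, temporal dynamics, and phylogenetic signal in niche optima.
Passing recovery and calibration tests therefore demonstrates correctness
of the estimators under the stated sampling models, not robustness to
every artifact of real amplicon libraries.

## Pipeline determinism and degenerate inputs

Every stochastic stage (rarefaction, PERMANOVA permutations) derives its
seed from the single configured seed by fixed offsets; output tables are
written with a fixed float format and line terminator, so identical
configurations yield byte-identical files. Stage failures abort with the
stage name and offending input. Degenerate inputs are errors, not silent
results: all-zero samples, unequal row sums passed to occurrence
statistics, constant predictor distances, groups of size 1, rank-deficient
predictors, pielou with one taxon.
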