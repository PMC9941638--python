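# Methods

This note records the models implemented in `panicleqtl`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Descriptor model

Each panicle trait (primary branch length, secondary branch number,
spikelet number) is treated as a function of relative branch position on
[0, 1]: branch rank *i* of *n*, counted from the distal end, sits at
*(i−1)/(n−1)*, so rank 1 is exactly 0 and rank *n* exactly 1 regardless of
branch number.  The smooth model is

    y_i = alpha + sum_{k=1..K} beta_k b_k(x_i) + eps_i.

**Basis.**  The b_k are cubic B-splines on evenly spaced knots spanning
[0, 1] (boundary knots repeated, K−3 interior knots).  A full B-spline
basis of size K+1 is built and its first member dropped in favour of an
explicit intercept; since B-splines sum to one, the constant function
remains exactly in the span.  The knots depend only on K, never on the
data — the load-bearing property, because it makes coefficient vectors
from panicles with different branch numbers directly comparable.  Basis
integrals come from the exact B-spline antiderivative; the roughness
penalty matrix (Gram matrix of second derivatives) from 3-point
Gauss–Legendre per knot span, which is exact for the piecewise-linear
second derivatives of cubics.

**df semantics.**  `df = K` is the number of non-intercept basis
functions; the intercept is always present, so a regression fit consumes
K+1 observations.  The candidate set is {3, 4, 5}; 5 mirrors the smallest
panicle the field protocol admits.  A panicle with fewer than K+1
branches cannot be fitted at that K: it is excluded from that candidate's
GCV sum (and a candidate losing more than 10% of panicles is
disqualified).

**Fit modes.**  The default is unpenalized regression (lambda = 0): with
K ≤ 5 and fixed knots the roughness penalty is nearly inactive, and the
regression mode keeps edf integral and the GCV sums exactly reproducible.
A penalized mode (second-derivative penalty, per-fit GCV choice of
lambda, edf = trace of the smoother matrix) is provided for smoothing
studies; as lambda grows it shrinks to the least-squares straight line,
the penalty's null space.

**df selection.**  Per trait, GCV = n·RSS/(n−edf)² is summed over every
plant's panicle; the candidate with the smallest sum wins and ties go to
the smaller K (parsimony).  Saturated fits (n ≤ edf) score infinity and
are excluded with a logged count.

**Normalization.**  The fitted curve is divided by its exact integral
I = alpha + sum_k beta_k·(integral of b_k); curves with I ≤ 1e−6 (no
usable mass) are rejected.  The transformation is linear in the
coefficients and negative excursions are kept, so PCA reconstruction of
descriptor vectors is exact and size-invariance holds exactly:
multiplying all of a panicle's measurements by c > 0 leaves the
descriptor unchanged.

**Line values.**  Each replicate plant is fitted and normalized
separately; the line descriptor is the coefficient-wise mean (the
integral is linear, so the mean still integrates to one).  Whether the
original analysis averaged coefficients or pooled plants into one fit is
not determinable; coefficient averaging was chosen because it weights
plants equally regardless of branch number.

## Pattern features

Per trait, a centered unscaled (covariance) PCA of the lines × (K+1)
descriptor matrix.  All min(n−1, K+1) components are kept, making the
round trip descriptor → scores → descriptor exact to machine precision.
Loading signs are fixed (largest-magnitude element positive) so runs are
reproducible; orientation relative to any external figure is arbitrary.
PC effects are visualised by moving one score to mean ± k·SD (default
k = 2) with other scores at their means and mapping back through the
loadings.  Replicate confidence bands are pointwise t intervals,
mean ± t_{(1+level)/2, m−1}·sd/√m on a 201-point grid; two phenotypes are
called indistinguishable when their bands intersect at every grid point.
Bands across replicate plants (rather than smoother standard errors) were
chosen because they reflect biological replication, not fit uncertainty.

## Heritability

VanRaden relationship matrix from {−1, 0, +1} dosages: markers mean
imputed, centered by twice the allele frequency,
G = WW′ / (2·Σ p_k(1−p_k)); monomorphic markers drop out of the
denominator.  REML for y = mu + g + e with Var(g) = Gσ²_G,
Var(e) = Iσ²_ε: the intercept is removed by an orthonormal error-contrast
basis, the contrast kernel eigendecomposed once, and the profiled
restricted likelihood maximised over log(σ²_G/σ²_ε) on [−10, 10] by an
81-point grid plus bounded refinement (xatol 1e−8); boundary solutions
(h² near 0 or 1) are kept.  h² = σ²_G/(σ²_G+σ²_ε) is NaN with a warning
when both components vanish.  Note the h² scale depends on the
relationship-matrix convention: with this G (diagonal ≈ 2 for inbred
lines) σ²_G is on the G scale, which is also how the recovery simulations
define truth.

## QTL scan

**Population model.**  BILs: one backcross to the recurrent parent, then
repeated selfing.  Genotype classes are the two homozygotes with
stationary frequencies (3/4, 1/4); residual heterozygotes (≈(1/2)^7 per
locus after six selfings, under 1% of calls) are treated as missing.

**Map.**  Two-point discordance D between adjacent markers (among lines
homozygous at both) is inverted through the BC1-then-selfed closed form
D(r) = 3r/(2(1+2r)) — derived by applying the Haldane–Waddington selfed
line expansion R = 2r/(1+2r) to the doubly heterozygous backcross progeny
— then converted to cM by Kosambi, d = 25·ln((1+2r)/(1−2r)).  Two-point
estimates are capped at r = 0.45.  A plain selfed-RIL inversion is
available as an alternative mode.  Single-interval estimates carry ~20%
sampling noise at n = 300 and 5 cM spacing; the estimator is validated on
its calibration (average interval error and total map length within 10%
in simulation), not per interval.

**Genotype probabilities.**  A two-state forward–backward HMM per
chromosome on a grid of markers plus pseudomarkers (default step 1 cM).
Transitions come from the same two-locus model (switch mass
s = (1−r)R + r gives P(recurrent→donor) = s/3, P(donor→recurrent) = s,
leaving the 3:1 prior stationary); emissions use a genotyping error rate
(default 1e−4), missing calls are uninformative.  An isolated call
contradicted by its neighbours is genuinely ambiguous between a
genotyping error and a double recombinant, so posterior mass at such
markers legitimately falls below 1−10ε.

**Scan.**  At each grid position a two-component normal mixture (class
means, common variance, mixture weights = the HMM probabilities) is
fitted by EM (start at the prior weights, ≤100 iterations, log-likelihood
tolerance 1e−8, variance floored at 1e−10 of the phenotype variance);
LOD = log₁₀ L₁/L₀ against the pooled single normal, floored at 0.  At a
complete, error-free marker this reduces exactly to single-marker
regression, LOD = (n/2)·log₁₀(RSS₀/RSS₁).  The EM is vectorised across
grid positions and across permutation columns, with converged
position/permutation pairs retired from the working set.

**Thresholds and peaks.**  Line labels are permuted jointly across the
genome (preserving marker correlation); the threshold is the empirical
(1−alpha) quantile (linear interpolation, R type 7) of the per-permutation
genome-wide maximum LOD.  One peak per chromosome is reported above
threshold, with a −2 LOD support interval expanded to the nearest flanking
grid positions, per-homozygote allele means ± sd/√m at the nearest marker,
and PVE = 1 − 10^(−2·LOD/n).

## Synthetic data generator

The generator mirrors the study design rather than any particular field
dataset.  Defaults: 75 lines, 3 replicate plants, BC1 + six selfings,
markers every 5 cM, branch count Poisson(11) floored at 5 (the protocol's
minimum), recurrent organ totals 92 cm branch length / 30 secondary
branches / 162 spikelets per panicle (a typical japonica panicle), branch
lengths gamma with CV 0.20, counts negative binomial with dispersion 8,
spikelet counts floored at 1.  Densities are Beta mixtures with a 15%
uniform component so every branch carries some organ mass: the recurrent
pattern rises proximally (Beta(2, 1.4) core), the donor pattern is its
distal mirror (Beta(1.4, 2)).  A *number* QTL multiplies a line's expected
totals by 1.45 for donor homozygotes (about the published spikelet
allele-mean ratio) without touching the density; a *pattern* QTL switches
the density without touching the totals.  Crossovers are interference-free
(Haldane) even though map estimation reports Kosambi distances, so map
round trips are approximate by design.

What the generator does **not** emulate: field/environment effects,
genotype-by-environment interaction, polygenic background beyond the
planted loci, segregation distortion, crossover interference, correlated
measurement error among neighbouring branches.  Passing tests therefore
demonstrate internal correctness and statistical calibration of the
pipeline under the stated breeding design, not robustness to every
property of field data.

## Test battery problem sizes

The statistical acceptance checks run at sizes chosen to give stable
rates while keeping the default suite fast: permutation type-I error over
400 null replicates (100 lines, two 50 cM chromosomes, 400 permutations
each; tolerance 0.05 ± 0.02 ≈ 1.8 binomial SE); detection power for a
30%-PVE additive QTL over 100 replicates of a 75-line panel with
1,000-permutation thresholds; the number/pattern dissociation over 10
replicates of the full pipeline (75 lines × 3 plants, three 60 cM
chromosomes, 1,000 permutations per trait), scored as per-trait detection
rates ≥ 90% plus a ≤ 10% cross-detection rate over replicate × trait
pairs — a strict "no false positive anywhere per replicate" reading would
be defeated by the 5% genome-wide error rate the thresholds themselves
guarantee.

## Known limitations

* Two-point map estimation ignores multi-locus information; for sparse or
  noisy marker data a multipoint estimator would be better calibrated.
* The two-state HMM discards residual heterozygote information (an
  optional three-state treatment is not implemented).
* The expansion formula assumes selfing to fixation (F∞); after six
  selfings the residual heterozygosity (≈0.8%) makes this a very close
  approximation.
* Exact reproduction of coefficient values from other spline software
  depends on the basis family and knot placement used there; variance
  proportions and QTL locations are robust to that choice, individual
  coefficients are not.
* PVE uses n = number of phenotyped lines; published tables computed this
  way are internally consistent only for moderate LOD values.
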