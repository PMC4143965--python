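# Methods

## Data model and units

A sample is a point pattern: synapse centroids inside an axis-aligned box
window, each point optionally carrying a Feret diameter (the diameter of
the smallest circumscribing sphere of the reconstructed synaptic
junction). Coordinates and diameters are stored in nanometres; intensities
are reported in synapses per µm³ with the single conversion constant
1 µm³ = 10⁹ nm³. Box membership is half-open per axis
(`origin ≤ x < origin + side`), so subsampling boxes never double-count a
point. Densities are kept at full precision internally and rounded to
three decimals only at reporting time.

Tissue shrinks during EM processing; `shrinkage_correct` divides all
linear measures (coordinates, diameters, box sides and origin) by the
linear shrinkage factor (default 0.90), so volumes come out divided by
its cube (≈ 0.73).

## Second-order summaries

`k3_translation` implements the Miles–Lantuéjoul–Stoyan–Hanisch
translation-corrected estimator of Ripley's K in 3D with the N²
normalization (deliberately not N(N−1)):

    K̂(d) = vol(B)²/N² Σ_{k≠l} 1{‖x_k−x_l‖ ≤ d} / γ_B(x_k−x_l)

For an axis-aligned box the set covariance is the product of clipped
sides, γ_B(v) = Π_k max(0, s_k − |v_k|). Pair counting uses a closed
inequality (distance ≤ d). The N² normalization makes the estimator low
by a factor (1 − 1/N); at the sample sizes here (N ≈ 100–420) this is
0.2–1%, well below Monte-Carlo noise, and it is applied identically to
data and simulations.

Distance grids run from 0 to 0.25 × (shortest box side) in 128 equal
steps by default. The translation correction degrades as γ_B → 0 when d
approaches the box dimensions, which motivates the 0.25 cap; the exact
plotted range in the source analyses is not stated, so this is a package
convention, exposed in configuration. Pairs with γ_B = 0 cannot occur for
d below the shortest side; they are excluded with a warning if a caller
ever constructs such a grid. When patterns from different windows share
an analysis (replicated tests, thinning cross-validation), the common
grid uses the smallest minimum side over all windows involved.

Besag's transform L(d) = (3K(d)/4π)^{1/3} maps the CSR closed form
K(d) = (4/3)πd³ onto the diagonal; regular (hard-core) patterns fall
below it at short range.

## RSA simulation

The null model for synapse placement is random sequential adsorption:
spheres with lognormally distributed Feret diameters are dropped
uniformly at random one at a time; a candidate that intersects any
accepted sphere is discarded, and a fresh location **and** a fresh
diameter are drawn; placement stops at the target count
round(λ · vol). Under the default `half_feret` convention a synapse is
the sphere circumscribing it, so two centroids may not lie closer than
(D_k + D_l)/2. The quoted description ("spheres whose radii follow the
lognormal distribution fitted using Feret's diameters") is ambiguous
between radius and diameter; since Feret's diameter is defined as a
diameter, `half_feret` is the default and `full_feret` is exposed as an
option and recorded in outputs.

A jamming guard aborts after a configurable number of consecutive
rejections (default 10 000) and reports the achieved count. At the
study's packing fractions (≈ 2–8%) jamming is never approached.

**Accepted-size bias.** Because rejected candidates resample their size,
large spheres are accepted less often and the realized diameters are
size-biased downward relative to the nominal lognormal law. The deficit
of the mean diameter grows with packing: measured ≈ 1% of the mean at
λ = 0.2 µm⁻³, ≈ 2.6% at 0.466, ≈ 3.9% at 0.87 and ≈ 4.9% at
λ = 1.4 µm⁻³ (nominal mean exp(µ + σ²/2) ≈ 401 nm). This is a property
of the algorithm as defined, not of the implementation; any analysis that
fits size laws to RSA output (e.g. the global model's pooled fit) inherits
it. Consumers comparing realized sizes against the nominal law should
expect this deficit; the test suite asserts its direction and magnitude.

Random thinning (`thin_to_intensity`) keeps a uniformly random subset of
round(λ_target · vol) points with their coordinates and diameters; a
subset of a non-overlapping set is non-overlapping, so the hard-core
property is inherited exactly, and uniform thinning leaves the K function
unchanged in expectation.

## Global envelope tests with leave-one-out parameters

Monte-Carlo goodness-of-fit tests are conservative when null parameters
are estimated from the tested sample itself. Testing sample j of layer i
therefore uses only the other m_i − 1 samples: the intensity is the
volume-weighted aggregate λ̂_ij = Σ_{t≠j} n_it / Σ_{t≠j} vol_it and the
size law is the lognormal ML fit (mean and population SD of log
diameters) of their pooled Feret diameters.

The envelope itself follows the two-batch construction: 99 null
simulations give the pointwise mean curve L̄; a disjoint batch of 99
simulations gives the constant half-width w_max = max over curves and
distances of |L_sim − L̄|; the null is rejected when the observed L
leaves L̄ ± w_max at any distance (two-sided — "outside the envelope"
covers both boundaries). Pointwise quantile envelopes are deliberately
not used. With batch sizes (n_c, n_e) the test is approximately
exchangeable, giving a type-I error near 1/(n_e + 1); at 99 + 99 this is
≈ 1%, and the test suite verifies ≤ 10% at a scaled-down 39 + 39.

## Replicated patterns and the group bootstrap test

Per-sample K curves on a common grid are aggregated per group with count
weights w_ij = n_ij (exponent configurable to 2). Groups are compared
with the functional statistic

    D = Σ_i W_i ∫ (√K̄_i(d) − √K̄(d))² dd,   W_i = Σ_j w_ij,

integrated by the trapezoid rule, the square root acting as the variance
stabilizer (same rationale as L). The null distribution is bootstrapped
from residual curves r_ij = √K̂_ij − √K̄_i, pooled across groups with
their weights, resampled with replacement and reattached around the
grand mean. Residuals around a weighted mean of m_i curves are variance-
deflated by (1 − w_ij/W_i); they are rescaled by the inverse square root
of that leverage before pooling, without which the bootstrap null of D is
shrunk and the test over-rejects (measured type-I error 0.15 instead of
0.09 at α = 0.05 with two groups of five replicates). The p-value is
(1 + #{D* ≥ D})/(1 + n_boot), with n_boot = 5000 by default.

The bootstrap treats residual curves as exchangeable. Replicates observed
in very different windows or with very different counts violate this
mildly; the one-vs-rest comparison of a two-sample group against 23
others shows a measured false-positive rate of ≈ 8% at nominal 5%.

## Thinning cross-validation

To test whether a set of layers is one RSA process observed at different
intensities: λ_global is set 1% above the maximum per-sample intensity
and rounded **up** to one decimal — rounding to nearest can land below
the densest sample's leave-one-out intensity, violating the defining
requirement λ_global > λ̂_ij, while the ceiling preserves it and yields
the same value (1.4) on the published table. The size law is fitted on
all member samples' pooled diameters. 198 dense simulations are generated
once in a 300 µm³ window (acquisition field of view, depth chosen to
volume; both configurable) and reused for every held-out sample; per
sample they are thinned to λ̂_ij, the first 99 giving the central curve
and the second 99 the width, and the held-out sample's L is tested
against that envelope.

Two intrinsic features of this procedure inflate its per-sample rejection
rate slightly above the nominal ≈ 1%: the observed sample lives in a
smaller window (≈ 140–280 µm³) than the simulations, so its L curve has
larger sampling variance than the curves that set w_max; and patterns
thinned from a denser RSA retain marginally more short-range structure
than RSA generated directly at the target intensity. On synthetic studies
the measured per-sample rejection rate is ≈ 5–8%, concentrated at
distances just beyond the hard-core range, consistent with the single
rejection in 23 samples reported in the source analysis.

## Synthetic studies

`synapstat.synth.generate_study` emulates the published design: six
layers with the published mean intensities (0.794, 1.098, 0.940, 1.222,
0.828, 0.466 µm⁻³), replicate counts (2, 3, 10, 3, 3, 4), a shared
lognormal size law (5.911, 0.404), and windows with the 7.6 × 5.7 µm
field of view and a whole number of 20 nm sections matched to the
published mean layer volumes. Animals are assigned round-robin so
animal-wise grouping is exercised. Each sample is an independent RSA
simulation, so per-sample counts are exactly round(λV) — real samples
additionally fluctuate in count, and real tissue contains features the
generator does not emulate (anisotropic z-resolution, segmentation error,
local inhomogeneity), so passing tests demonstrate correctness of the
statistical machinery under the model, not properties of real cortex.

A `core_scale` > 1 multiplies a layer's exclusion diameters (log-mean
shifted by log core_scale) at unchanged intensity, emulating a layer with
stronger repulsion. Packing fraction scales with core_scale³: at the
study's intensities scales beyond ≈ 1.7 approach RSA jamming and a ×3
scale is physically impossible, so contrast experiments use scales up to
1.6 (or larger scales at reduced intensity). The one-vs-rest group test
flags a scaled layer-I analogue with frequency rising from ≈ 8% (scale 1,
the false-positive rate) through ≈ 88% (scale 1.3) to ≈ 100% (scale 1.6).

## Density comparison

The subsampling box is the componentwise minimum of all sample windows.
Each of 50 draws per layer picks a sample uniformly with replacement and
a uniform box position inside it, and records count/volume. Layers are
compared with the tie-corrected Kruskal–Wallis test and pairwise
two-sided Mann–Whitney tests with Bonferroni adjustment (exact null
distribution for groups ≤ 8 without ties, tie-corrected normal
approximation otherwise, via scipy). A Levene homoscedasticity check is
computed report-only — its failure is the reason the pipeline is
rank-based — and the pipeline always proceeds rank-based. The same
functions accept any per-layer value lists, e.g. nearest-neighbour
distances (which are raw Euclidean distances, no edge correction, as in
descriptive summary tables).

## Numerical and testing choices

* All randomness flows through numpy Generators; pipeline stages spawn
  independent child seeds from one master seed, so every artifact is
  reproducible bit for bit.
* Simulation-heavy checks are scaled to desk size: envelope calibration
  at 39 + 39 over 200 repetitions, group-test calibration at n_boot = 199
  over 100 repetitions, pipeline-level checks pooled over four synthetic
  studies (full 99 + 99 envelopes, 198 dense simulations each).
* The CSR unbiasedness check compares the mean estimated K against
  (4/3)πd³ within three Monte-Carlo standard errors. At the smallest grid
  distances pair events are so rare that the sample SD across simulations
  collapses to zero; there the correct Monte-Carlo SE is the Poisson
  null SE built from the per-pair contribution 2·vol/N², and the check
  uses the larger of the two estimates. The L comparison propagates the
  same SE through the delta method (dL/dK = 1/(4πL²)).

## Known limitations

* The accepted-size deficit of RSA output (above) means realized mean
  diameters are 2.6–4.9% below the nominal lognormal mean across the
  study's intensity range; exact 2%-level agreement with the nominal mean
  is not attainable under the resample-on-rejection rule.
* The residual bootstrap assumes exchangeable residual curves across
  replicates; strongly unbalanced or heteroscedastic designs inflate its
  false-positive rate by a few percent.
* No periodic boundaries, inhomogeneous intensities, Gibbs/Strauss
  interactions, or pointwise-rank envelopes; asymmetric vs symmetric
  synapse types are not distinguished.
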