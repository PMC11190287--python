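# Methods

This note documents the models, conventions and numerical choices behind
`biotex`, and what its synthetic-data validation does and does not
demonstrate.

## Orientations, symmetry, misorientation

An orientation is the rotation mapping crystal coordinates into specimen
coordinates, stored as a scalar-first unit quaternion canonicalized to
`w >= 0`. Bunge Euler angles (φ1, Φ, φ2) in the Z–X–Z intrinsic convention
— the convention of the CTF and ANG vendor formats — describe the passive
specimen-to-crystal transform; the stored active rotation is its transpose.
File I/O uses degrees (CTF) or radians (ANG); everything internal is
quaternion algebra.

Apatite is treated with the 12 proper rotations of point group 622, the
rotational part of the hexagonal Laue class 6/mmm. Diffraction cannot
distinguish inversion-related orientations, so improper operations are
redundant for orientation statistics and are omitted from the quaternion
algebra. Default lattice parameters are fluorapatite a = 9.37 Å,
c = 6.88 Å, overridable per phase (the choice only affects
mixed-index direction families; <0001>, <10-10> and <11-20> are
insensitive to it).

The misorientation angle between two orientations minimizes the rotation
angle over symmetry-equivalent products. Because the rotation angle is
invariant under conjugation, minimizing over one-sided products `m·s` is
exactly equivalent to the two-sided `s1·m·s2` search; the test suite
nevertheless checks against the full two-sided brute force. For 622 the
maximum attainable misorientation is ≈ 93.84°, which the random-pair
supremum test reproduces.

## ODF model and Texture Index

The orientation distribution function is a kernel density on SO(3),

    f(g) = Σᵢ wᵢ · (1/12) Σ_s ψ_κ(ω(g, gᵢ·s)),     ψ_κ(ω) = C(κ)·cos^{2κ}(ω/2),

with the de la Vallée Poussin kernel ψ normalized to unit mass against the
normalized Haar measure: C(κ) = π / (2·B(κ + ½, 3/2)). The halfwidth
parameter is the half width at half maximum of ψ as a function of
misorientation angle; κ solves cos^{2κ}(hw/2) = ½, giving κ ≈ 568.75 at the
default 4° halfwidth. Symmetrization by averaging over the 12 group copies
keeps the total mass exactly 1.

The Texture Index TI = ∫ f(g)² dg equals 1 for the uniform distribution and
grows with preferred orientation. It is evaluated two independent ways:

* **Quadrature (default).** A deterministic midpoint grid on the Euler-angle
  fundamental box of 622 (φ1 ∈ [0,360), Φ ∈ [0,90], φ2 ∈ [0,60)) with the
  exact sin Φ Haar weights, at resolution min(2°, halfwidth/2). The grid is
  left-rotated by a fixed generic rotation — left multiplication commutes
  with the right symmetry action, so the rotated box is still a fundamental
  domain — which keeps the distorted cells near the Euler gimbal locus away
  from special orientations such as the identity. Kernel sums use a KD-tree
  over grid nodes with the kernel truncated where it falls below 10⁻³ of
  its peak; the truncation costs ≈ 0.3% of mass, well inside the quadrature
  tolerance. Symmetry copies of data points with no grid node in kernel
  range are dropped before the pair search.
* **Closed-form series (cross-check).** TI = Σᵢⱼ wᵢwⱼ·⟨A⟩ᵢⱼ with the kernel
  autocorrelation A(θ) = Σ_l ψ̂_l²/(2l+1)·χ_l(θ) computed from the Chebyshev
  (character) coefficients of ψ by 1-D Gauss–Legendre quadrature, and ⟨A⟩ᵢⱼ
  the mean of A over the 12 one-sided symmetry products of each pair. This
  route is grid-free and quadratic in the number of components.

The two routes agree to ≈ 10⁻⁴ relative; both are checked against a
Monte-Carlo integral of f² over Haar samples. A note on that oracle: for a
*single* 4° component the variance of f² makes a 10⁶-sample Monte-Carlo
estimate noisy at the several-percent level, so tight (2%) agreement checks
use mixtures of ~100 kernels, whose Monte-Carlo error is a few tenths of a
percent.

A kernel density built from n discrete orientations has expected TI
≈ TI_true + (∫ψ_sym²)/n ≈ TI_true + 709/n at 4° halfwidth. This
finite-sample inflation is not a bug: it is exactly the TI-versus-area
sampling bias the subsampling experiment quantifies.

## Pole figures, MUD, pfJ

Pole figures are spherical kernel densities of all symmetry-equivalent
specimen-frame directions of a Miller–Bravais family, antipodally
symmetrized (diffraction cannot sign a direction) and normalized so the
uniform distribution reads 1 (multiples of uniform density, MUD). The
spherical kernel is the sphere analogue of the same family,
(κ+1)·cos^{2κ}(θ/2), with the same halfwidth convention. The evaluation
grid is a spherical Fibonacci lattice (default 16384 nodes ≈ 1.6° spacing)
whose equal-area cells make quadrature weights uniform; pfJ is the mean of
MUD² over the grid. Very large direction sets are first accumulated on a
finer auxiliary lattice (≈ 0.9° spacing, far below the kernel width) to
bound the cost. Only crystal symmetry is applied — specimen symmetry is
triclinic, matching the asymmetric pole figures of real dental elements.

Sampling noise on MUD for a uniform fabric scales like √(κ/2n_eff), where
n_eff counts distinct equivalent directions; at n = 10⁴ orientations and 4°
halfwidth the pointwise standard deviation is ≈ 0.05–0.17 depending on the
family multiplicity. Uniform-limit tests therefore assert mean deviations,
and peak-deviation bounds were frozen from repeated Monte-Carlo runs per
family.

## Misorientation statistics and the M-index

Uncorrelated misorientation histograms draw seeded random distinct pixel
pairs (default cap 10⁵ pairs, 1° bins over [0°, 180°]). The random
(Mackenzie-type) reference for the symmetry is estimated once by seeded
Monte Carlo on 10⁶ independent Haar pairs and cached; two independent seeds
differ by < 0.005 total variation at that size, an order of magnitude below
the effects measured. The M-index is the discrete total-variation distance
M = ½ Σ|reference − observed|, 0 for a random fabric and → 1 for a single
crystal. Pairs are drawn from pixels, not reconstructed grains, because the
analysis applies no grain reconstruction to the texture data.

## Grain reconstruction diagnostics

Segmentation labels 4-connected components of indexed pixels whose neighbor
misorientation is below the threshold; grains smaller than 2 pixels are
then discarded and the labelling is applied once more, removing spurious
single-pixel grains. Labels are renumbered in raster order, so results are
platform-deterministic. The grain mean orientation is the principal
eigenvector of the quaternion outer-product sum after moving each member
into the symmetry branch of the grain's seed pixel. The fill step assigns
to each non-indexed pixel the mean orientation of its majority neighboring
grain, iterating inward so enclosed holes fill; regions touching no grain
stay non-indexed, and indexed pixels are never modified.

One caveat discovered during implementation: the number of grains is *not*
always non-increasing in the threshold once the sub-2-pixel discard rule is
active, because a pixel isolated at a low threshold can join or found a
surviving grain at a higher one. The coarsening property is asserted only
on fixtures where no sub-2-pixel grains occur; general correctness is
covered by an independent union-find oracle.

The threshold sweep (default 1°–17° in steps of 4°) reports, per threshold,
the grain count, median grain size and the fraction of grain-boundary
pixels adjacent to non-indexed pixels. On synthetic maps whose non-indexed
pixels are placed on patch borders — emulating beam-damage patterns — this
coincidence fraction exceeds 0.5, reproducing the demonstration that
inferred grain boundaries largely trace missing data, which is why grain
sizes are diagnostics here, never biological results.

## Subsampling and group statistics

The subsampling experiment places seeded random axis-aligned squares
(overlap allowed; a non-overlap mode exists) of several pixel sizes,
rejects squares with fewer than 100 indexed pixels, and computes TI,
M-index and optionally pfJ per square. Pearson correlation between TI and
area with a two-sided test of ρ = 0 quantifies the area sensitivity;
comparing index-versus-log-area slopes on a relative scale (slope divided
by the index mean) shows the M-index responding far less than TI.

Group comparisons are the tie-corrected Kruskal–Wallis H test (χ²
approximation, df = k − 1) and pairwise two-sample Wilcoxon rank-sum tests.
The Bonferroni divisor defaults to 6 — the number of samples, reproducing
the published analysis — although 6 groups form 15 pairs; the divisor is an
argument. At α = 0.05 the per-comparison level is 0.83% with 99.17%
confidence intervals; interval bounds for the location shift use the
Hodges–Lehmann construction (order statistics of all pairwise differences
at the normal-approximation rank cutoff).

## Raman ν₁-PO₄³⁻ screen

The symmetric phosphate stretch near 964 cm⁻¹ is fit over a 940–985 cm⁻¹
window (configurable) with a pseudo-Voigt sharing one FWHM between its
Gaussian and Lorentzian parts plus a linear baseline, which absorbs
fluorescence slope with two parameters. Initialization is deterministic
(argmax center, half-maximum width, end-point baseline), so fits are
reproducible. Recovery on synthetic spectra at SNR 50 is ≈ 0.01 cm⁻¹
(PCMI) and ≈ 0.03 cm⁻¹ (FWHM) median absolute error — an order of
magnitude below the 963.67–964.26 cm⁻¹ spread the screen interprets.
Proprietary acquisition software may parameterize the profile differently;
agreement with externally fitted parameters is expected at the ~0.1 cm⁻¹
level, not bit-exact.

Ranged major axis regression (model II, appropriate when both variables
carry error) rescales x and y by their observed ranges, takes the major
axis of the rescaled scatter, and back-transforms the slope by
range(y)/range(x); the line passes through the means and r² is the squared
Pearson correlation. Slope/intercept differences between two datasets are
judged by seeded case-resampling bootstrap (default 2000 resamples) at the
95% percentile interval.

## Synthetic-data generator

The generator emulates the texture archetypes observed in conodont hyaline
tissue, with every step a pure function of (recipe, seed):

* **c-axis**: a rotationally symmetric Fisher-type spread (tangent-plane
  Gaussian, exponential map) about the mean direction, default specimen X
  (the occlusal / denticle long axis), with per-taxon angular dispersion.
* **a-rotation**: the rotation angle about c on its 60° hexagonal period —
  uniform ("girdle"), wrapped-normal ("dispersed"), or a wrapped-normal
  mixture ("clustered", including the 3-cluster case).
* **Patches**: anisotropic Voronoi tessellation (distance stretched along a
  chosen elongation axis; default 12 × 4 px patches) gives spatially
  coherent elongated clusters whose long axes are decoupled from the
  crystallographic c-axis, as in the tissue. One orientation is drawn per
  patch; per-pixel noise adds a small random rotation.
* **Non-indexed pixels**: a recipe fraction (defaults 0.15–0.35, matching
  the 13–43% non-indexing of real acquisitions) is masked either at random
  or preferentially on patch borders.

The default six-step series tightens every dial monotonically
(c dispersion 16° → 3.5°, a-rotation from girdle through a 3-cluster stage
to a 3° cluster, patch noise 4° → 1.5°), so the generated
"biomineralization control" ranking is unambiguous. Whole-map TI then
spans roughly 15 to 220 across the series — bracketing the teens-to-90
range of real crown tissues, with the sharpest synthetic stage deliberately
beyond it so ordering tests have headroom.

What passing these tests shows: the estimators are calibrated at the
uniform limit, agree with independent oracles, and recover a known
monotone control signal and the finite-sample area bias under realistic
indexing gaps. What they do not show: robustness to spatially varying
indexing quality correlated with orientation, pseudo-symmetric misindexing,
instrument drift, or any feature of real diffraction-pattern quality — the
generator draws patches independently and masks pixels without reference
to orientation.

## Problem sizes used in validation

Acceptance-grade runs use 64 × 64 maps for the six-step series (10 seeds),
a 60 × 60 homogeneous map with 5 square sizes × 50 squares for the TI-area
experiment (10 seeds), 10⁴ orientations for uniform limits, 10⁶ Haar
samples for Monte-Carlo TI and the misorientation reference, and a
3 × 3 × 3 parameter grid at SNR 50 for Raman recovery — sizes chosen so the
statistical claims are sharp while a full validation pass stays cheap on a
single CPU.
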