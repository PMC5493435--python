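# Methods

## Harmonic polarity statistics

Profiles are grey values I₁…I_N at N arc-length-equidistant positions along
a closed cortical outline, mean-normalized (Iₖ ← Iₖ / mean). Sample k is
assigned the angle θₖ = 2πk/N; the polarization coefficient P and nematic
order parameter S are the magnitudes of the first and second circular
harmonics of the normalized profile (see README for the formulas). Both are
invariant to the profile's start index and traversal direction and to
overall intensity scale, which is what makes manual, arbitrarily started
outline traces comparable; the phase (P) and axis angle (S) do depend on the
start convention and are reported against the package-wide geometric origin
(the outline point in the anterior–posterior direction from the centroid,
angles clockwise-positive in the y-down image frame).

Numerical notes:

* Accumulation is plain double-precision dot products; the equality
  tolerance used in tests is 1e-9 relative.
* For nonnegative profiles 0 ≤ P, S ≤ 1, with P = 1 only for a
  single-sample delta. The uniform null is exactly 0 because Σ cos(mθₖ) = 0
  when N does not divide m; the default minimum N for S is 8 (below that the
  second harmonic is poorly posed against the first), and 3 for P.
* No noise-bias correction is applied. Harmonic magnitude estimators are
  positively biased under additive noise (E[P] > 0 on a noisy uniform ring,
  roughly σ/(mean·√(2N)) in scale); the statistic is kept exactly as defined
  and the bias is left to the experimental design (compare groups at
  comparable noise).
* P is **not** monotone in crescent concentration for arbitrary cortical
  baselines: for the crescent law below, P(κ) = Ae⁻ᵏI₁(κ)/(B + Ae⁻ᵏI₀(κ))
  peaks near κ ≈ 4 and then falls whenever the unmodulated cortex level B
  exceeds ≈ 5% of the crescent amplitude A, because a sharper crescent
  carries less total mass relative to the baseline ring. Monotone recovery
  (and the corresponding tests) therefore applies to crescent-dominated,
  background-corrected profiles.

## Profile extraction

The extraction pipeline replaces the manual freehand workflow: (1) outline
the cell as the 0.5 iso-contour of a binary mask, taken on a lightly
Gaussian-blurred indicator (σ = 1 px) so the rasterization staircase does
not alias into the harmonics — the analogue of a smooth hand trace; (2)
sample the image by bilinear interpolation at N arc-length-equidistant
points, averaging across a band normal to the outline (default width 3 px —
wider than a 1 px line and more robust to small outline error); (3) subtract
a background estimate, flooring at zero; (4) divide by the mean.

Background is estimated as the median grey value outside a 3 px dilation of
the cell mask. Background correction is applied before normalization for
both the P and the S pipelines, for internal consistency; the uncorrected
variant is available by passing background 0. The phase origin is found by
bisection on the signed angle of the outline around its centroid, so the
sampled profile is independent of the vertex-list order to ~1e-12 of an arc
unit. Coordinates are 0-based, y-down; arc length is reported in px unless a
µm-per-px scale is configured. N defaults to 100 samples per cell; because P
and S are means over samples of a smooth profile, they are insensitive to N
well below that (the closed-form examples in the tests use N = 36).

## Synthetic data generator

The generator emulates the three input families the analysis consumes.

**Cell images.** An elliptical cell (default semi-axes 32 × 26 px in a
128×128 16-bit frame, ~60 px diameter — typical pixel scales for a mitotic
SOP; the true values are not fixed by any convention, so they are exposed in
the spec) with three intensity zones: background, cytoplasm, and a cortical
ring of width 6 px centered on the ellipse boundary. The ring is rasterized
by first-order signed-distance thresholding with 1 px linear anti-aliasing;
the 6 px default keeps the 3 px sampling band away from the ring's
anti-aliased edges (a 4 px ring biases the band mean ≈ 5% low). Ring
intensity follows a von-Mises-shaped crescent law normalized to its peak,

    I(θ) = baseline + amplitude · exp(κ(cos(θ − μ) − 1)),

chosen because it gives a single concentration knob κ with an exactly
uniform limit at κ = 0; no claim is made that real crescents follow this
profile. Noise is additive Gaussian clipped at zero (Poisson shot noise is a
plausible alternative, not implemented as the default). The κ = 0 ring of
the rasterized image reproduces the closed form on the ring centerline to
< 2% relative error and survives the full extraction pipeline with a profile
CV < 2%.

**Division populations.** Division angles are wrapped-normal(mean, SD)
mapped into (−180°, 180°]; daughter intensity pairs are built from a
Beta(α, β)-distributed min/max ratio (mean α/(α+β)) applied to a bright
daughter intensity of 100 grey values with 10% lognormal scatter. Defaults
mirror the study conditions the package targets: n = 60 divisions per
genotype, angle SD 35° (control-like) with 68° as the dispersed comparison,
strongly asymmetric segregation (α, β = 2, 8). Companion cortical profiles
for a population (one per cell, concentration `polarization_kappa`,
amplitude 1000 over baseline 100 — a crescent-dominated regime — with noise
SD 30) come from `generate_population_profiles`; crescent centers are drawn
uniformly since the harmonic magnitudes are phase-invariant.

**Defect tables.** Genotype × category counts are independent multinomial
draws per genotype from caller-supplied probability vectors, emulating
per-wing bristle-defect scoring (e.g. 100 wings per genotype).

What the generator does **not** emulate: optical blur and PSF anisotropy,
photobleaching and focus drift, neighbouring cells and tissue context,
cell-shape irregularity beyond an ellipse, or any biological coupling
between crescent strength, segregation and division angle (the three draws
are independent). Tests passing on synthetic data therefore validate the
measurement arithmetic and its invariances, not segmentation robustness on
real micrographs.

## Division statistics

The segregation ratio is min/max of the daughter intensities, symmetric in
the daughters, 1 exactly on ties. The division angle is computed with atan2
(never modular arithmetic on raw degrees), clockwise-positive in the y-down
viewer frame, reported to 0.01°; negating the daughter axis (a daughter
relabeling) shifts the angle by 180°, re-wrapped. Angle dispersion is
summarized primarily by the arithmetic sample SD (n − 1 denominator) of the
signed angles — the form in which such SDs are conventionally reported for
this assay, and the only form that can reach values like 68° on (−180°,
180°] data — with the circular SD √(−2 ln R̄) reported alongside as the
statistically sounder companion. At SD 35° the wrapping bias of the
arithmetic SD is ≈ 1%, at 68° ≈ 2–3%; both are inside the Monte-Carlo
tolerances the tests use. The n − 1 denominator is a documented choice; at
n = 60 it differs from n by < 1%.

## Group tests

**Mann–Whitney.** U from midranks. For n_a + n_b ≤ 16 without ties, the p
value is exact over all C(n_a+n_b, n_a) labelings; the two-sided exact p is
2·min(tail probabilities) capped at 1 (conventions differ across software;
this one is symmetric and matches the enumeration definition). Otherwise the
normal approximation with tie and continuity corrections is used; an
all-tied input returns p = 1. The reported statistic is min(U_a, U_b).

**Freeman–Halton.** The exact test conditions on both margins; "as or more
extreme" means table probability ≤ the observed table's, compared with a
1e-12 relative tolerance so floating-point ordering cannot split
analytically tied tables. Hypergeometric weights use log-factorials
(lgamma), safe at totals of hundreds. The fixed-margin table space is
enumerated by recursive margin-constrained fill when a cheap upper bound
(products of row-composition counts) is ≤ 5·10⁶; above that a seeded
permutation Monte-Carlo (default 20 000 draws, add-one corrected) estimates
the same tail. A table with an all-zero row or column returns p = 1.0 with a
degeneracy flag rather than an error. On 2×2 tables the procedure reduces
exactly to two-sided Fisher; on r×c it matches R's `fisher.test` to the
printed precision in the frozen reference cases.

## Problem sizes in the test suite

The distributional checks use sizes chosen to make Monte-Carlo tolerances
meaningful at desk scale: 1000 random profiles for the invariance sweep,
1000 replicates of n = 60 for angle-SD recovery (tolerance 5% at SD 10°/35°,
10% at 68° where wrapping bias enters), 2000 simulated null tables (2
genotypes × 3 categories, n = 20 each) for the type-I bound of 6% at
α = 0.05, every 2×2 table with margins ≤ 12 for the Fisher equivalence, and
200 seeded replicates of the two-genotype n = 60 experiment for the power
check (p < 0.001 in ≥ 95% of replicates).

## Known limitations

* The outline must be a single, non-self-intersecting closed component; no
  automated SOP segmentation, tracking, or multi-channel handling.
* The phase origin assumes the centroid ray crosses the outline once in the
  A–P direction (true for convex and mildly non-convex cells).
* Arithmetic SD on circular data is biased toward 104° (the uniform limit)
  at large dispersions; the circular SD is the better statistic there and is
  always reported alongside.
* The Monte-Carlo Freeman–Halton path has sampling error ≈ √(p(1−p)/B); for
  borderline decisions raise `n_monte_carlo` or the enumeration threshold.
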