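# Methods

## Data model and conventions

Spectra live on strictly ascending wavenumber grids (cm⁻¹); files stored
instrument-style (4000 → 800 cm⁻¹) are flipped together with their
absorbances at ingestion so that every derivative and integral downstream
uses one convention. Region windows are closed intervals that select
actual grid points; window edges are never interpolated. The default
synthetic grid is 800–4000 cm⁻¹ at 2 cm⁻¹ spacing — the nominal
instrument resolution is 4 cm⁻¹ and stored spectra are typically ~2×
oversampled; the spacing is a convention of this package and is
configurable.

## Preprocessing

**EMSC.** Each raw spectrum is modeled by ordinary least squares as
*a* + *b*·m(ν) + Σₖ dₖ·νk̃ᵏ, where m is the reference (default: the set
mean), ν̃ is the wavenumber rescaled to [−1, 1], and the polynomial
order defaults to 2. The corrected spectrum is (raw − a − poly)/b. A
gain b ≤ 10⁻⁶ is rejected as unrelated to the reference; a constant
reference is rejected as collinear with the offset column. No
interferent/constituent spectra are included in the design — the plain
additive+multiplicative model is the v1 scope.

**SNV** centres each spectrum to mean 0 and scales to sample standard
deviation 1 (n−1 denominator, the chemometrics convention — stated so
tests can be exact). **Unit-vector** normalization divides by the
Euclidean norm.

**Rubber band** is the lower convex hull of the (ν, A) point set
(Andrew monotone chain), evaluated between hull vertices by linear
interpolation and subtracted; the output is ≥ 0 and vanishes at the
hull vertices. No iterative refinement — the hull is the canonical
definition.

**Savitzky–Golay** derivatives use a 9-point window and third polynomial
order by default and require an equally spaced grid (10⁻⁶ relative).
The (window−1)/2 points at each end are flagged invalid
(`meta['sg_edge']`) rather than padded: padding fabricates curvature
that corrupts minima detection near region edges. Peak/minima detection
excludes the flagged edges.

Two documented preprocessing chains feed PCA: `emsc_snv` for the
fingerprint and lipid regions, and `emsc_d2_uvn` (EMSC, SG second
derivative, unit-vector) for the DNA region.

## PCA

Mean-centered (not variance-scaled — spectra arrive normalized), via
SVD. Loadings are orthonormal; the sign of each loading is fixed by
making its largest-magnitude element positive, so scores and loadings
are reproducible. Explained-variance fractions are singular values
squared over total centered variance. k = 3 components by default,
matching the PC-1..PC-3 scope of the analyses this supports. A
brute-force covariance eigendecomposition serves as the test oracle.

## Amide-I deconvolution

Procedure, in order: (1) average the group's spectra over
1700–1600 cm⁻¹; (2) subtract the straight line through the window-end
absorbances; (3) unit-vector normalize; (4) compute the SG second
derivative and assign the five component centers to local minima within
±8 cm⁻¹ of the nominal values (1610/1630/1652/1682/1690 cm⁻¹), choosing
the *nearest* minimum when several exist and falling back to the
nominal center (with a flag) when none exists; (5) fit five Gaussians
by bound-constrained least squares (`scipy.optimize.least_squares`,
analytic Jacobian): heights ≥ 0, widths σ ∈ [3, 25] cm⁻¹, centers
bounded ±4 cm⁻¹ around the assigned values — bounded rather than fixed
because real minima drift, and the bound prevents label swapping.
Heights are initialized by non-negative least squares on the
fixed-width Gaussian basis; the fit is multi-started over
σ₀ ∈ {5, 10, 15} cm⁻¹ and the lowest ΣError² kept (no randomness).
(6) Areas are computed analytically as h·σ·√(2π) — exact for the model
being fit; ∫α/∫β divides the α-helix area by the 1630 cm⁻¹ β-sheet
area only (`beta_denominator="all_beta"` pools all β forms instead). A
β area below 10⁻⁶ of the total flags the ratio undefined rather than
returning an infinity.

ΣError² is evaluated on the baseline-corrected, unit-vector-normalized
spectrum (the procedure order implies this normalization; magnitudes
around 10⁻⁴–10⁻⁷ on unit-norm data).

**Reference recovery profiles.** For recovery experiments,
`reference_amide_profile` builds a noiseless five-Gaussian profile with
a programmed α/β area ratio: σ = 12 cm⁻¹ for the α-helix, 8 cm⁻¹ for
all other components, minor components at 0.02/0.05/0.02 of the β area.
Two hazards of the procedure drove these choices. First, the
endpoint-anchored baseline subtracts whatever real band intensity
reaches the window ends; keeping the edge components small makes the
profile ≈ 0 there, so step (2) removes (almost) nothing real. Second,
in strongly α-dominated compositions the α shoulder shifts the β-sheet
second-derivative minimum several cm⁻¹ low, and the ±4 cm⁻¹ fit bound
around a badly assigned center can exclude the true 1630 cm⁻¹ center; a
broad α against a sharp β keeps the assignment within ~1 cm⁻¹. These
widths are a fixed property of the reference construction, not fitted
quantities.

## Band metrics

`band_integral` is the trapezoid over grid points inside the closed
window; `local_linear` mode first subtracts the chord through the
window-endpoint samples. The **B–H index** integrates 2620–2460 cm⁻¹
above a local baseline anchored on the *means of the outer five
samples* at each end of the window: a chord hung on two single noisy
samples contributes ~σ·width of integral noise, dominating everything
else, while averaged anchors cost nothing (the doublet tails are
negligible at the window ends) and cut that term ~√5-fold. The
detection floor is 3× the propagated standard deviation of the integral
under the window's estimated point noise (noise estimated from second
differences, insensitive to smooth bands; propagation uses the exact
linear weights of the integral-minus-chord operation). Values below the
floor report as 0 — this makes "below detection" operational for
untreated cells.

The **unsaturation index** ratios the local-baseline band integrals of
the olefinic =C–H band (3010 ± 10 cm⁻¹) and the CH₂ symmetric stretch
(2850 ± 10 cm⁻¹); the ±10 cm⁻¹ windows are package defaults (narrow
enough to isolate the bands, wide enough for σ ≈ 8 cm⁻¹ components) and
configurable. The **CH₃/CH₂ ratio** takes maxima within ±4 cm⁻¹ of
2960 and 2921 cm⁻¹.

`integrate_map_band` produces the per-pixel band-integral image of a
raster; the hotspot is the argmax (row-major first occurrence on ties,
flagged), the centroid weights pixel coordinates by non-negative
intensity, and an optional mask yields the fraction of intensity inside
it. Whether maps should be integrated on raw or baseline-corrected
pixels is not standardized; `local_linear` is the default and recorded.

## Synthetic generator

Each cell spectrum is a sum of Gaussian component bands (protein amide
I/II, DNA phosphate bands, lipid CH stretches, the B–H doublet at
2557/2537 cm⁻¹ and the cluster C–H at 3031 cm⁻¹), modulated by:
per-group multiplicative effect factors; per-cell lognormal amplitude
jitter (sd 0.1 — enough structure for EMSC to have work to do, small
enough for recovery); a random quadratic baseline (coefficient ranges
±0.05/±0.02/±0.01 on the rescaled axis); a multiplicative scatter
transform a + b·(·) with b ∈ [0.7, 1.3]; and additive Gaussian noise
(sd 0.005 AU). A single seeded `numpy` Generator drives all draws in a
documented order (per cell: band jitters in library order, baseline
coefficients, scatter offset and gain, noise vector), so outputs are
bit-reproducible from the seed.

Group effects encode the studied directions of change: control groups
carry B–H factors of exactly 0; treated groups gain the doublet
(dose-monotonic), shift the α/β amide-I balance, reduce olefinic
intensity; the mesenchymal line additionally shifts CH₂/CH₃ intensity.
The *magnitudes* are conventions of this generator — no effect sizes are
published for these changes — and are configuration, not constants.

What the generator does **not** emulate: Mie and resonant-Mie
scattering, water-vapor lines, detector nonlinearity, and realistic
covariance between distant bands (jitter is per-band independent).
Passing tests therefore demonstrate correctness of the analysis chain
under the stated noise model, not robustness to every artifact of real
acquisitions.

Hyperspectral maps scale the B–H bands by a radial Gaussian profile
(σ = nucleus radius / 2) at a programmed nucleus centre, the other bands
by a wider cell-body profile, and add baseline + noise per pixel;
the returned mask marks pixels within the nucleus radius.

## Statistics

Group comparisons use the two-sided Welch t-test (no equal-variance
assumption; a pooled-variance flag exists). Two constant equal samples
return t = 0, p = 1 by convention. Stars at p < 0.05/0.01/0.001 with
strict inequalities (p = 0.05 is not significant). No multiple-testing
correction is applied by default, matching the per-band reporting
convention this mirrors; a Bonferroni option can be layered by callers.
Viability percent implements
(A570 sample − A570 blank)/(A570 control − A570 blank) × 100 exactly.

## Problem sizes and determinism

Default test and example sizes — 1601-point grids, 10–50 cells per
group, 11×11 to 21×21 rasters, 5–20 replicate seeds — were chosen so the
full suite runs in seconds while keeping every statistical check
well-powered. The pipeline writes all tables with fixed float formatting
and records the config digest, seed and package version in a manifest;
rerunning with the same config and seed reproduces every table
byte-for-byte.

## Known limitations

* The JCAMP-DX reader covers only the affine-scaled `(X++(Y..Y))` AFFN
  layout; compressed (SQZ/DIF/DUP) files and multi-spectra blocks are
  out of scope, as are OPUS/SPC/ENVI binaries.
* The deconvolution model is Gaussian-only (no Voigt/Lorentzian), and
  the endpoint-anchored linear baseline makes fitted areas sensitive to
  band intensity at the window ends; results on profiles with heavy
  spectral weight at 1600/1700 cm⁻¹ carry a systematic that the
  five-Gaussian model partially absorbs into the edge components.
* EMSC without interferent spectra cannot separate chemical from
  physical variation when they are collinear.
* Band metrics assume the drug window is free of organic absorption;
  strongly scattering samples violate this.
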