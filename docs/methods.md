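# Methods

This note documents the models, algorithms, and numerical choices behind
`petbench`, including the points where the design was genuinely open and
the package had to commit to one concretization.

## Domain model and coordinate conventions

Images, masks and studies live on a shared axis-aligned voxel grid. Voxel
indices are 0-based and the physical position (mm) of the *center* of
voxel (i, j, k) is `origin + index * spacing`. All distances — expansions,
Hausdorff distances, centroid errors — are computed in physical
millimetres, so anisotropic voxels behave correctly; Hausdorff distances
and uncertainty-volume thicknesses are reported in cm, volume/uptake
errors in percent. Oblique (non-axis-aligned) DICOM or NIfTI orientations
are rejected rather than resampled: every contour in a study must live on
the PET grid itself, and silent resampling would change the metrics being
benchmarked.

Masks produced anywhere in the package carry their source image's spacing,
origin and frame identifier unchanged (geometry propagation), and this is
property-tested.

## Metrics

Level I errors are signed fractional differences ×100; positive volume
error means over-segmentation. The center of mass is the *unweighted*
binary-mask centroid by default; an intensity-weighted variant is
available behind a flag because the conventional definition on masks alone
does not involve the image.

The modified Hausdorff distance needs a definition of "point on the
contour". We use the physical centers of boundary voxels, where a boundary
voxel is a mask voxel with at least one face-adjacent (6-connectivity)
outside neighbor and the volume border counts as outside. This is
deterministic, cheap (KD-tree nearest-neighbor queries), and exactly
checkable against a brute-force double loop.

The delineation-uncertainty-volume thickness divides the DUV volume
(voxel count × voxel volume) by the surface area of the *reference*
contour, measured as the total area of exposed voxel faces. Normalizing by
the reference (rather than the test contour or some average surface) keeps
the quantity well defined when the test contour is badly wrong, at the
cost of slightly overestimating thickness for expansions. This
normalization is a package choice; only the intent ("average thickness of
the uncertainty volume") is standard.

Empty-test-mask policy: volume error = −100 %, DSC = S = 0; PPV, uptake
errors, centroid and Hausdorff distances are *undefined* (empty
denominators or arg-mins) and are recorded as missing with a reason —
never as 0, which would bias summary statistics toward better-looking
agreement limits.

## Segmentation methods

All methods operate inside a user search region (lesion bounding box plus
margin; the default helper uses a 15 mm margin) and share one
post-processing step: keep the 26-connected component containing the
region maximum (or the largest, if the anchor fell outside), fill fully
enclosed holes, clip to the region. On noiseless two-valued phantoms every
method recovers the object exactly; this is the suite's strongest sanity
anchor.

Parameters that matter, with defaults:

- **FT** fraction (42 or 50 % of region max are the common choices).
- **SBR**: threshold T = B̄ + θ(SBR)(S̄ − B̄) with S̄ = mean of voxels
  ≥ 90 % of max, B̄ = background-shell mean, θ(SBR) = a + b/SBR. The
  constants (a, b) are scanner- and reconstruction-specific, so they are
  *fitted* on phantom studies (`calibrate_sbr`: per-case optimal θ by
  bisection, then least squares against 1/SBR) rather than hard-coded.
  When no background shell is supplied one is built automatically as the
  ring between the 2- and 4-voxel dilations of the 70 %-of-max core.
- **AT**: fixed point of T ← B̄ + ε(mean inside mask − B̄), ε = 0.5,
  initialized from the 40 % mask, max 50 iterations; ε = 1 degenerates to
  thresholding at the object mean and is permitted but flagged in the
  docstring.
- **RG**: descending thresholds 95 → 10 % of max in 5 % steps; the
  connected component of the seed is tracked and growth stops before the
  component touches the region boundary or before a step-to-step volume
  ratio exceeds `jump_factor` (1.5). The jump test engages only once the
  component holds ≥ 20 voxels: below that, ratios are discretization
  artifacts (a 2-voxel component tripling is not a flood), and without the
  guard a single hot noise voxel freezes growth immediately.
- **KM/GMM/GCM**: intensity clustering with seeded initialization
  (k-means n_init = 10; EM with k-means init, reg_covar 1e−8). Tumor =
  highest-mean cluster/component (posterior ≥ 0.5 for GMM). GCM selects
  the component count in {2, 3, 4} by BIC.
- **WC/WT**: the image is Gaussian-smoothed (σ = 1 voxel by default),
  the gradient magnitude is computed in physical units, markers are the
  6-connected local-minima plateaus, and the watershed basins are
  clustered into two groups by mean intensity (seeded k-means); the tumor
  is the high group's component containing the maximum. Smoothing the
  *image* rather than the gradient keeps the edge inflection — and hence
  the watershed line — in place while suppressing spurious noise ridges.
  Markers use 6-connectivity because the ridge separating two plateaus
  can be a single voxel wide, which 26-connectivity would leak across.
  A single-basin result falls back to FT40 with a warning.

All stochastic methods take an explicit seed and are bit-reproducible;
automatic methods are expected to be 100 % reproducible, so this is a hard
requirement, not a convenience.

## Contour perturbations

Isotropic expansion/shrinkage threshold the Euclidean distance transform
computed with the grid spacing as sampling (distances between voxel
centers). The iso-volumetric deformation picks a seeded random direction,
splits the mask at its centroid into two half-space caps, dilates one cap
by the requested depth and erodes the opposite cap boundary-inward —
removing voxels in order of increasing interior depth, ties broken by flat
index — until exactly as many voxels are removed as were added. This is
the deterministic limit of bisecting an erosion depth to a volume
tolerance: the volume is preserved *exactly* (trivially within the 0.5 %
tolerance, which is still checked) while the shape changes. The default
depth is 0.2 cm, small enough that the erosion cap of a 1–2 cm lesion can
balance the dilation; on grids coarser than the requested depth the
deformation is at least one voxel layer deep so it never degenerates to
the identity. The exact local procedure and its tolerance are package
choices; only the intent (change geometry, preserve volume) is standard.

The standard specificity suite holds eight labeled contours: the RC
itself, a 0.5 cm shrinkage, expansions of 0.25/0.35/0.45/0.5/1.0 cm, and
the iso-volumetric deformation. Expected signatures, all property-tested:
expansions have S = 1, PPV < 1, positive volume error growing with
distance and strictly decreasing DSC; the shrinkage has PPV = 1 and
negative volume error; the deformation has (near-)zero volume error but
DSC < 1 — volume error alone cannot see it, which is exactly why the
suite contains it.

## Simulator

The simulation chain is: activity phantom → Gaussian PSF blur (image
space) → slice-wise parallel-beam projection → count scaling + uniform
scatter/randoms + Poisson draw → FBP or OSEM reconstruction.

Assumptions and simplifications, in decreasing order of importance:

- **2-D slice-wise geometry.** Each axial slice is projected and
  reconstructed independently with a parallel-beam geometry; no fully 3-D
  scanner model, no detector effects beyond the Gaussian PSF. This is
  sufficient to produce count-dependent noise, reconstruction-dependent
  texture and partial-volume blur — the phenomenology a segmentation
  benchmark needs — at desk scale.
- **No attenuation;** scatter and randoms are uniform additive sinogram
  components with configurable fractions (defaults 0.10 and 0.05). Their
  expected total makes the overall expected count
  counts_target/(1 − sf − rf).
- **PSF** is an isotropic Gaussian (default FWHM 5 mm, a typical clinical
  reconstruction resolution), applied pre-projection and — when
  `psf_in_recon` — inside the OSEM system operator and its adjoint.

The projector is an explicit sparse matrix (pixel-driven, linear
interpolation onto detector bins; bin width = pixel size). Each pixel's
interpolation weights sum to one at every angle, so per-angle mass is
conserved exactly, and the OSEM forward/backprojection pair is exactly
adjoint — both properties are asserted in tests, and the projector is
cross-checked against `skimage.transform.radon` on a smooth slice. FBP
uses an FFT ramp filter with the additive component pre-subtracted;
because activity is non-negative by construction, the FBP output's small
negative ripples are clipped at zero. OSEM uses multiplicative updates
over interleaved angle subsets (default 4 iterations × 6 subsets) with
the additive expectation inside the denominator, initialised from a
uniform positive image.

The reference contour of a simulated tumor is the support of uptake
strictly above background in the *original* activity map — absolute
truth, unaffected by PSF or noise. For two-level (core/rim) tumors, the
RC covers the whole tumor, not just the hot core.

**Count level.** The default suite uses counts_target = 1e6 expected true
counts for a 32×32×16 field of view, chosen so that reconstructed images
show clearly visible but clinically plausible noise: segmentation methods
score mean DSC ≈ 0.7–0.96 on the standard sphere suite, a spread
comparable to published method panels. Far lower counts produce images in
which no method is usable, which would test noise rather than
segmentation.

**What the generator does not emulate:** anatomical background texture
and organ boundaries, attenuation/scatter spatial structure, respiratory
motion, heterogeneous real tracer distributions, inter-scanner
variability. Passing the suite therefore demonstrates correctness of the
benchmark machinery and robustness to tomographic noise/blur — not
clinical performance on patient data.

## Evaluation harness and statistics

The result table holds one row per (study, method, metric), with missing
values carried explicitly. Summaries over studies use the absolute value
of signed error metrics (a method that over-segments half the time and
under-segments the other half is not a good method). Standard deviations
are sample SDs (ddof = 1) throughout: the published eight-method
cross-panel SD of mean absolute volume errors {27, 21, 60, 61, 42, 70,
39, 42} is 17.15 ≈ 17 under this convention (the population convention
would give 16.0).

Agreement limits are median ± 1 SD of per-method means, with the
better-performance side clamped to the metric's best achievable value:
lower = 0 for error/distance metrics (the published volume-error example
clamps 42 − 17 = 25 down to 0), upper = 1 for DSC/S/PPV. The clamping
side per metric ships as a registry in the metric definitions.
Containment is boundary-inclusive and uses |value| for signed errors.
Global summaries and ALs only include methods with a complete run (every
study × every metric) — a guard against cherry-picking favourable cases.

Robustness along an axis (acquisition instance, reconstruction, voxel
sampling, lesion geometry) is the mean over lesions of the per-lesion SD
of a metric across the studies differing only along that axis; lesion
identity is (dataset, reference-contour label). Discriminative power is
the range and SD of per-method means, also expressed as a percentage of
the median.

Reports (Local for one study, Global for a database) are rendered as
Markdown or print-ready HTML with pandas tables and matplotlib bar plots;
the output is a pure function of the inputs (no timestamps), so
regenerated reports are byte-identical.

## Problem sizes

The test suite and the acceptance script use 32×32×16 grids at 4 mm
(suites of up to 50 studies) and 64×64×40 grids at 2 mm for the
perturbation analyses; metric oracle checks run on 10³-voxel grids. These
sizes keep a full run in the tens of seconds while leaving every
phenomenon of interest (partial volume, noise, digitization) clearly
expressed.

## Known limitations

- Dose/outcome-level ("Level III") metrics are out of scope.
- No multi-rater consensus metrics (STAPLE-like); one reference contour
  (or an indexed list) per study.
- RTSTRUCT rasterization assumes simple (non-self-intersecting) planar
  polygons; even-odd holes across multiple rings on a slice are
  supported, boundary voxel centers count as inside.
- The SBR calibration requires phantom cases spanning a range of SBR
  values; with a single case the least-squares fit is underdetermined.
- FBP at very low counts can clip a substantial negative fraction,
  biasing background means upward; OSEM is the default for noisy suites.
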