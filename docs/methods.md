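# Methods

This note documents the models implemented in `fastpet`, the
assumptions behind them, the defaults and why they were chosen, and
what the synthetic phantoms do and do not establish about real data.

## Geometry model

The scanner is described entirely in sinogram coordinates: a line of
response (LOR) is (radial offset, azimuthal view, axial plane[, TOF
bin]).  The Vision-600 preset carries the published data dimensioning
(520 × 50 × 815 × 33, span 19) and field of view (72.6 × 72.6 ×
26.2 cm³ on a 440 × 440 × 159 grid of 1.65 × 1.65 × 1.646 mm voxels).
Crystal-level details (ring count, pitch, gaps, dead time,
depth-of-interaction) are deliberately out of scope: every pipeline
stage consumes and produces sinograms, so the sinogram format is a
complete geometry description for this purpose.

Two modelling choices follow from information that the dimensioning
alone cannot provide:

* **Axial planes.** The michelogram segment structure implied by span
  compression cannot be reconstructed from the plane count without the
  ring count, so the 815 planes are laid out uniformly over the axial
  FOV and each behaves as a direct plane at its own axial position.
  Axial obliqueness lost to span compression is absorbed by the
  pre-smoothing kernel.  Consequence: axial resolution of the model is
  slightly optimistic, and per-segment effects are not representable.
* **TOF timing.** TOF bin width (169 ps) and coincidence timing
  resolution (210 ps FWHM) are typical Vision values, exposed as plain
  config fields because they are not part of the dimensioning.

`make_scaled_geometry(scale)` shrinks every count (round half up,
minimum 1, TOF bins forced odd) while preserving the physical FOV, so
desk-scale runs exercise the identical code path with coarser
sampling.  At scale 0.25 the view count (13) is not divisible by the
common 5-subset protocol; since OSEM does not require balanced subsets
(each subset normalizes by its own sensitivity image `Aᵀ_u 1`), the
reconstructor accepts unbalanced view-interleaved subsets and warns
instead of refusing.

## Projector

Joseph's method: each ray is stepped along its dominant axis and
sampled by linear interpolation along the other, ties broken toward x;
radial spacing is FOV/n_projections and views cover [0, π) uniformly.
Per view the operator is materialized as a sparse matrix, so the back
projector is its exact transpose — adjointness holds to machine
precision, which makes the EM monotonicity guarantee testable rather
than approximate.

Two normalizations coexist:

* raw line integrals in mm (used for attenuation factors,
  `exp(−0.1 · ∫μ dl)` with μ in cm⁻¹);
* a counts-preserving form `A·diag(1/c)` with `c = Aᵀ1`, under which
  the total sinogram equals the total image for any non-negative image
  inside the sampled bore.  This convention is what gives the
  sensitivity calibration its exact meaning: a non-attenuated source
  of `K` kBq scanned for `T` s yields exactly `S·K·T` true counts.

TOF spreads each ray contribution over bins with a Gaussian centered
on the emission point's position along the LOR (σ from the timing
resolution), truncated at ±3σ and renormalized per contribution, so
the TOF-summed operator equals the non-TOF operator exactly.

## Simulation chain and calibration

Steps: pre-smooth → Bq/ml-to-decays → project → attenuate → scale by
sensitivity → add uniform randoms → add scatter → denormalize → sum to
noise-free prompts → Poisson sample prompts and an independent
delayed-window sinogram.  Everything before the Poisson step is linear
in acquisition time, sensitivity and global activity scale; the NEMA
experiment driver exploits this by simulating once at T = 1 s and
rescaling per count level.

Calibration defaults (all config-exposed):

| parameter | default | meaning |
|---|---|---|
| sensitivity | 38 cps/kBq | true counts per kBq·s for a non-attenuated source |
| random rate | 0.20 | Σrandoms / Σtrues; randoms uniform in projection space |
| pre-smooth FWHM | 3.0 mm | isotropic Gaussian, σ = FWHM/2.3548 per axis in voxels |
| scatter fraction | 0.30 | Σscatter / Σprompts after scaling (see below) |

The random rate is held fixed across activity levels — a known
simplification of this class of simulator; real randoms vary with the
singles rate.  The delayed window is Poisson-sampled independently of
the noisy prompts, as a physical delayed-window acquisition would be.
Component-based normalization is modelled as uniform, so the
denormalize step defaults to the identity (it cancels between
simulation and reconstruction); a bin-wise normalization sinogram can
be supplied.

`calibrate_sensitivity` is closed-form (counts are linear in S).
`calibrate_presmooth` grid-searches the FWHM by simulating and
reconstructing the NEMA phantom per candidate and minimizing the sum
of squared recovery-coefficient differences against a reference; it is
noise-free and therefore deterministic, and reports the objective for
every candidate as an audit trail.

## Scatter

Watson-style single-scatter simulation in 2D per slice: scatter points
are a deterministic stride over voxels with μ > 0.005 cm⁻¹ (default
500 per slice); for each LOR and point, the contribution is (emission
integral along one leg) × (attenuation survival of both legs) × μ(P) ×
Klein–Nishina cross-section at the scattering angle × energy-window
acceptance (default 435–585 keV, a typical Vision window) × inverse
square of both leg lengths, summed over both leg assignments.  Leg
integrals are precomputed on a detector-angle table (4 × n_views
samples, 64 path samples) and interpolated per LOR.  The per-slice
estimates are expanded axially by inverse single-slice rebinning
(linear interpolation between slice positions) and smoothed by a small
Gaussian in sinogram space (default 3 bins FWHM).

Absolute scaling of a scatter estimate requires detector-efficiency
data that only vendor software has; `scale_scatter` therefore scales
globally to a configurable scatter fraction (default 0.30) and offers
an `"absolute"` pass-through.  Multiple scatter, out-of-FOV scatter
and energy-resolution modelling beyond the window acceptance are out
of scope.  With TOF on, scatter is spread uniformly over TOF bins (the
conservative choice; totals are preserved).

## Reconstruction

Ordinary-Poisson OSEM with randoms and scatter as additive terms and
attenuation inside the system matrix.  Declared numerical policy
(these are choices, not inferences about any vendor implementation):
initialization x₀ = 1 inside the sampled FOV; division guard
ε = 10⁻¹⁰ × mean(prompts); voxels with zero subset sensitivity are
masked to 0 with a warning; subsets are view-interleaved (view j →
subset j mod n); optional PSF is an isotropic image-space Gaussian
applied inside both A and Aᵀ; an optional Gaussian post-filter is
applied once at the end.  Reconstructed images are in counts per voxel
and are converted to Bq/ml by `counts_to_activity`
(× 1000 / (S · v_ml · T)).

## Phantoms

**NEMA IQ.** Six spheres (inner diameters 10/13/17/22/28/37 mm, wall
thickness ignored) centered 57.2 mm from the axis on one transaxial
plane, in a D-shaped body — a circular cylinder of 180 mm interior
length chamfered flat at y = −0.7 R — whose radius is solved so the
cavity volume is 9575 ml (R ≈ 136.7 mm).  Attenuation is water
(0.096 cm⁻¹) inside the shell, zero outside; the physical phantom's
lung insert is omitted to match that simplified attenuation
description.  Default concentrations 2930 / 27 369 Bq/ml give the
9.34:1 sphere-to-background ratio.  Rasterization supersamples each
voxel (default 3³) so edge voxels carry volume-weighted mixtures; the
exact sphere plane position and body length are not standardized by
the inputs available here and follow NU-2 conventions,
config-overridable.

**Synthetic torso.** An elliptic-cylinder body (soft tissue,
3000 Bq/ml), two low-density lungs (0.03 cm⁻¹, 500 Bq/ml), liver
(7000), spleen (5500), spine (0.15 cm⁻¹, 1500), plus spherical lesions
defined by (center, diameter, uptake ratio over the local background).
A seeded log-normal texture (σ = 0.12 of log-intensity, smoothed over
1.5 voxels, mean-corrected) multiplies the activity inside the body.
Organ values are plausible 5-minute-frame FDG concentrations chosen
once as generator defaults; they are not fitted to any patient data.
The torso reproduces heterogeneous uptake, organ-boundary contrast and
lesion partial-volume behaviour, but not respiratory motion, bone
marrow, patient-specific anatomy or CT-derived attenuation — so
pipeline results on it demonstrate internal consistency of the
simulator, not clinical performance.

## Evaluation stack

* RC = mean(image over exact sphere ROI)/true concentration; sphere
  ROIs collect voxel centers inside the true sphere (falling back to
  the nearest voxel when a sphere is sub-voxel at desk scale).
* Background ROI: annulus of 80–95 mm about the phantom axis on the
  sphere plane ± 2 slices.  The inner radius clears
  the sphere ring (57.2 + 18.5 = 75.7 mm) and the outer stays inside
  the body chamfer plane (−0.7 R = −95.7 mm); an annulus that
  intersects a sphere ROI raises an error.
* COV = population SD / mean inside a ROI; voxel-wise mean/STD maps
  across realizations; Freedman–Diaconis histograms (bin width
  2·IQR·n^(−1/3), linear-interpolation quantiles, single-bin fallback
  for degenerate IQR).
* Intensity features: peak (mean over in-ROI voxel centers within a
  1 cm³ sphere centered on the hottest ROI voxel, ties to the lowest
  linear index), mean, median, biased-moment skewness m₃/m₂^1.5
  (defined as 0 for constant ROIs), COV.
* GLCM features: grey levels ⌊v/bin width⌋+1 anchored at absolute 0;
  symmetric distance-1 co-occurrences per transaxial slice in the four
  planar directions, counting only pairs fully inside the ROI; counts
  pooled over slices per direction before normalization; joint
  average, joint entropy (bits), energy, homogeneity (inverse
  difference), correlation (1 for constant ROIs), averaged over
  directions.  The bin width is in the caller's image units; with
  images in Bq/ml the concordance experiment uses 100, which yields
  50–300 grey levels at clinical-range concentrations.  A literal
  100 kBq/ml width would collapse clinical-range images to one grey
  level and make every texture feature degenerate.
* Paired features are compared by OLS with t-based 95% CIs plus the
  Pearson correlation.

## Segmentation concordance

Overlap metrics use the Taha–Hanbury forms, including
VS = 1 − |FP−FN|/(2TP+FP+FN).  MCC is computed over the union bounding
box padded by 5 voxels by default so the true-negative count does not
swamp the statistic on large grids (full-volume mode available).
STAPLE: EM with a spatially uniform prior equal to the mean foreground
fraction, rater sensitivities/specificities initialized at 1 − 10⁻⁵
and clipped into (10⁻⁵, 1 − 10⁻⁵), convergence on the maximum
parameter change (10⁻⁶) or 100 iterations; these hyperparameters are
declared choices.  Shape features: volume = voxel count × voxel
volume; surface area from a marching-cubes isosurface of the mask
lightly smoothed with a 1-voxel Gaussian (suppressing the staircase
bias of a binary isosurface); axis lengths 2·√(5 λₖ) from the
eigenvalues of the foreground-coordinate covariance, the scaling that
recovers the exact diameters of solid ellipsoids in the continuum
limit (a pure-Gaussian convention of 4·√λ would understate a solid
sphere's diameter by ~11%).  Lin's CCC uses population moments.

In the concordance experiment, lesion masks are auto-thresholded at
40% of the local peak (connected component containing the lesion
center within a local box); this is a stand-in for human analysts and
is labelled as such in every report manifest.

## Problem sizes and determinism

Desk-scale defaults (geometry scale 0.25: 130 × 13 × 204 sinogram,
110 × 110 × 40 grid) keep a full NEMA analysis — five count levels,
noise realizations, OP-OSEM 8 × 5 reconstructions and the scatter
model — in the minutes range on one CPU, while exercising the same
code paths as the full-size geometry; the package's own analyses are
run at this scale.  One master seed drives everything; noise
realization i uses stream seed + i, and per-count-level streams are
offset deterministically, so every reported number is reproducible
from its manifest.

## Known limitations

Uniform-plane axial model (no michelogram); fixed random rate; uniform
normalization; single scatter only, fractionally scaled; spatially
invariant PSF and pre-smoothing; no decay, dead time or bed motion; at
desk scale the two smallest NEMA spheres are sub-voxel, so their ROIs
degenerate to one or two voxels and their RC/COV values carry large
discretization variance (visible as the dominant term in the RC-bias
acceptance run).
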