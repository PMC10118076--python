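# Methods

## The CE-boost model

Contrast-enhancement boost (CE-boost) is a purely image-domain
post-processing step for CT angiography.  Given a pre-contrast volume
`pre` and a contrast-enhanced volume `enh`, both in Hounsfield units:

1. **Align** — `pre` is rigidly registered onto the grid of `enh`
   (head/neck motion between the two acquisitions is approximately rigid).
2. **Subtract** — the iodine map `I = enh − pre_aligned` isolates the
   attenuation added by the contrast agent.  Vessels come out positive;
   unenhancing tissue cancels.  Negative values, which can only be noise
   or residual misregistration (iodine concentration is non-negative),
   are clamped to zero by default.
3. **Denoise** — `I` is passed through an edge-preserving denoiser.
   Subtraction doubles the noise variance, so this step is what makes the
   recombination useful rather than noise-amplifying.
4. **Recombine** — `boosted = denoise(enh) + w · denoise(I)` with weight
   `w ≥ 0` (default 1).

With the `identity` denoiser and `w = 1` the pipeline reduces exactly to
`boosted = 2·enh − pre`; this linear identity is bit-exact on
integer-quantized HU data (which CT data is) and is used as an oracle in
the tests.

### Why the enhanced volume is denoised too

If only the iodine map were denoised, the combined image would contain
the enhanced volume's own noise *plus* a positively correlated smoothed
copy of it, so its measured noise could never drop below the conventional
image's.  Observed CE-boost products produce images with *lower* noise
than the conventional input, which is only possible if the enhanced
volume passes through the denoiser as well.  The pipeline therefore
denoises both by default (`BoostParams.denoise_enhanced`); disabling it
restores the strict "enhanced + w·iodine" combination.

### Denoiser choice

The default is 3-D non-local means (patch size 3, search distance 3,
filtering strength h = 15 HU).  NLM's piecewise-constant prior flattens
noise and the tails of the scanner blur while steepening vessel edges,
and it does so *uniformly across vessel calibers*: on noiseless phantoms
the measured FWHM of the boosted vessel is 0.01–0.04 mm below the
conventional one for radii 1.1–2.0 mm.  A slice-wise bilateral filter
(selectable) also preserves edges but its discrete response perturbs the
measured width with a sign that depends on how the vessel radius lands on
the voxel grid (+0.05 mm at r = 1.6 mm, −0.07 mm at r = 1.9 mm), which
makes it unsuitable as the default for a pipeline whose purpose includes
sharpening.  A Gaussian filter and the identity are also available.

`h = 15 HU` sits just above the noise SD of a subtraction image at
typical CTA noise levels (≈7–11 HU per acquisition, hence ≈10–15 HU in
the difference).  All strengths are configurable.

### Registration

Rigid (6-DOF Euler) registration, multi-resolution (shrink 4/2/1,
smoothing 2/1/0 mm), regular-step gradient descent, linear interpolation.
The metric is mean squared error with the enhancing voxels excluded:
both volumes are HU CT, so outside the vessels the intensities should
match directly, while inside them they differ *by design*; masking out
fixed-image voxels above 200 HU prevents the enhancement itself from
biasing the alignment.  (A Mattes mutual-information metric was evaluated
and rejected: its histogram binning leaves a ~0.2 mm bias even when
self-registering a noiseless phantom; plain unmasked correlation was
rejected because the vessel mismatch tilts its optimum by ~0.4°.)
Registration residuals on known misalignments up to 3 mm / 2° are below
0.06° and 0.02 mm.

## The digital vessel phantom

The generator emulates the *measurement context* of a head-and-neck CTA
study: a soft-tissue background (40 HU), a subcutaneous-fat compartment
(−100 HU) for the noise ROI, a muscle compartment (60 HU) for the CNR
reference, and straight tubular vessels whose HU rises from ≈45
(unenhanced blood) to ≈450 (opacified artery) between the two
acquisitions.  These tissue values are domain-typical package defaults,
not measurements from any dataset, and are all configurable.  The default
phantom is 32×96×96 voxels at 0.5 mm isotropic spacing with three vessels
of radius 1.1, 1.6 and 1.9 mm (diameters 2.2–3.8 mm, the caliber range of
the posterior-circulation arteries this kind of study measures).

Rasterization is performed at 4× supersampling per axis and averaged
down, so boundary voxels carry partial-volume values; a Gaussian PSF
(default σ = 0.4 mm) models the scanner blur; independent zero-mean white
Gaussian noise (default σ = 10 HU) is added separately to the pre and
enhanced volumes.  An optional rigid misalignment of the pre acquisition
is applied *analytically* — the scene is evaluated at transformed
coordinates — so the displaced volume has no interpolation artifacts.
The fat and muscle compartments end inside the volume along z because
real anatomy is not translation-invariant along the scan axis; without
that structure a z-shift would be unidentifiable by registration.

What the phantom deliberately does **not** model: projection-domain
physics (beam hardening, photon starvation), spatially correlated or
dose-dependent quantum noise, kVp-dependent iodine enhancement, curved or
branching vessels, bone, and patient-to-patient anatomical variation.
Passing phantom tests therefore demonstrates that the pipeline and the
measurement chain behave correctly under known ground truth — not that
clinical effect sizes will match; the study-scale numbers summarized from
patients are not reproducible from synthetic data, and the batch
comparisons here check the *direction* of each effect, not its magnitude.

## Objective image-quality measurements

* **ROI statistics** — circular in-plane ROI; membership is
  voxel-center-in-disc on the axial slice nearest the ROI center; at
  least 5 voxels required; SD uses the n−1 denominator.
* **Image noise** — SD inside a 100 mm² subcutaneous-fat ROI.  One noise
  figure per volume serves every segment's SNR/CNR.
* **SNR / CNR** — vessel mean / noise, and (vessel − muscle) / noise.
* **SNR map** — voxelwise value / noise, written as NIfTI.
* **Attenuation profile** — linear interpolation along a probe crossing
  the vessel, step = min(spacing)/4 for sub-voxel crossing precision.
* **FWHM** — half-maximum level is `baseline + (peak − baseline)/2`;
  the baseline defaults to the mean of the outer 20 % of samples on each
  side (vessels sit on non-zero tissue HU); crossings are found by linear
  interpolation walking outward from the peak; a profile without a peak
  above baseline or whose flank never falls below half-max has *no*
  FWHM (recorded as missing, never 0).
* **Vessel ROI size** — disc radius 0.7× the (true or estimated) vessel
  radius, a reproducible stand-in for "the largest ROI avoiding the
  vessel wall".
* Segment attenuation may average several ROIs (default: three adjacent
  axial slices) with equal weight.

## Statistics

* **Normality** — Shapiro–Wilk, and Kolmogorov–Smirnov against a normal
  with the sample's mean and SD (no Lilliefors correction; the plain KS
  contract is what the report's routing uses).
* **Routing** — continuous metrics use the paired t-test when
  Shapiro–Wilk does not reject normality of the differences (p ≥ 0.05),
  otherwise Wilcoxon signed-rank; FWHM and ordinal (Likert) scores always
  use Wilcoxon.  All p-values two-sided, significance 0.05.
* **Wilcoxon signed-rank** — zeros dropped, ties mid-ranked.  Exact null
  distribution for n ≤ 15 via a dynamic program over doubled midranks
  (equivalent to enumerating all 2ⁿ sign assignments; the tests verify
  this against literal enumeration); two-sided exact
  p = min(1, 2·min(P(W ≤ w), P(W ≥ w))).  For n > 15, normal
  approximation with tie correction and continuity correction.
* **Cohen's kappa** — unweighted, on the pooled 5-level scale, per
  criterion plus pooled over criteria (reported separately because the
  pooling convention behind a single published kappa is ambiguous);
  linear/quadratic weighting available.  Interpretation bins:
  ≥ 0.81 excellent, 0.61–0.80 substantial, 0.41–0.60 moderate,
  0.21–0.40 fair, < 0.21 poor.

## Problem sizes and determinism

Batch comparisons use 20 phantom replicates of the default 32×96×96
phantom — small enough to run on one CPU in about two minutes, large
enough that every directional effect is significant at 0.05.  All
randomness (phantom noise, case seeds) flows from explicit integer seeds
through `numpy.random.default_rng`; the same spec and seed reproduce
volumes bit-for-bit.

## Known limitations

* The vendor's actual denoiser and recombination weight are proprietary;
  observed attenuation ratios (≈1.47) suggest an effective w < 1, but
  this package exposes w rather than inferring the vendor formula, so
  default boosted attenuation is ≈1.9× conventional.
* Only axis-aligned NIfTI volumes and axial, axis-aligned DICOM series
  are read; oblique acquisitions are rejected, not resampled.
* Rigid registration only; no deformable motion compensation.
* FWHM is measured on straight probes through known centers; there is no
  automatic vessel segmentation or centerline extraction.
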