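"""The CE-boost algorithm: align, subtract, denoise, recombine.

Contrast-enhancement boost amplifies vascular opacification without extra
contrast agent or hardware: the pre-contrast volume is subtracted from the
contrast-enhanced volume to isolate an iodine map, the map is denoised, and
a weighted copy is added back onto the enhanced volume,

    boosted = enhanced + w * denoise(enhanced - pre_aligned)

The iodine map is computed as ``enhanced - pre`` so that enhancing vessels
come out positive.  Because subtracting two acquisitions doubles the noise
variance, denoising the iodine map alone cannot reduce the noise of the
combined image below the conventional image's; the pipeline therefore also
passes the enhanced volume through the same denoiser before recombination
(``denoise_enhanced=True``, the default), which is what gives the boosted
image both higher vascular attenuation *and* lower image noise.  With the
``identity`` denoiser and ``w = 1`` the pipeline reduces exactly to
``boosted = 2*enhanced - pre``, voxelwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, GeometryError, RegistrationError
from .transforms import RigidTransform
from .volume_io import CTVolume, from_sitk, to_sitk

__all__ = [
    "BoostParams",
    "IodineMap",
    "register_pre_to_enhanced",
    "subtract_iodine",
    "denoise_iodine",
    "denoise_volume",
    "combine_boost",
    "ce_boost_pipeline",
]

DENOISERS = ("identity", "gaussian", "bilateral", "nlm")


@dataclass
class BoostParams:
    """Tunable parameters of the CE-boost pipeline.

    registration : {"none", "rigid"}
        Whether to rigidly align the pre-contrast volume first.
    denoiser : {"nlm", "bilateral", "gaussian", "identity"}
        Denoiser applied to the iodine map (and, if ``denoise_enhanced``,
        to the enhanced volume).  The default is 3-D non-local means at a
        fixed strength: its piecewise-constant prior flattens noise and
        blur tails while steepening vessel edges uniformly across vessel
        calibers, which is the behavior the boosted image needs (lower
        noise *and* shorter FWHM).  The slice-wise bilateral alternative
        preserves edges but its discrete response perturbs measured vessel
        width with a sign that depends on how the vessel radius lands on
        the voxel grid.
    weight : float >= 0
        Recombination weight w; the boosted image is enhanced + w*iodine.
    clamp_negative_iodine : bool
        Set physically impossible negative iodine values to zero.
    denoise_enhanced : bool
        Denoise the enhanced volume before recombination (see module docs).
    """

    registration: str = "rigid"
    denoiser: str = "nlm"
    weight: float = 1.0
    clamp_negative_iodine: bool = True
    denoise_enhanced: bool = True
    # per-denoiser strengths; nlm_h_hu sits just above the noise SD of a
    # subtraction image at typical CTA noise levels (~7-11 HU per volume)
    gaussian_sigma_mm: float = 0.8
    bilateral_sigma_spatial_mm: float = 1.0
    bilateral_sigma_hu: float = 60.0
    nlm_patch_size: int = 3
    nlm_patch_distance: int = 3
    nlm_h_hu: float = 15.0

    def validate(self) -> None:
        if self.registration not in ("none", "rigid"):
            raise ConfigError(f"unknown registration mode {self.registration!r}")
        if self.denoiser not in DENOISERS:
            raise ConfigError(
                f"unknown denoiser {self.denoiser!r}; choose from {DENOISERS}"
            )
        if self.weight < 0:
            raise ConfigError("weight must be >= 0")
        for name in (
            "gaussian_sigma_mm",
            "bilateral_sigma_spatial_mm",
            "bilateral_sigma_hu",
            "nlm_h_hu",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass
class IodineMap:
    """HU-difference field sharing the source volumes' geometry."""

    volume: CTVolume
    provenance: str = "raw"  # {"raw", "denoised"}

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def register_pre_to_enhanced(
    pre: CTVolume,
    enhanced: CTVolume,
    mode: str = "rigid",
    mask_enhancement_above_hu: float = 200.0,
) -> tuple[CTVolume, RigidTransform]:
    """Align the pre-contrast volume onto the enhanced volume's grid.

    mode="none" returns the input untouched with an identity transform.
    mode="rigid" minimizes masked mean squared error over a rigid (Euler)
    transform and resamples with linear interpolation.  Both acquisitions
    are HU CT, so outside the enhancing structures the intensities match
    directly; voxels whose enhanced value exceeds ``mask_enhancement_above_hu``
    (iodinated vessels, which by design differ between the two volumes)
    are excluded from the metric so the enhancement itself cannot bias the
    alignment.  The returned transform maps enhanced-grid physical points
    to pre-volume points (the resampling convention), i.e. it is the
    inverse of the physical motion that displaced the pre acquisition.
    """
    if mode == "none":
        return pre, RigidTransform()
    if mode != "rigid":
        raise ConfigError(f"unknown registration mode {mode!r}")

    import SimpleITK as sitk

    fixed = to_sitk(enhanced)
    moving = to_sitk(pre)
    initial = sitk.CenteredTransformInitializer(
        fixed,
        moving,
        sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricFixedMask(sitk.Cast(fixed < mask_enhancement_above_hu, sitk.sitkUInt8))
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-6,
        numberOfIterations=800,
        gradientMagnitudeTolerance=1e-10,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(initial, inPlace=False)
    try:
        final = reg.Execute(fixed, moving)
    except RuntimeError as exc:  # e.g. no overlapping samples
        raise RegistrationError(f"rigid registration failed: {exc}") from exc

    euler = sitk.Euler3DTransform(
        sitk.CompositeTransform(final).GetNthTransform(0)
    )
    resampled = sitk.Resample(
        moving, fixed, final, sitk.sitkLinear, 0.0, sitk.sitkFloat64
    )
    aligned = from_sitk(resampled)

    # sitk works in (x, y, z) physical points
    tx, ty, tz = euler.GetTranslation()
    cx, cy, cz = euler.GetCenter()
    # Convert to this package's (z,y,x) intrinsic-zyx parametrization via
    # the rotation matrix to avoid Euler-convention pitfalls.
    from scipy.spatial.transform import Rotation

    m_xyz = np.asarray(euler.GetMatrix()).reshape(3, 3)
    rz, ry, rx = Rotation.from_matrix(m_xyz).as_euler("ZYX", degrees=True)
    transform = RigidTransform(
        rotation_deg=(rz, ry, rx),
        translation_mm=(tz, ty, tx),
        center_mm=(cz, cy, cx),
    )
    return aligned, transform


# ---------------------------------------------------------------------------
# Subtraction
# ---------------------------------------------------------------------------

def subtract_iodine(
    enhanced: CTVolume, aligned_pre: CTVolume, clamp_negative: bool = True
) -> IodineMap:
    """Voxelwise iodine map ``enhanced - pre`` (vessels positive).

    Negative values — noise or residual misregistration, since iodine
    concentration cannot be negative — are clamped to 0 when requested.
    """
    if not enhanced.same_grid(aligned_pre):
        raise GeometryError(
            f"grid mismatch: {enhanced.shape}/{enhanced.spacing} vs "
            f"{aligned_pre.shape}/{aligned_pre.spacing}"
        )
    diff = enhanced.data - aligned_pre.data
    if clamp_negative:
        diff = np.maximum(diff, 0.0)
    return IodineMap(enhanced.with_data(diff), provenance="raw")


# ---------------------------------------------------------------------------
# Denoising
# ---------------------------------------------------------------------------

def _denoise_array(data: np.ndarray, spacing, params: BoostParams) -> np.ndarray:
    if params.denoiser == "identity":
        return data.copy()
    if params.denoiser == "gaussian":
        sigma_vox = [params.gaussian_sigma_mm / s for s in spacing]
        return gaussian_filter(data, sigma=sigma_vox, mode="nearest")
    if params.denoiser == "bilateral":
        from skimage.restoration import denoise_bilateral

        # slice-wise 2-D bilateral (the common practice for axial CT);
        # shift to non-negative first — the filter is shift-equivariant.
        shift = float(data.min())
        shifted = data - shift
        sigma_spatial_vox = params.bilateral_sigma_spatial_mm / float(
            min(spacing[1], spacing[2])
        )
        out = np.empty_like(shifted)
        for k in range(shifted.shape[0]):
            out[k] = denoise_bilateral(
                shifted[k],
                sigma_color=params.bilateral_sigma_hu,
                sigma_spatial=sigma_spatial_vox,
            )
        return out + shift
    if params.denoiser == "nlm":
        from skimage.restoration import denoise_nl_means

        return denoise_nl_means(
            data,
            patch_size=params.nlm_patch_size,
            patch_distance=params.nlm_patch_distance,
            h=params.nlm_h_hu,
            fast_mode=True,
        )
    raise ConfigError(f"unknown denoiser {params.denoiser!r}")


def denoise_iodine(iodine: IodineMap, params: BoostParams) -> IodineMap:
    """Denoise a raw iodine map, preserving means in homogeneous regions."""
    params.validate()
    if iodine.provenance != "raw":
        raise ConfigError("denoise_iodine expects a raw iodine map")
    out = _denoise_array(iodine.data, iodine.volume.spacing, params)
    return IodineMap(iodine.volume.with_data(out), provenance="denoised")


def denoise_volume(vol: CTVolume, params: BoostParams) -> CTVolume:
    """Apply the configured denoiser to a CT volume."""
    params.validate()
    return vol.with_data(_denoise_array(vol.data, vol.spacing, params))


# ---------------------------------------------------------------------------
# Recombination
# ---------------------------------------------------------------------------

def combine_boost(
    enhanced: CTVolume, iodine_denoised: IodineMap, params: BoostParams
) -> CTVolume:
    """boosted = enhanced + w * iodine, voxelwise."""
    if iodine_denoised.provenance != "denoised":
        raise ConfigError("combine_boost expects a denoised iodine map")
    if not enhanced.same_grid(iodine_denoised.volume):
        raise GeometryError("iodine map and enhanced volume are on different grids")
    return enhanced.with_data(enhanced.data + params.weight * iodine_denoised.data)


def ce_boost_pipeline(
    pre: CTVolume, enhanced: CTVolume, params: BoostParams | None = None
) -> tuple[CTVolume, IodineMap, RigidTransform]:
    """Full CE-boost: register -> subtract -> denoise -> combine.

    Returns the boosted volume, the denoised iodine map, and the recovered
    registration transform (identity when registration is "none").
    Deterministic for fixed inputs and parameters.
    """
    params = params or BoostParams()
    params.validate()
    aligned_pre, transform = register_pre_to_enhanced(
        pre, enhanced, mode=params.registration
    )
    iodine = subtract_iodine(
        enhanced, aligned_pre, clamp_negative=params.clamp_negative_iodine
    )
    iodine_d = denoise_iodine(iodine, params)
    base = denoise_volume(enhanced, params) if params.denoise_enhanced else enhanced
    boosted = combine_boost(base, iodine_d, params)
    return boosted, iodine_d, transform
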