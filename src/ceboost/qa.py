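"""Objective image-quality measurements.

Implements the standard CT-angiography quality metrics: mean attenuation in
a circular ROI, image noise as the SD inside a 100 mm² subcutaneous-fat ROI,
SNR (vessel attenuation / noise), CNR ((vessel − muscle) / noise), a
voxelwise SNR map, and vessel sharpness as the full width at half maximum
(FWHM) of an attenuation line profile drawn across the vessel.

Conventions (documented because FWHM positions depend on them):

* ROI membership is voxel-center-in-disc, on the axial slice nearest the
  ROI center; sample SD uses the n−1 denominator.
* Line profiles are linearly interpolated at a uniform step, default
  ``min(spacing)/4``, for sub-voxel crossing precision.
* The FWHM baseline defaults to the mean of the outer 20% of samples on
  each side of the profile — vessels sit on non-zero tissue HU, so the
  half-maximum must be relative to the local background.
* One image-noise figure (the fat-ROI SD) serves every segment's SNR/CNR
  within a volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .errors import FWHMUndefinedError, MeasurementError
from .volume_io import CTVolume

__all__ = [
    "ROISpec",
    "LineProbe",
    "QARecord",
    "SegmentPlan",
    "MeasurementPlan",
    "roi_stats",
    "image_noise",
    "snr",
    "cnr",
    "snr_map",
    "attenuation_profile",
    "fwhm",
    "evaluate_case",
    "records_to_dataframe",
]


# ---------------------------------------------------------------------------
# Measurement primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROISpec:
    """Circular in-plane ROI: center (z, y, x) mm and area in mm²."""

    center: tuple[float, float, float]
    area_mm2: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise MeasurementError(f"ROI {self.label!r}: area must be positive")

    @property
    def radius_mm(self) -> float:
        return math.sqrt(self.area_mm2 / math.pi)


@dataclass(frozen=True)
class LineProbe:
    """Straight sampling line (z, y, x) mm, crossing a vessel through its center."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    sample_step_mm: float | None = None  # default: min(spacing)/4

    @property
    def length_mm(self) -> float:
        return float(
            np.linalg.norm(np.asarray(self.end) - np.asarray(self.start))
        )


@dataclass
class QARecord:
    """One vessel-segment measurement row (one image variant)."""

    segment: str
    variant: str  # {"conventional", "boosted"}
    attenuation_hu: float
    noise_hu: float
    snr: float
    cnr: float
    fwhm_mm: float | None = None
    error: str | None = None


# ---------------------------------------------------------------------------
# ROI statistics
# ---------------------------------------------------------------------------

def _roi_mask(vol: CTVolume, roi: ROISpec) -> tuple[int, np.ndarray, np.ndarray]:
    cz, cy, cx = vol.mm_to_voxel(roi.center)
    k = int(round(cz))
    if not (0 <= k < vol.shape[0]):
        raise MeasurementError(
            f"ROI {roi.label!r}: slice z={roi.center[0]} mm outside volume"
        )
    r = roi.radius_mm
    ny, nx = vol.shape[1], vol.shape[2]
    ys = (np.arange(ny) - cy) * vol.spacing[1]
    xs = (np.arange(nx) - cx) * vol.spacing[2]
    in_disc = (ys[:, None] ** 2 + xs[None, :] ** 2) <= r**2
    # ROI must sit fully inside the volume
    y0, y1 = roi.center[1] - r, roi.center[1] + r
    x0, x1 = roi.center[2] - r, roi.center[2] + r
    lo = vol.voxel_to_mm((0, 0, 0))
    hi = vol.voxel_to_mm(np.asarray(vol.shape) - 1)
    if y0 < lo[1] - 1e-9 or y1 > hi[1] + 1e-9 or x0 < lo[2] - 1e-9 or x1 > hi[2] + 1e-9:
        raise MeasurementError(f"ROI {roi.label!r} extends outside the volume")
    return k, in_disc, vol.data[k][in_disc]


def roi_stats(vol: CTVolume, roi: ROISpec) -> tuple[float, float, int]:
    """(mean HU, sample SD HU, n voxels) over voxel centers inside the disc."""
    _, _, values = _roi_mask(vol, roi)
    n = int(values.size)
    if n < 5:
        raise MeasurementError(
            f"ROI {roi.label!r}: only {n} voxels inside (need >= 5)"
        )
    return float(values.mean()), float(values.std(ddof=1)), n


def image_noise(vol: CTVolume, fat_roi: ROISpec) -> float:
    """Image noise: sample SD of HU in the subcutaneous-fat ROI (100 mm² default)."""
    _, sd, _ = roi_stats(vol, fat_roi)
    return sd


def snr(attenuation: float, noise: float) -> float:
    """Signal-to-noise ratio: vessel attenuation / image noise."""
    if noise <= 0:
        raise MeasurementError(f"noise must be positive, got {noise}")
    return attenuation / noise


def cnr(vessel_hu: float, muscle_hu: float, noise: float) -> float:
    """Contrast-to-noise ratio: (vessel − muscle) / image noise."""
    if noise <= 0:
        raise MeasurementError(f"noise must be positive, got {noise}")
    return (vessel_hu - muscle_hu) / noise


def snr_map(vol: CTVolume, noise: float) -> CTVolume:
    """Voxelwise SNR field (value / noise), sharing the input geometry."""
    if noise <= 0:
        raise MeasurementError(f"noise must be positive, got {noise}")
    return vol.with_data(vol.data / noise)


# ---------------------------------------------------------------------------
# Line profiles and FWHM
# ---------------------------------------------------------------------------

def attenuation_profile(
    vol: CTVolume, probe: LineProbe
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the volume along the probe with linear interpolation.

    Returns (positions mm along the probe from its start, HU values).
    """
    start = np.asarray(probe.start, dtype=float)
    end = np.asarray(probe.end, dtype=float)
    length = probe.length_mm
    if length <= 0:
        raise MeasurementError("probe has zero length")
    step = probe.sample_step_mm or min(vol.spacing) / 4.0
    if step <= 0:
        raise MeasurementError("sample step must be positive")
    n = int(math.floor(length / step + 1e-9)) + 1
    positions = np.arange(n) * step
    pts = start + (positions / length)[:, None] * (end - start)
    idx = vol.mm_to_voxel(pts)  # (n, 3) continuous voxel coords
    upper = np.asarray(vol.shape) - 1
    if np.any(idx < -1e-9) or np.any(idx > upper + 1e-9):
        raise MeasurementError("probe exits the volume")
    values = map_coordinates(
        vol.data, np.clip(idx, 0, upper).T, order=1, mode="nearest"
    )
    return positions, values


def fwhm(
    positions: np.ndarray,
    values: np.ndarray,
    baseline: str | float = "edge_mean",
) -> float:
    """Full width at half maximum of a single-peaked profile, in mm.

    The half-maximum level is ``baseline + (peak − baseline)/2``; crossings
    are located by linear interpolation between samples on each flank,
    walking outward from the peak.  ``baseline="edge_mean"`` estimates the
    background as the mean of the outer 20% of samples on each side.
    A profile with no peak above baseline, or with a flank that never
    drops below half maximum, has no defined FWHM and raises
    :class:`FWHMUndefinedError` (record as missing, never as 0).
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size or x.size < 5:
        raise MeasurementError("profile needs >= 5 aligned samples")
    if baseline == "edge_mean":
        k = max(1, int(round(0.2 * x.size)))
        base = float(np.concatenate([y[:k], y[-k:]]).mean())
    else:
        base = float(baseline)
    ipk = int(np.argmax(y))
    peak = float(y[ipk])
    if peak <= base:
        raise FWHMUndefinedError("no peak above baseline")
    half = base + (peak - base) / 2.0

    def _cross(direction: int) -> float:
        i = ipk
        while 0 <= i + direction < y.size:
            j = i + direction
            if y[j] < half:
                # linear interpolation between samples i and j
                t = (half - y[i]) / (y[j] - y[i])
                return float(x[i] + t * (x[j] - x[i]))
            i = j
        raise FWHMUndefinedError(
            f"{'right' if direction > 0 else 'left'} flank never crosses half maximum"
        )

    left = _cross(-1)
    right = _cross(+1)
    return right - left


# ---------------------------------------------------------------------------
# Case evaluation (drives the per-segment QA table)
# ---------------------------------------------------------------------------

@dataclass
class SegmentPlan:
    """Measurement plan for one vessel segment.

    Multiple ROIs (e.g. the same disc on adjacent slices) are averaged with
    equal weight into the segment attenuation.
    """

    label: str
    rois: list[ROISpec]
    probe: LineProbe | None = None


@dataclass
class MeasurementPlan:
    fat_roi: ROISpec
    muscle_roi: ROISpec
    segments: list[SegmentPlan] = field(default_factory=list)


def evaluate_case(
    conventional: CTVolume,
    boosted: CTVolume,
    plan: MeasurementPlan,
) -> list[QARecord]:
    """Run the full measurement plan on both image variants.

    Returns one :class:`QARecord` per (segment, variant).  A failed FWHM
    measurement is recorded on the row (``fwhm_mm=None`` with the error
    message) and the run continues.
    """
    records: list[QARecord] = []
    for variant, vol in (("conventional", conventional), ("boosted", boosted)):
        noise = image_noise(vol, plan.fat_roi)
        muscle_mean, _, _ = roi_stats(vol, plan.muscle_roi)
        for seg in plan.segments:
            means = [roi_stats(vol, r)[0] for r in seg.rois]
            att = float(np.mean(means))
            rec = QARecord(
                segment=seg.label,
                variant=variant,
                attenuation_hu=att,
                noise_hu=noise,
                snr=snr(att, noise),
                cnr=cnr(att, muscle_mean, noise),
            )
            if seg.probe is not None:
                try:
                    pos, vals = attenuation_profile(vol, seg.probe)
                    rec.fwhm_mm = fwhm(pos, vals)
                except (MeasurementError, FWHMUndefinedError) as exc:
                    rec.error = str(exc)
            records.append(rec)
    return records


def records_to_dataframe(records: list[QARecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "segment": r.segment,
                "variant": r.variant,
                "attenuation_hu": r.attenuation_hu,
                "noise_hu": r.noise_hu,
                "snr": r.snr,
                "cnr": r.cnr,
                "fwhm_mm": r.fwhm_mm,
                "error": r.error,
            }
            for r in records
        ]
    )
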