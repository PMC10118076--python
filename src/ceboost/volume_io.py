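"""CT volume container and file I/O.

A :class:`CTVolume` is a 3-D scalar field of Hounsfield units (HU) with
geometry.  The internal axis order is fixed to ``(z, y, x)`` — slowest axis
first — and every physical coordinate in this package (spacing, origin, ROI
centers, probe endpoints) uses the same ``(z, y, x)`` ordering in mm.
Voxel indices are 0-based and a voxel's physical position is its *center*:

    position_mm = origin + index * spacing

Readers reorder external conventions (NIfTI's x-fastest storage, DICOM's
patient-space axes) onto this grid on ingest; non-axis-aligned orientations
are rejected rather than resampled, because silent resampling corrupts the
noise statistics that the QA module measures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

from .errors import GeometryError, VolumeIOError

__all__ = [
    "CTVolume",
    "read_volume",
    "write_volume",
    "read_nifti",
    "write_nifti",
    "read_dicom_series",
]


@dataclass
class CTVolume:
    """3-D scalar field in HU with (z, y, x) geometry.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Attenuation in Hounsfield units.
    spacing : 3-tuple of float
        Per-axis voxel size in mm, (z, y, x); all strictly positive.
    origin : 3-tuple of float
        Physical (z, y, x) position in mm of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise GeometryError(
                f"volume must be 3-D with each axis >= 1, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise GeometryError("volume contains non-finite HU values")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_mm(self, index: np.ndarray) -> np.ndarray:
        """Continuous voxel index (z, y, x) -> physical mm point."""
        idx = np.asarray(index, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def mm_to_voxel(self, point_mm: np.ndarray) -> np.ndarray:
        """Physical mm point (z, y, x) -> continuous voxel index.

        Exact inverse of :meth:`voxel_to_mm`; out-of-bounds indices are
        returned unflagged (callers decide whether that is an error).
        """
        p = np.asarray(point_mm, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_grid(self, other: "CTVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_data(self, data: np.ndarray) -> "CTVolume":
        """New volume sharing this geometry."""
        return replace(self, data=np.asarray(data, dtype=np.float64))


def mm_to_voxel(vol: CTVolume, point_mm) -> np.ndarray:
    return vol.mm_to_voxel(point_mm)


def voxel_to_mm(vol: CTVolume, index) -> np.ndarray:
    return vol.voxel_to_mm(index)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def write_nifti(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write as NIfTI-1 with an axis-aligned affine (float32 data)."""
    # nibabel stores x-fastest: transpose (z, y, x) -> (x, y, z).
    arr = np.asarray(vol.data, dtype=np.float32).transpose(2, 1, 0)
    sz, sy, sx = vol.spacing
    oz, oy, ox = vol.origin
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = [ox, oy, oz]
    nib.save(nib.Nifti1Image(arr, affine), os.fspath(path))


def read_nifti(path: str | os.PathLike) -> CTVolume:
    path = os.fspath(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types
        raise VolumeIOError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-5):
        raise GeometryError(
            f"{path!r}: oblique/non-axis-aligned NIfTI orientation is not supported"
        )
    diag = np.diag(rot)
    if np.any(diag <= 0):
        raise GeometryError(
            f"{path!r}: negative/zero affine scales (flipped axes) are not supported"
        )
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise GeometryError(f"{path!r}: expected a 3-D volume, got shape {data.shape}")
    sx, sy, sz = diag
    ox, oy, oz = affine[:3, 3]
    return CTVolume(data.transpose(2, 1, 0), spacing=(sz, sy, sx), origin=(oz, oy, ox))


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def read_dicom_series(directory: str | os.PathLike) -> CTVolume:
    """Read an axial DICOM series directory into HU.

    RescaleSlope/RescaleIntercept are applied exactly once.  Slices must
    share in-plane spacing and an axis-aligned orientation and be uniformly
    spaced along z; anything else is a geometry error, never resampled.
    """
    import pydicom

    directory = os.fspath(directory)
    if not os.path.isdir(directory):
        raise VolumeIOError(f"not a directory: {directory!r}")
    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue  # skip non-DICOM files (DICOMDIR, reports, ...)
        if hasattr(ds, "PixelData"):
            slices.append((f, ds))
    if not slices:
        raise VolumeIOError(f"no DICOM image slices found in {directory!r}")

    def _ipp(ds):
        return [float(v) for v in ds.ImagePositionPatient]

    first = slices[0][1]
    orient = np.asarray([float(v) for v in first.ImageOrientationPatient])
    ident = np.array([1, 0, 0, 0, 1, 0], dtype=float)
    if not np.allclose(orient, ident, atol=1e-4):
        raise GeometryError(
            f"{directory!r}: non-axis-aligned DICOM orientation {orient.tolist()} rejected"
        )
    ps = [float(v) for v in first.PixelSpacing]  # (row=y, col=x)
    for f, ds in slices[1:]:
        if not np.allclose([float(v) for v in ds.PixelSpacing], ps, atol=1e-6):
            raise GeometryError(f"{f!r}: inconsistent in-plane PixelSpacing")
        if not np.allclose(
            [float(v) for v in ds.ImageOrientationPatient], orient, atol=1e-4
        ):
            raise GeometryError(f"{f!r}: inconsistent slice orientation")

    slices.sort(key=lambda fs: _ipp(fs[1])[2])
    zs = np.array([_ipp(ds)[2] for _, ds in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.any(dz <= 0) or not np.allclose(dz, dz[0], atol=1e-3):
            raise GeometryError(
                f"{directory!r}: non-uniform DICOM slice spacing {dz.tolist()}"
            )
        slice_spacing = float(dz[0])
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0) or 1.0)

    planes = []
    for f, ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        inter = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        planes.append(ds.pixel_array.astype(np.float64) * slope + inter)
    data = np.stack(planes, axis=0)  # (z, rows=y, cols=x)
    x0, y0, z0 = _ipp(slices[0][1])
    return CTVolume(
        data,
        spacing=(slice_spacing, ps[0], ps[1]),
        origin=(float(z0), float(y0), float(x0)),
    )


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike, format: str | None = None) -> CTVolume:
    """Read a CT volume (``nifti`` file or ``dicom_series`` directory)."""
    p = os.fspath(path)
    if format is None:
        format = "dicom_series" if os.path.isdir(p) else "nifti"
    if format == "nifti":
        if not os.path.exists(p):
            raise VolumeIOError(f"no such file: {p!r}")
        return read_nifti(p)
    if format == "dicom_series":
        return read_dicom_series(p)
    raise VolumeIOError(f"unknown volume format {format!r}")


def write_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume; NIfTI is the only output format."""
    write_nifti(vol, path)


# ---------------------------------------------------------------------------
# SimpleITK bridge (used by registration)
# ---------------------------------------------------------------------------

def to_sitk(vol: CTVolume):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.asarray(vol.data, dtype=np.float64))
    img.SetSpacing(tuple(reversed(vol.spacing)))  # sitk wants (x, y, z)
    img.SetOrigin(tuple(reversed(vol.origin)))
    return img


def from_sitk(img) -> CTVolume:
    import SimpleITK as sitk

    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise GeometryError("non-identity direction matrices are not supported")
    data = sitk.GetArrayFromImage(img).astype(np.float64)
    return CTVolume(
        data,
        spacing=tuple(reversed(img.GetSpacing())),
        origin=tuple(reversed(img.GetOrigin())),
    )
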