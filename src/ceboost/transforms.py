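"""Rigid transforms in physical (mm) space.

All points are 3-vectors ordered (z, y, x) to match the package's volume
axis convention.  A :class:`RigidTransform` rotates about a fixed center and
then translates:

    T(p) = R (p - c) + c + t

Rotation angles are intrinsic Euler rotations about the z, y and x axes (in
that order), given in degrees.  This is the parametrization used both by the
phantom's misalignment model and by the registration wrapper, so recovered
and applied transforms can be composed and compared directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (degrees, about ``center``) followed by translation (mm)."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix acting on (z, y, x) vectors."""
        # scipy works in (x, y, z); permute in and out.
        rz, ry, rx = self.rotation_deg
        rot = Rotation.from_euler("ZYX", [rz, ry, rx], degrees=True)
        m_xyz = rot.as_matrix()
        perm = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
        return perm @ m_xyz @ perm.T

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (..., 3) array of (z, y, x) mm points."""
        p = np.asarray(points, dtype=float)
        c = np.asarray(self.center_mm, dtype=float)
        t = np.asarray(self.translation_mm, dtype=float)
        return (p - c) @ self.matrix.T + c + t

    def inverse(self) -> "RigidTransform":
        rz, ry, rx = self.rotation_deg
        inv_rot = Rotation.from_euler("ZYX", [rz, ry, rx], degrees=True).inv()
        izyx = inv_rot.as_euler("ZYX", degrees=True)
        m_inv = self.matrix.T
        t = np.asarray(self.translation_mm, dtype=float)
        return RigidTransform(
            rotation_deg=tuple(izyx),
            translation_mm=tuple(-(m_inv @ t)),
            center_mm=self.center_mm,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return T such that T(p) = self(other(p)), centered at self.center."""
        m = self.matrix @ other.matrix
        rz, ry, rx = Rotation.from_matrix(
            np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], float)
            @ m
            @ np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], float).T
        ).as_euler("ZYX", degrees=True)
        c = np.asarray(self.center_mm, float)
        # self(other(p)) = M (p - c) + c + t_eff with both recentered at c.
        probe = np.zeros(3)
        t_eff = self.apply(other.apply(probe)) - (m @ (probe - c) + c)
        return RigidTransform((rz, ry, rx), tuple(t_eff), tuple(c))

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rotation_deg, 0) and np.allclose(
            self.translation_mm, 0
        )

    def magnitude(self) -> tuple[float, float]:
        """(rotation angle in degrees, translation norm in mm).

        The rotation angle is the single-axis equivalent angle of the full
        rotation; useful for asserting a residual transform is near identity.
        """
        rz, ry, rx = self.rotation_deg
        rot = Rotation.from_euler("ZYX", [rz, ry, rx], degrees=True)
        angle = float(np.degrees(np.linalg.norm(rot.as_rotvec())))
        return angle, float(np.linalg.norm(self.translation_mm))
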