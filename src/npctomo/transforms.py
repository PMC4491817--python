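"""Rigid-body transforms and single-interpolation volume resampling.

Euler convention (pinned for the whole package): intrinsic Z-X-Z with
right-handed axes.  ``phi`` rotates about z, ``theta`` about the new x,
``psi`` about the final z; angles in degrees.  Rotation acts on the volume
(not the sampling grid) about the center voxel ``floor(N/2)`` of each
dimension, followed by a translation in voxels.  Resampling is always a
single trilinear interpolation, so a chain of alignment steps is applied to
raw data by composing transforms first and interpolating once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform
from scipy.spatial.transform import Rotation

from .volume import Volume

__all__ = ["RigidTransform", "compose", "apply_transform", "rotation_angle_deg"]


@dataclass
class RigidTransform:
    """Three intrinsic Z-X-Z Euler angles (degrees) plus a shift in voxels."""

    phi: float = 0.0
    theta: float = 0.0
    psi: float = 0.0
    shift: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=float).reshape(3)
        params = [self.phi, self.theta, self.psi, *self.shift]
        if not np.all(np.isfinite(params)):
            raise ValueError(f"non-finite transform parameters: {params}")

    # -- group structure ----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, shift=(0.0, 0.0, 0.0)) -> "RigidTransform":
        import warnings

        with warnings.catch_warnings():
            # theta == 0 makes phi/psi degenerate; scipy resolves psi := 0,
            # which is exactly the tie-break we want.
            warnings.simplefilter("ignore", UserWarning)
            phi, theta, psi = Rotation.from_matrix(matrix).as_euler(
                "ZXZ", degrees=True)
        return cls(phi, theta, psi, np.asarray(shift, dtype=float))

    @property
    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix mapping pre-rotation to post-rotation coords."""
        return Rotation.from_euler(
            "ZXZ", [self.phi, self.theta, self.psi], degrees=True).as_matrix()

    def inverse(self) -> "RigidTransform":
        rinv = self.matrix.T
        return RigidTransform.from_matrix(rinv, -rinv @ self.shift)

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying *inner* first, then *self*."""
        r = self.matrix @ inner.matrix
        t = self.shift + self.matrix @ inner.shift
        return RigidTransform.from_matrix(r, t)

    def angles(self) -> np.ndarray:
        return np.array([self.phi, self.theta, self.psi])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"RigidTransform(phi={self.phi:.3f}, theta={self.theta:.3f}, "
                f"psi={self.psi:.3f}, shift={np.round(self.shift, 3)})")


def compose(t_outer: RigidTransform, t_inner: RigidTransform) -> RigidTransform:
    """``apply(v, compose(a, b)) == apply(apply(v, b), a)`` up to interpolation."""
    return t_outer.compose(t_inner)


def rotation_angle_deg(a: RigidTransform, b: RigidTransform | None = None) -> float:
    """Magnitude (degrees) of the relative rotation between two transforms."""
    ra = Rotation.from_matrix(a.matrix)
    if b is not None:
        ra = Rotation.from_matrix(b.matrix).inv() * ra
    return float(np.degrees(ra.magnitude()))


def _affine(data: np.ndarray, matrix: np.ndarray, shift: np.ndarray,
            order: int = 1, cval: float | None = None) -> np.ndarray:
    """Rotate *data* by *matrix* about the center voxel, then shift (voxels)."""
    center = np.array([s // 2 for s in data.shape], dtype=float)
    rinv = matrix.T
    offset = center - rinv @ (center + np.asarray(shift, dtype=float))
    if cval is None:
        cval = float(data.mean())
    return affine_transform(data, rinv, offset=offset, order=order,
                            mode="constant", cval=cval, prefilter=False)


def apply_transform(volume: Volume | np.ndarray, transform: RigidTransform,
                    order: int = 1, cval: float | None = None):
    """Resample a volume under a rigid transform with one trilinear interpolation.

    The rotation acts about the center voxel ``floor(N/2)``; voxels mapped
    from outside the field of view are filled with the volume mean (keeps
    cross-correlation normalization stable near the box edge).
    """
    if order not in (0, 1):
        raise ValueError("only nearest (0) and trilinear (1) interpolation are supported")
    if isinstance(volume, Volume):
        out = _affine(volume.data, transform.matrix, transform.shift, order, cval)
        return Volume(out, volume.voxel_size, volume.origin)
    return _affine(np.asarray(volume, dtype=np.float32), transform.matrix,
                   transform.shift, order, cval)
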