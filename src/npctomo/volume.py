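"""Volume container, MRC2014 I/O, soft masks and Fourier-shell indexing.

The :class:`Volume` is the universal container for tomograms, subtomograms
and averaged density maps: a 3-D scalar grid with an isotropic voxel size in
Angstrom and a physical origin.  Axis order is ``(x, y, z)`` throughout the
package; the electron beam runs along ``z`` and the tilt axis along ``y``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Volume",
    "FormatError",
    "read_mrc",
    "write_mrc",
    "soft_sphere_mask",
    "fourier_shells",
]


class FormatError(ValueError):
    """Raised when an MRC file violates the MRC2014 format."""


@dataclass
class Volume:
    """3-D scalar density grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Density values (arbitrary units), finite.
    voxel_size : float
        Isotropic voxel edge length in Angstrom, > 0.
    origin : ndarray, shape (3,)
        Physical position of voxel (0, 0, 0) in Angstrom.
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must be a 3-D grid with all dimensions >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if not (self.voxel_size > 0):
            raise ValueError("voxel_size must be > 0")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size, self.origin.copy())

    def is_cubic(self) -> bool:
        nx, ny, nz = self.data.shape
        return nx == ny == nz


# ---------------------------------------------------------------------------
# MRC2014 I/O (mode 2, little-endian).  Header layout per the MRC2014 spec:
# 56 int/float words followed by 10 x 80-byte text labels.
# ---------------------------------------------------------------------------

_HEADER_SIZE = 1024
_MAP_ID = b"MAP "


def write_mrc(volume: Volume, path) -> None:
    """Write *volume* to *path* as MRC2014 mode 2 (float32)."""
    data = np.ascontiguousarray(volume.data, dtype="<f4")
    nx, ny, nz = data.shape
    vs = float(volume.voxel_size)
    header = bytearray(_HEADER_SIZE)
    # nx/ny/nz are the fast/medium/slow axes of the file; we store x fast.
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, 2)  # mode 2 = float32
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nxstart..
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx my mz
    struct.pack_into("<3f", header, 40, nx * vs, ny * vs, nz * vs)  # cell a b c
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc mapr maps
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    struct.pack_into("<i", header, 88, 1)  # ispg = 1 (volume)
    struct.pack_into("<i", header, 92, 0)  # nsymbt
    struct.pack_into("<3f", header, 196, *volume.origin)
    header[208:212] = _MAP_ID
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 0)  # nlabl
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # MRC stores the first header axis fastest; numpy C-order has the
        # last axis fastest, so write the transposed view.
        fh.write(data.transpose(2, 1, 0).tobytes())


def read_mrc(path) -> Volume:
    """Read an MRC2014 volume.  Only mode 2 (float32) maps are supported."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise FormatError("truncated header: file shorter than 1024 bytes")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        if min(nx, ny, nz) < 1:
            raise FormatError(f"invalid dimensions nx/ny/nz = {(nx, ny, nz)}")
        mode = struct.unpack_from("<i", header, 12)[0]
        if mode != 2:
            raise FormatError(f"unsupported mode {mode}; only mode 2 (float32)")
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        if min(mx, my, mz) < 1:
            raise FormatError(f"invalid sampling mx/my/mz = {(mx, my, mz)}")
        cella = struct.unpack_from("<3f", header, 40)
        if header[208:212] not in (_MAP_ID, b"MAP\x00"):
            raise FormatError("missing MAP identifier at header word 53")
        origin = np.array(struct.unpack_from("<3f", header, 196))
        nsymbt = struct.unpack_from("<i", header, 92)[0]
        if nsymbt < 0:
            raise FormatError(f"invalid nsymbt = {nsymbt}")
        fh.seek(_HEADER_SIZE + nsymbt)
        count = nx * ny * nz
        raw = fh.read(4 * count)
        if len(raw) < 4 * count:
            raise FormatError(
                f"truncated data block: expected {count} voxels, "
                f"got {len(raw) // 4}")
        data = np.frombuffer(raw, dtype="<f4", count=count)
    data = data.reshape(nz, ny, nx).transpose(2, 1, 0)
    voxel_size = cella[0] / mx if mx else 1.0
    return Volume(np.ascontiguousarray(data), voxel_size, origin)


# ---------------------------------------------------------------------------
# Soft spherical mask
# ---------------------------------------------------------------------------

def soft_sphere_mask(shape, center=None, radius=None, edge_width=2.0) -> np.ndarray:
    """Spherical mask with a raised-cosine falloff.

    Values are exactly 1 for r <= radius - edge_width and exactly 0 for
    r >= radius; in between the profile is ``0.5 (1 + cos(pi t))`` with
    ``t`` the normalized distance into the edge.
    """
    shape = tuple(int(s) for s in shape)
    if center is None:
        center = [s // 2 for s in shape]
    if radius is None:
        radius = min(shape) / 2 - 1
    if radius <= 0:
        raise ValueError("radius must be > 0")
    edge_width = float(max(edge_width, 0.0))
    grids = np.meshgrid(*[np.arange(s, dtype=np.float32) for s in shape],
                        indexing="ij")
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    mask = np.zeros(shape, dtype=np.float32)
    mask[r <= radius - edge_width] = 1.0
    if edge_width > 0:
        band = (r > radius - edge_width) & (r < radius)
        t = (r[band] - (radius - edge_width)) / edge_width
        mask[band] = 0.5 * (1.0 + np.cos(np.pi * t))
    return mask


def fourier_shells(shape) -> np.ndarray:
    """Integer Fourier shell index per voxel, in natural FFT (unshifted) order.

    Shell width is one Fourier voxel; DC is shell 0.  Requires a cubic shape.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or len(set(shape)) != 1:
        raise ValueError(f"fourier_shells requires a cubic shape, got {shape}")
    n = shape[0]
    k = np.fft.fftfreq(n) * n  # integer-valued frequencies
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    r = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
    return np.round(r).astype(np.int32)
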