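"""Forward imaging model and weighted backprojection.

Single-axis tilt geometry: beam along z, tilt axis along y (optionally
rotated in the x-y plane by an azimuth).  A projection at tilt angle a is
the line integral along the beam through the volume rotated by R_y(a); in
Fourier space it samples the central plane with atan2(kz, kx) = a, which is
exactly the support described by :class:`npctomo.align.WedgeMask`.

The corruption model applies a strip-wise CTF (defocus varying across the
tilted image as df(x) = df0 + x sin(a)), a sinc² detector MTF and additive
white Gaussian noise; :func:`invert_corruption` is its exact known-model
inverse (sign *and* amplitude), used for round-trip validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import WedgeMask
from .ctf import CtfModel, ctf_2d, mtf_2d, strip_bounds, strip_defoci
from .transforms import _affine
from .volume import Volume

__all__ = ["AcquisitionSpec", "TiltSeries", "project_tilt_series",
           "corrupt", "invert_corruption", "weighted_backprojection"]


@dataclass
class AcquisitionSpec:
    """Single-axis acquisition geometry and noise model."""

    tilt_min: float = -60.0
    tilt_max: float = 60.0
    tilt_step: float = 3.0
    tilt_axis: float = 0.0        # azimuth of the tilt axis from y, degrees
    defocus_nominal: float = -6.0  # μm, negative = underfocus
    pixel_size: float = 13.2       # Å
    dose_noise_sigma: float = 0.0  # additive sigma relative to signal RMS
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tilt_min < self.tilt_max:
            raise ValueError("tilt_min must be < tilt_max")
        if self.tilt_step <= 0:
            raise ValueError("tilt_step must be > 0")

    @property
    def tilt_angles(self) -> np.ndarray:
        return np.arange(self.tilt_min, self.tilt_max + self.tilt_step / 2,
                         self.tilt_step)


@dataclass
class TiltSeries:
    """Ordered stack of projections with tilt geometry and per-image defocus."""

    images: np.ndarray             # (n_tilt, nx, ny)
    tilt_angles: np.ndarray        # degrees
    tilt_axis: float = 0.0         # azimuth, degrees
    pixel_size: float = 13.2       # Å
    defoci: np.ndarray | None = None  # μm per image

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.tilt_angles = np.asarray(self.tilt_angles, dtype=float)
        if self.images.ndim != 3 or len(self.images) != len(self.tilt_angles):
            raise ValueError("images must be (n_tilt, nx, ny) matching tilt_angles")
        if self.defoci is None:
            self.defoci = np.full(len(self.tilt_angles), np.nan)
        self.defoci = np.asarray(self.defoci, dtype=float)

    def copy(self) -> "TiltSeries":
        return TiltSeries(self.images.copy(), self.tilt_angles.copy(),
                          self.tilt_axis, self.pixel_size, self.defoci.copy())


def _tilt_matrix(angle_deg: float, azimuth_deg: float = 0.0) -> np.ndarray:
    """Rotation about the (azimuth-rotated) y axis by the tilt angle."""
    a = np.deg2rad(angle_deg)
    ry = np.array([[np.cos(a), 0.0, np.sin(a)],
                   [0.0, 1.0, 0.0],
                   [-np.sin(a), 0.0, np.cos(a)]])
    if azimuth_deg:
        b = np.deg2rad(azimuth_deg)
        rz = np.array([[np.cos(b), -np.sin(b), 0.0],
                       [np.sin(b), np.cos(b), 0.0],
                       [0.0, 0.0, 1.0]])
        return rz @ ry @ rz.T
    return ry


def project_tilt_series(volume: Volume, acq: AcquisitionSpec) -> TiltSeries:
    """Line-integral projections of a cubic volume over the tilt range."""
    if not volume.is_cubic():
        raise ValueError("projection requires a cubic volume (pad first)")
    data = volume.data
    images = []
    for ang in acq.tilt_angles:
        rot = _affine(data, _tilt_matrix(ang, acq.tilt_axis), np.zeros(3),
                      order=1, cval=0.0)
        images.append(rot.sum(axis=2))
    defoci = np.full(len(acq.tilt_angles), acq.defocus_nominal)
    return TiltSeries(np.stack(images), acq.tilt_angles, acq.tilt_axis,
                      volume.voxel_size, defoci)


def amorphous_tilt_series(n_images: int = 9, size: int = 256,
                          pixel_size: float = 4.0, seed: int = 0,
                          tilt_range=(-60.0, 60.0)) -> TiltSeries:
    """White-texture projections of an amorphous specimen (ice/carbon stand-in).

    A structureless specimen has a flat spectrum, so after corruption its
    periodogram carries clean Thon rings — the substrate defocus estimation
    needs (projections of a smooth particle alone do not provide one).
    """
    rng = np.random.default_rng(seed)
    images = rng.normal(size=(n_images, size, size)).astype(np.float32)
    angles = np.linspace(tilt_range[0], tilt_range[1], n_images)
    return TiltSeries(images, angles, 0.0, pixel_size)


# ---------------------------------------------------------------------------
# Corruption model and its exact inverse
# ---------------------------------------------------------------------------

def _strip_ctfs(image_shape, pixel_size, tilt_angle, tilt_axis, defocus_nominal,
                model: CtfModel, n_strips: int):
    from .ctf import clamp_strips
    bounds = strip_bounds(image_shape[0],
                          clamp_strips(image_shape[0], n_strips))
    defoci = strip_defoci(image_shape[0], pixel_size, tilt_angle,
                          defocus_nominal, bounds)
    return bounds, defoci


def _apply_per_strip(image, bounds, defoci, pixel_size, model, func):
    """FFT each exact strip tile, transform with *func*(F, ctf), inverse."""
    out = np.empty_like(image)
    for (lo, hi), df in zip(bounds, defoci):
        strip = image[lo:hi]
        c = ctf_2d(strip.shape, pixel_size, df, model)
        out[lo:hi] = np.fft.ifft2(func(np.fft.fft2(strip), c)).real
    return out


def corrupt(tilt_series: TiltSeries, acq: AcquisitionSpec,
            model: CtfModel | None = None, n_strips: int = 16) -> TiltSeries:
    """Apply strip-wise CTF, detector MTF and additive Gaussian noise."""
    model = model or CtfModel(defocus_um=acq.defocus_nominal)
    rng = np.random.default_rng(acq.seed)
    out = tilt_series.copy()
    for i, ang in enumerate(out.tilt_angles):
        img = out.images[i]
        bounds, defoci = _strip_ctfs(img.shape, out.pixel_size, ang,
                                     out.tilt_axis, acq.defocus_nominal,
                                     model, n_strips)
        img = _apply_per_strip(img, bounds, defoci, out.pixel_size, model,
                               lambda F, c: F * c)
        if model.mtf != "unit":
            m = mtf_2d(img.shape, out.pixel_size, model)
            img = np.fft.ifft2(np.fft.fft2(img) * m).real
        if acq.dose_noise_sigma > 0:
            sigma = acq.dose_noise_sigma * float(out.images[i].std())
            img = img + rng.normal(0.0, sigma, img.shape)
        out.images[i] = img
        out.defoci[i] = acq.defocus_nominal
    return out


def invert_corruption(tilt_series: TiltSeries, acq: AcquisitionSpec,
                      model: CtfModel | None = None, n_strips: int = 16,
                      floor: float = 0.05) -> TiltSeries:
    """Exact known-forward-model inverse of :func:`corrupt` (noise aside).

    Divides each strip by the CTF where |CTF| exceeds *floor* (restoring
    sign and amplitude) and by the MTF floored the same way.
    """
    model = model or CtfModel(defocus_um=acq.defocus_nominal)
    out = tilt_series.copy()
    for i, ang in enumerate(out.tilt_angles):
        img = out.images[i]
        bounds, defoci = _strip_ctfs(img.shape, out.pixel_size, ang,
                                     out.tilt_axis, acq.defocus_nominal,
                                     model, n_strips)

        def inv(F, c):
            sign = np.where(c < 0, -1.0, 1.0)
            denom = np.where(np.abs(c) > floor, c, floor * sign)
            return F / denom

        img = _apply_per_strip(img, bounds, defoci, out.pixel_size, model, inv)
        if model.mtf != "unit":
            m = mtf_2d(img.shape, out.pixel_size, model)
            img = np.fft.ifft2(np.fft.fft2(img) / np.maximum(m, floor)).real
        out.images[i] = img
    return out


# ---------------------------------------------------------------------------
# Weighted backprojection
# ---------------------------------------------------------------------------

def weighted_backprojection(tilt_series: TiltSeries,
                            mask_to_wedge: bool = True) -> Volume:
    """Ramp-weighted (r*-weighted) backprojection of a tilt series.

    Each projection is weighted in 2-D Fourier space by |k_perp| (frequency
    component perpendicular to the tilt axis), smeared along the beam and
    rotated back; the result is restricted to the sampled Fourier wedge so
    the unsampled region is empty by construction.
    """
    ts = tilt_series
    if len(ts.tilt_angles) < 3:
        raise ValueError("weighted backprojection needs at least 3 projections")
    n = ts.images.shape[1]
    if ts.images.shape[2] != n:
        raise ValueError("projections must be square")
    az = np.deg2rad(ts.tilt_axis)
    fx = np.fft.fftfreq(n)
    kx, ky = np.meshgrid(fx, fx, indexing="ij")
    kperp = np.abs(kx * np.cos(az) - ky * np.sin(az))
    kperp.flat[0] = np.abs(fx[1]) / 2.0  # keep a little DC
    vol = np.zeros((n, n, n), dtype=np.float64)
    for img, ang in zip(ts.images, ts.tilt_angles):
        weighted = np.fft.ifft2(np.fft.fft2(img) * kperp).real
        smear = np.repeat(weighted[:, :, None], n, axis=2) / n
        vol += _affine(smear.astype(np.float32),
                       _tilt_matrix(ang, ts.tilt_axis).T, np.zeros(3),
                       order=1, cval=0.0)
    span = ts.tilt_angles.max() - ts.tilt_angles.min()
    if mask_to_wedge and span < 179.0:
        wedge = WedgeMask(ts.tilt_angles.min(), ts.tilt_angles.max(),
                          (n, n, n))
        vol = np.fft.ifftn(np.fft.fftn(vol) * wedge.grid).real
    return Volume(vol.astype(np.float32), ts.pixel_size)
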