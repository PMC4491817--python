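"""Missing-wedge constrained subtomogram alignment, averaging and FSC.

A tomogram acquired over a limited tilt range (±60° here) leaves a wedge of
Fourier space unsampled.  Correlating two subtomograms is therefore only
meaningful over the *intersection* of their (rotated) Fourier supports; this
module implements that constrained cross-correlation, a restricted-range
exhaustive angular search around the current pose, wedge-compensated
averaging with a single trilinear interpolation per raw particle, and
Fourier shell correlation with threshold-crossing resolution estimates.

The same engine drives every level of the hierarchy: whole-pore (global)
alignment, C8 protomer refinement and subprotomer refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transforms import RigidTransform, apply_transform, _affine, \
    rotation_angle_deg
from .volume import Volume, fourier_shells

__all__ = [
    "WedgeMask", "AngularWindow", "FscCurve", "DegenerateOverlapError",
    "constrained_cc", "align_particle", "align_particles", "average",
    "split_halves", "fsc", "resolution_at", "exclude_at_limits",
    "normalized_cc",
]


class DegenerateOverlapError(ValueError):
    """The intersection of two Fourier supports is too small to correlate."""


# ---------------------------------------------------------------------------
# Wedge masks
# ---------------------------------------------------------------------------

@dataclass
class WedgeMask:
    """Binary Fourier support of a single-axis tilt series.

    Beam along z, tilt axis along y: the projection at tilt angle a samples
    the central plane with kz/kx = tan(a), so a Fourier voxel is inside the
    support when the wrapped angle atan2(kz, kx) falls within
    [tilt_min, tilt_max].  Stored in natural (unshifted) FFT order.
    """

    tilt_min: float
    tilt_max: float
    shape: tuple

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if not self.tilt_min < self.tilt_max:
            raise ValueError("tilt_min must be < tilt_max")
        self._grid: np.ndarray | None = None

    @property
    def grid(self) -> np.ndarray:
        if self._grid is None:
            n = self.shape[0]
            k = np.fft.fftfreq(n) * n
            kx, _, kz = np.meshgrid(k, k, k, indexing="ij")
            ang = np.degrees(np.arctan2(kz, kx))
            ang = (ang + 90.0) % 180.0 - 90.0  # Friedel wrap to [-90, 90)
            self._grid = (ang >= self.tilt_min) & (ang <= self.tilt_max)
        return self._grid

    def rotated(self, matrix: np.ndarray) -> np.ndarray:
        """Support after rotating the particle by *matrix* (boolean grid)."""
        return rotate_support(self.grid, matrix)

    def fraction(self) -> float:
        return float(self.grid.mean())


def rotate_support(grid: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Rotate a Fourier-support mask (natural order) about the zero frequency."""
    shifted = np.fft.fftshift(grid).astype(np.float32)
    rot = _affine(shifted, matrix, np.zeros(3), order=1, cval=0.0)
    return np.fft.ifftshift(rot >= 0.5)


def full_support(shape) -> np.ndarray:
    return np.ones(tuple(int(s) for s in shape), dtype=bool)


# ---------------------------------------------------------------------------
# Angular windows
# ---------------------------------------------------------------------------

@dataclass
class AngularWindow:
    """Symmetric search window (± degrees) per Euler angle, with a grid step."""

    dphi: float
    dtheta: float
    dpsi: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if min(self.dphi, self.dtheta, self.dpsi) < 0:
            raise ValueError("window half-widths must be non-negative")

    def _axis(self, half: float) -> np.ndarray:
        if half == 0:
            return np.array([0.0])
        n = int(round(half / self.step))
        return np.linspace(-n * self.step, n * self.step, 2 * n + 1)

    def offsets(self) -> np.ndarray:
        """(n, 3) array of (dphi, dtheta, dpsi) grid offsets, 0-centered."""
        g = np.meshgrid(self._axis(self.dphi), self._axis(self.dtheta),
                        self._axis(self.dpsi), indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)


# ---------------------------------------------------------------------------
# Constrained cross-correlation
# ---------------------------------------------------------------------------

def _as_data(v) -> np.ndarray:
    return v.data if isinstance(v, Volume) else np.asarray(v, dtype=np.float32)


def constrained_cc(reference, particle, wedge_ref, wedge_particle,
                   transform: RigidTransform | None = None,
                   min_overlap: int = 32) -> float:
    """Normalized cross-correlation over the intersection of Fourier supports.

    The reference and its wedge are rotated by *transform*; correlation is
    evaluated over Omega = rotated ref support ∩ particle support, excluding
    the DC term, with norms computed within Omega.  Result is in [-1, 1].
    """
    ref = _as_data(reference)
    par = _as_data(particle)
    if ref.shape != par.shape:
        raise ValueError("reference and particle must have equal shapes")
    if transform is None:
        transform = RigidTransform.identity()
    rotref = apply_transform(ref, transform)
    wref = (wedge_ref.rotated(transform.matrix) if isinstance(wedge_ref, WedgeMask)
            else full_support(ref.shape) if wedge_ref is None
            else rotate_support(np.asarray(wedge_ref, bool), transform.matrix))
    wpar = (wedge_particle.grid if isinstance(wedge_particle, WedgeMask)
            else full_support(par.shape) if wedge_particle is None
            else np.asarray(wedge_particle, bool))
    omega = wref & wpar
    omega.flat[0] = False  # exclude DC: removes the mean within Omega
    n_omega = int(omega.sum())
    if n_omega < min_overlap:
        raise DegenerateOverlapError(
            f"Fourier support overlap {n_omega} voxels is below the "
            f"floor of {min_overlap}")
    f1 = np.fft.fftn(rotref)[omega]
    f2 = np.fft.fftn(par)[omega]
    num = float(np.real(np.vdot(f2, f1)))
    den = float(np.sqrt(np.vdot(f1, f1).real * np.vdot(f2, f2).real))
    if den == 0:
        return 0.0
    return num / den


def normalized_cc(a, b) -> float:
    """Plain real-space normalized cross-correlation (zero-mean)."""
    x = _as_data(a).astype(np.float64).ravel()
    y = _as_data(b).astype(np.float64).ravel()
    x = x - x.mean()
    y = y - y.mean()
    den = np.sqrt((x * x).sum() * (y * y).sum())
    return float((x * y).sum() / den) if den else 0.0


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _phase_ramp(shape, shift) -> np.ndarray:
    """exp(-2πi k·s / N): Fourier factor of a real-space shift by *s* voxels."""
    n = shape[0]
    k = np.fft.fftfreq(n)
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    return np.exp(-2j * np.pi * (kx * shift[0] + ky * shift[1] + kz * shift[2]))


def _peak_parabolic(ccmap: np.ndarray, bound: float) -> tuple[np.ndarray, float]:
    """Integer peak of a circular CC map within |shift| <= bound, refined
    per-axis by parabolic interpolation."""
    n = ccmap.shape[0]
    k = np.fft.fftfreq(n) * n  # signed shift value of each index
    allowed = (np.abs(k[:, None, None]) <= bound) \
        & (np.abs(k[None, :, None]) <= bound) \
        & (np.abs(k[None, None, :]) <= bound)
    masked = np.where(allowed, ccmap, -np.inf)
    idx = np.unravel_index(int(np.argmax(masked)), ccmap.shape)
    peak = float(ccmap[idx])
    shift = np.array([k[i] for i in idx], dtype=float)
    for ax in range(3):
        lo = list(idx); hi = list(idx)
        lo[ax] = (idx[ax] - 1) % n
        hi[ax] = (idx[ax] + 1) % n
        ym, y0, yp = ccmap[tuple(lo)], peak, ccmap[tuple(hi)]
        denom = ym - 2 * y0 + yp
        if denom < 0:  # concave: refine
            delta = 0.5 * (ym - yp) / denom
            shift[ax] += float(np.clip(delta, -0.5, 0.5))
    return shift, peak


def align_particles(particle_volumes, reference, window: AngularWindow,
                    wedges=None, current=None, shift_bound: float | None = None,
                    n_inner: int = 3, mask: np.ndarray | None = None,
                    wedge_ref: WedgeMask | np.ndarray | None = None):
    """Restricted-range alignment of many particles against one reference.

    For every particle the search composes an incremental rotation (grid of
    Euler offsets from *window*, expressed in the reference frame) and a
    translation onto the current transform.  Candidate rotations of the
    reference are precomputed once and shared across particles.  Rotations
    are scored at the current translation (applied as an exact Fourier phase
    ramp); the translation is then re-read from the cross-correlation map of
    the best rotation, and the inner loop repeats ``n_inner`` times.

    Returns a list of ``(transform, score, at_window_limit)`` tuples; the
    transform maps the *raw* particle into the reference frame, so averaging
    later needs a single interpolation.

    An optional real-space *mask* (reference frame, e.g. the nuclear-envelope
    / central-channel exclusion) multiplies both the rotated references and
    the particles' scoring copies.
    """
    ref = _as_data(reference)
    n = ref.shape[0]
    if shift_bound is None:
        shift_bound = n / 4
    offsets = window.offsets()
    limits = np.array([window.dphi, window.dtheta, window.dpsi])

    # Rotated references, shared across particles.  The Euler grid contains
    # duplicate rotations (phi and psi degenerate at theta = 0), so ties are
    # broken by the smallest rotation magnitude, then the lowest grid index.
    rot_ffts = []
    rot_supports = None
    if wedge_ref is not None:
        wref_grid = (wedge_ref.grid if isinstance(wedge_ref, WedgeMask)
                     else np.asarray(wedge_ref, bool))
        rot_supports = []
    rot_mags = np.empty(len(offsets))
    for j, off in enumerate(offsets):
        dt = RigidTransform(off[0], off[1], off[2])
        rot_mags[j] = rotation_angle_deg(dt)
        rotated = apply_transform(ref, dt.inverse())
        if mask is not None:
            rotated = rotated * mask
        rot_ffts.append(np.fft.fftn(rotated).astype(np.complex64))
        if rot_supports is not None:
            rot_supports.append(rotate_support(wref_grid, dt.inverse().matrix))

    results = []
    n_particles = len(particle_volumes)
    for i in range(n_particles):
        t0 = (current[i] if current is not None else RigidTransform.identity())
        raw = _as_data(particle_volumes[i])
        scoring = apply_transform(raw, t0)
        if mask is not None:
            scoring = scoring * mask
        wedge = wedges[i] if wedges is not None else None
        omega = (wedge.rotated(t0.matrix) if isinstance(wedge, WedgeMask)
                 else full_support(raw.shape) if wedge is None
                 else rotate_support(np.asarray(wedge, bool), t0.matrix))
        omega = omega.copy()
        omega.flat[0] = False
        fp = np.fft.fftn(scoring).astype(np.complex64)
        fp_m = np.conj(fp) * omega
        norm_p = float(np.sqrt(np.sum((fp.real ** 2 + fp.imag ** 2) * omega)))

        u = np.zeros(3)  # shift applied to the rotated reference
        best_j = 0
        for _ in range(max(1, int(n_inner))):
            # ccmap[u] corresponds to multiplying fr * fp_m by exp(+2pi i k.u/N)
            ramp = (_phase_ramp(ref.shape, -u).astype(np.complex64)
                    if np.any(u) else None)
            probe = fp_m * ramp if ramp is not None else fp_m
            scores = np.empty(len(offsets))
            for j, fr in enumerate(rot_ffts):
                if rot_supports is None:
                    num = float(np.real(np.sum(fr * probe)))
                    nr = float(np.sqrt(np.sum(
                        (fr.real ** 2 + fr.imag ** 2) * omega)))
                    den = nr * norm_p
                else:
                    om = rot_supports[j] & omega
                    num = float(np.real(np.sum(fr * probe * om)))
                    nr = float(np.sqrt(np.sum(
                        (fr.real ** 2 + fr.imag ** 2) * om)))
                    npn = float(np.sqrt(np.sum(
                        (fp.real ** 2 + fp.imag ** 2) * om)))
                    den = nr * npn
                scores[j] = num / den if den else -np.inf
            smax = scores.max()
            tied = np.flatnonzero(scores >= smax - 1e-6)
            # equal rotations carry several Euler labels; prefer the
            # smallest magnitude, then the smallest label (else identity
            # would be reported as an at-window-limit (-w, 0, +w) offset)
            label = np.abs(offsets[tied]).max(axis=1)
            order = np.lexsort((tied, label, np.round(rot_mags[tied], 6)))
            best_j = int(tied[order[0]])
            fr = rot_ffts[best_j]
            if rot_supports is None:
                ccmap = np.fft.ifftn(fr * fp_m).real
            else:
                ccmap = np.fft.ifftn(
                    fr * np.conj(fp) * (rot_supports[best_j] & omega)).real
            u, _ = _peak_parabolic(ccmap, shift_bound)
        fr = rot_ffts[best_j]
        ramp = _phase_ramp(ref.shape, -u).astype(np.complex64)
        if rot_supports is None:
            nr = float(np.sqrt(np.sum((fr.real ** 2 + fr.imag ** 2) * omega)))
            score = float(np.real(np.sum(fr * fp_m * ramp))) / (nr * norm_p)
        else:
            om = rot_supports[best_j] & omega
            nr = float(np.sqrt(np.sum((fr.real ** 2 + fr.imag ** 2) * om)))
            npn = float(np.sqrt(np.sum((fp.real ** 2 + fp.imag ** 2) * om)))
            score = float(np.real(np.sum(fr * np.conj(fp) * om * ramp))) \
                / (nr * npn)

        off = offsets[best_j]
        # Scoring matched apply(ref, dR^-1) shifted by u against the rotated
        # particle; the incremental particle->reference move is (dR, s) with
        # s = dR @ u, composed onto the current transform.
        drot = RigidTransform(off[0], off[1], off[2])
        s = drot.matrix @ u
        t_new = RigidTransform(off[0], off[1], off[2], s).compose(t0)
        at_limit = bool(np.any((limits > 0)
                        & (np.abs(np.abs(off) - limits) < window.step / 2)))
        results.append((t_new, score, at_limit))
    return results


def align_particle(particle, reference, window: AngularWindow, wedge=None,
                   current: RigidTransform | None = None,
                   shift_bound: float | None = None, n_inner: int = 3):
    """Single-particle wrapper around :func:`align_particles`."""
    res = align_particles([particle], reference, window,
                          wedges=None if wedge is None else [wedge],
                          current=None if current is None else [current],
                          shift_bound=shift_bound, n_inner=n_inner)
    return res[0]


# ---------------------------------------------------------------------------
# Averaging
# ---------------------------------------------------------------------------

def average(particle_volumes, transforms=None, wedges=None,
            coverage_floor: float = 1e-3, mask: np.ndarray | None = None,
            normalize: bool = True) -> Volume:
    """Wedge-compensated average with one trilinear interpolation per particle.

    Each raw particle is resampled exactly once under its composed transform;
    its Fourier data, masked to its rotated wedge support, is accumulated and
    the sum is divided by the accumulated wedge coverage (floored at
    ``coverage_floor`` x max coverage to avoid amplifying barely-sampled
    voxels).  The output is normalized to zero mean / unit variance inside
    *mask* (whole box by default).
    """
    vols = [(_as_data(v)) for v in particle_volumes]
    if len(vols) == 0:
        raise ValueError("cannot average an empty particle set")
    shape = vols[0].shape
    voxel = (particle_volumes[0].voxel_size
             if isinstance(particle_volumes[0], Volume) else 1.0)
    fsum = np.zeros(shape, dtype=np.complex128)
    cov = np.zeros(shape, dtype=np.float64)
    for i, raw in enumerate(vols):
        t = transforms[i] if transforms is not None else RigidTransform.identity()
        aligned = apply_transform(raw, t)
        if wedges is not None and wedges[i] is not None:
            w = wedges[i]
            sup = (w.rotated(t.matrix) if isinstance(w, WedgeMask)
                   else rotate_support(np.asarray(w, bool), t.matrix))
        else:
            sup = full_support(shape)
        fsum += np.fft.fftn(aligned) * sup
        cov += sup
    floor = coverage_floor * cov.max()
    out = np.fft.ifftn(fsum / np.maximum(cov, floor)).real
    if normalize:
        sel = mask > 0.5 if mask is not None else np.ones(shape, bool)
        mu, sd = out[sel].mean(), out[sel].std()
        out = (out - mu) / (sd if sd > 0 else 1.0)
    return Volume(out.astype(np.float32), voxel)


def coverage_fraction(transforms, wedge: WedgeMask,
                      coverage_floor: float = 1e-3) -> float:
    """Fraction of Fourier voxels left unsampled after pooling rotated wedges."""
    cov = np.zeros(wedge.shape, dtype=np.float64)
    for t in transforms:
        cov += wedge.rotated(t.matrix)
    return float((cov < coverage_floor * max(cov.max(), 1e-30)).mean())


# ---------------------------------------------------------------------------
# Half sets and FSC
# ---------------------------------------------------------------------------

def split_halves(particle_ids, mode: str = "fsc", labels=None):
    """Split particles into two disjoint sets.

    mode "fsc": odd/even by particle id.  mode "cross": by study label
    (exactly two distinct labels required).
    """
    ids = np.asarray(particle_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 particles to split")
    if mode == "fsc":
        even = ids[np.asarray(ids) % 2 == 0]
        odd = ids[np.asarray(ids) % 2 == 1]
        return even, odd
    if mode == "cross":
        if labels is None:
            raise ValueError("cross mode requires labels")
        labels = np.asarray(labels)
        uniq = np.unique(labels)
        if len(uniq) != 2:
            raise ValueError(f"cross mode requires exactly 2 labels, got {uniq}")
        return ids[labels == uniq[0]], ids[labels == uniq[1]]
    raise ValueError(f"unknown split mode {mode!r}")


@dataclass
class FscCurve:
    """Fourier shell correlation versus spatial frequency (1/Angstrom)."""

    frequencies: np.ndarray
    values: np.ndarray
    threshold_label: str = ""
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)


def fsc(volume_a, volume_b, voxel_size: float | None = None) -> FscCurve:
    """Per-shell normalized correlation between two maps of equal shape."""
    a = _as_data(volume_a)
    b = _as_data(volume_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if voxel_size is None:
        voxel_size = (volume_a.voxel_size if isinstance(volume_a, Volume) else 1.0)
    if isinstance(volume_a, Volume) and isinstance(volume_b, Volume):
        if abs(volume_a.voxel_size - volume_b.voxel_size) > 1e-6:
            raise ValueError("voxel size mismatch")
    n = a.shape[0]
    shells = fourier_shells(a.shape).ravel()
    fa = np.fft.fftn(a).ravel()
    fb = np.fft.fftn(b).ravel()
    nmax = n // 2
    num = np.bincount(shells, weights=np.real(fa * np.conj(fb)),
                      minlength=nmax + 1)[:nmax + 1]
    da = np.bincount(shells, weights=np.abs(fa) ** 2, minlength=nmax + 1)[:nmax + 1]
    db = np.bincount(shells, weights=np.abs(fb) ** 2, minlength=nmax + 1)[:nmax + 1]
    den = np.sqrt(da * db)
    vals = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    freqs = np.arange(nmax + 1) / (n * voxel_size)
    return FscCurve(freqs, np.clip(vals, -1.0, 1.0), voxel_size=voxel_size)


def resolution_at(curve: FscCurve, threshold: float,
                  return_flag: bool = False):
    """Resolution (Angstrom) at the first downward crossing of *threshold*.

    Linearly interpolated between shells.  If the curve never drops below
    the threshold the Nyquist resolution (2 x voxel size) is returned with
    the ``no_crossing`` flag set.
    """
    v = curve.values
    f = curve.frequencies
    res = None
    for i in range(1, len(v)):
        if v[i] < threshold <= v[i - 1]:
            if v[i] == v[i - 1]:
                fc = f[i]
            else:
                fc = f[i - 1] + (threshold - v[i - 1]) * (f[i] - f[i - 1]) \
                    / (v[i] - v[i - 1])
            res = 1.0 / fc if fc > 0 else np.inf
            break
    no_crossing = res is None
    if no_crossing:
        res = 2.0 * curve.voxel_size
    return (res, no_crossing) if return_flag else res


# ---------------------------------------------------------------------------
# Exclusion bookkeeping
# ---------------------------------------------------------------------------

def exclude_at_limits(table: pd.DataFrame,
                      flag_column: str = "at_window_limit") -> pd.DataFrame:
    """Mark particles whose alignment landed on the window boundary.

    Rows with the flag set get ``keep=False`` and reason ``angle_at_limit``;
    all other rows are untouched.  Returns a new table.
    """
    if flag_column not in table.columns:
        raise ValueError(f"table has no {flag_column!r} column")
    out = table.copy()
    hit = out[flag_column].astype(bool) & out["keep"]
    out.loc[hit, "keep"] = False
    out.loc[hit, "reason"] = "angle_at_limit"
    return out
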