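"""Ground-truth NPC phantoms and benchmark subtomogram generation.

The phantom emulates the specimen geometry the pipeline is built for: an
eightfold-symmetric pore of eight 40 nm spheres on a 90 nm circle, decorated
with C8-replicated protomer substructure (a cytoplasmic-ring-like blob above
the midplane, a smaller nucleoplasmic blob below it, and an off-azimuth blob
that breaks the protomer's internal symmetry), optionally embedded in a
double-membrane patch on a gently curved oblate-spheroidal surface.  Two
optional features make downstream contracts testable: a *variable domain*
whose content is re-randomized per particle (local-resolution contrast) and
a planted asymmetric "Y-complex-like" rigid body at a known pose (docking
recovery).

Scale presets
-------------
paper : 3.3 Å voxels, 512-voxel particle boxes (reference acquisition).
desk  : 13.2 Å voxels, 256-voxel tomograms, 128-voxel particle boxes.
bench : 26.4 Å voxels, 64-voxel particle boxes — the full 169 nm field of
        the reference boxes at 1/8 sampling, small enough for minute-scale
        benchmark problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .particles import new_particle_table
from .transforms import RigidTransform, apply_transform, rotation_angle_deg
from .volume import Volume, soft_sphere_mask
from .align import WedgeMask

__all__ = [
    "PAPER_VOXEL_A", "DESK_VOXEL_A", "BENCH_VOXEL_A",
    "PorePhantom", "PlacementError",
    "make_npc_density", "make_y_body", "build_phantom",
    "make_subtomograms", "c8_angular_error",
]

PAPER_VOXEL_A = 3.3   #: reference pixel size at the specimen level (Å)
DESK_VOXEL_A = 13.2   #: 4x-binned desk-scale voxel (Å)
BENCH_VOXEL_A = 26.4  #: 8x-binned benchmark voxel (Å)

RING_DIAMETER_NM = 90.0    #: circle carrying the eight template spheres
SPHERE_DIAMETER_NM = 40.0  #: template sphere diameter
LUMEN_HEIGHT_NM = 35.0     #: luminal spacing of the double membrane


def _add_soft_sphere(data: np.ndarray, center_vox, radius_vox: float,
                     amplitude: float = 1.0, edge_vox: float | None = None) -> None:
    """Accumulate a raised-cosine-edged solid sphere in place.

    The edge defaults to max(2, radius/3) voxels: wide enough that a 45°
    trilinear resampling of the C8-symmetric assembly stays above 0.999
    self-correlation at benchmark sampling.
    """
    if edge_vox is None:
        edge_vox = max(2.0, radius_vox / 3.0)
    shape = data.shape
    lo = [max(0, int(np.floor(c - radius_vox - 1))) for c in center_vox]
    hi = [min(s, int(np.ceil(c + radius_vox + 2))) for s, c in zip(shape, center_vox)]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    grids = np.meshgrid(*[np.arange(l, h, dtype=np.float32)
                          for l, h in zip(lo, hi)], indexing="ij")
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center_vox)))
    edge = max(edge_vox, 1e-6)
    prof = np.clip((radius_vox - r) / edge, 0.0, 1.0)
    prof = 0.5 * (1.0 - np.cos(np.pi * prof))
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * prof


@dataclass
class PorePhantom:
    """Parameters of the synthetic eightfold pore."""

    box: int = 64
    voxel_size: float = BENCH_VOXEL_A
    ring_diameter_nm: float = RING_DIAMETER_NM
    sphere_diameter_nm: float = SPHERE_DIAMETER_NM
    n_fold: int = 8
    substructure: bool = True
    variable_domain: tuple | None = None  # ((cx, cy, cz) vox, radius vox)
    planted_body_pose: RigidTransform | None = None

    def protomer_radius_vox(self) -> float:
        return self.ring_diameter_nm * 10.0 / 2.0 / self.voxel_size


def make_npc_density(phantom: PorePhantom) -> Volume:
    """Render the C8-symmetric pore density (variable domain *not* included)."""
    n = phantom.box
    vox = phantom.voxel_size
    data = np.zeros((n, n, n), dtype=np.float32)
    c = n // 2
    ring_r = phantom.ring_diameter_nm * 10.0 / 2.0 / vox
    sph_r = phantom.sphere_diameter_nm * 10.0 / 2.0 / vox
    for k in range(phantom.n_fold):
        a = 2.0 * np.pi * k / phantom.n_fold
        _add_soft_sphere(data, (c + ring_r * np.cos(a), c + ring_r * np.sin(a), c),
                         sph_r, 1.0)
        if phantom.substructure:
            # protomer substructure, C8-replicated: breaks the z-mirror and
            # the protomer's internal left/right symmetry
            r1 = 330.0 / vox  # 33 nm ring-moiety radius
            z1 = 170.0 / vox  # cytoplasmic blob height
            _add_soft_sphere(data, (c + r1 * np.cos(a), c + r1 * np.sin(a), c + z1),
                             90.0 / vox, 1.2)
            _add_soft_sphere(data, (c + r1 * np.cos(a), c + r1 * np.sin(a), c - z1),
                             60.0 / vox, 1.0)
            a2 = a + np.deg2rad(12.0)
            _add_soft_sphere(data, (c + ring_r * np.cos(a2), c + ring_r * np.sin(a2),
                                    c + 80.0 / vox), 50.0 / vox, 0.9)
    if phantom.planted_body_pose is not None:
        body = make_y_body(n, vox)
        placed = apply_transform(body.data, phantom.planted_body_pose, cval=0.0)
        data += placed
    return Volume(data, vox)


def make_y_body(box: int = 40, voxel_size: float = DESK_VOXEL_A) -> Volume:
    """Asymmetric 'Y-complex-like' rigid body (~45 nm extended) in its own box.

    A beaded stem and two unequal arms, out-of-plane kinks and a stem-base
    knob: enough low-resolution texture that no wrong orientation of the
    body correlates highly with the right one.
    """
    data = np.zeros((box, box, box), dtype=np.float32)
    c = box // 2
    vox = voxel_size

    def nm(v):
        return v * 10.0 / vox

    # stem (beaded, slightly curved out of plane)
    for i, t in enumerate(np.linspace(0, 1, 8)):
        _add_soft_sphere(data, (c + nm(2) * t * t, c - nm(13) * t,
                                c + nm(3) * t),
                         nm(3.4 - 0.8 * t), 1.0)
    # long arm with terminal bead
    for t in np.linspace(0, 1, 6):
        _add_soft_sphere(data, (c + nm(10) * t, c + nm(9) * t, c - nm(4) * t),
                         nm(2.8), 0.9)
    _add_soft_sphere(data, (c + nm(10), c + nm(9), c - nm(4)), nm(3.8), 1.2)
    # short arm, kinked the other way
    for t in np.linspace(0, 1, 4):
        _add_soft_sphere(data, (c - nm(8) * t, c + nm(7) * t, c + nm(5) * t),
                         nm(2.4), 0.8)
    # stem-base knob + perpendicular hook: breaks pseudo-symmetries
    _add_soft_sphere(data, (c + nm(2), c - nm(13), c + nm(3)), nm(4.6), 1.3)
    _add_soft_sphere(data, (c + nm(7), c - nm(10), c + nm(1)), nm(3.0), 1.1)
    return Volume(data, voxel_size)


def add_variable_domain(density: np.ndarray, center_vox, radius_vox: float,
                        rng: np.random.Generator,
                        amplitude: float | None = None) -> np.ndarray:
    """Return a copy with the spherical region replaced by a smooth random blob.

    Emulates a structurally variable subdomain: its content differs from
    particle to particle, so its local resolution must degrade relative to
    the rigid remainder.
    """
    out = density.copy()
    mask = soft_sphere_mask(out.shape, center_vox, radius_vox, edge_width=2.0)
    field_ = rng.normal(size=out.shape).astype(np.float32)
    f = np.fft.fftn(field_)
    n = out.shape[0]
    k = np.fft.fftfreq(n) * n
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    kr = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
    smooth = np.fft.ifftn(f * np.exp(-(kr / (n / 16.0)) ** 2)).real
    smooth = smooth / (smooth.std() + 1e-12)
    if amplitude is None:
        # variability must rival the local structure it replaces: both the
        # removed density's edge and the mask boundary stay common to every
        # particle, and a weaker random field would leave that common
        # content dominating the local correlation
        msum = float(mask.sum())
        local_rms = np.sqrt(float((density ** 2 * mask).sum())
                            / max(msum, 1.0))
        amplitude = 2.5 * max(local_rms, float(density.std()))
    # zero-mean random content: a one-signed field would imprint the mask
    # shape itself
    out = out * (1.0 - mask) + amplitude * smooth * mask
    return out


# ---------------------------------------------------------------------------
# Tomogram-level phantom
# ---------------------------------------------------------------------------

class PlacementError(ValueError):
    """Requested NPC copies overlap; carries the colliding index pairs."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        super().__init__(f"overlapping NPC copies: {self.pairs}")


@dataclass
class MembraneSpec:
    """Oblate spheroid carrying the double membrane patch (all nm)."""

    # centered so the upper surface apex passes through the tomogram center:
    # gentle curvature, a few degrees of normal tilt across the field
    center_nm: tuple = (0.0, 0.0, -450.0)
    semi_axis_a_nm: float = 900.0
    semi_axis_c_nm: float = 450.0
    lumen_height_nm: float = LUMEN_HEIGHT_NM
    shell_sigma_nm: float = 4.0


def _spheroid_surface_z(mem: MembraneSpec, x_nm, y_nm):
    """Upper surface height z(x, y) of the spheroid, relative to its center."""
    a, cax = mem.semi_axis_a_nm, mem.semi_axis_c_nm
    arg = 1.0 - (x_nm / a) ** 2 - (y_nm / a) ** 2
    return cax * np.sqrt(np.clip(arg, 0.0, None))


def _spheroid_normal(mem: MembraneSpec, x_nm, y_nm, z_nm):
    a, cax = mem.semi_axis_a_nm, mem.semi_axis_c_nm
    n = np.array([2 * x_nm / a ** 2, 2 * y_nm / a ** 2, 2 * z_nm / cax ** 2])
    return n / np.linalg.norm(n)


def build_phantom(n_copies: int = 4, tomo_shape=(128, 128, 128),
                  voxel_size: float = BENCH_VOXEL_A,
                  phantom: PorePhantom | None = None,
                  membrane: MembraneSpec | None = None,
                  tilt_cap_deg: float = 12.0, min_margin_vox: int = 2,
                  seed: int = 0, positions_vox=None):
    """Tomogram-sized ground-truth density plus the exact per-copy poses.

    NPC copies sit on the upper surface of the membrane spheroid with the
    pore axis along the local outward normal (out-of-plane tilt therefore
    bounded by the patch curvature and ``tilt_cap_deg``) and a uniform
    in-plane rotation.  Returns ``(tomogram, table, normals)`` where the
    table's transforms map each raw subtomogram crop into the phantom's
    reference frame.

    Raises :class:`PlacementError` when copies overlap.
    """
    rng = np.random.default_rng(seed)
    phantom = phantom or PorePhantom(box=64, voxel_size=voxel_size)
    membrane = membrane or MembraneSpec()
    shape = tuple(int(s) for s in tomo_shape)
    tomo = np.zeros(shape, dtype=np.float32)
    center = np.array([s // 2 for s in shape], dtype=float)
    extent_vox = (phantom.ring_diameter_nm + phantom.sphere_diameter_nm) \
        * 10.0 / voxel_size
    min_sep = extent_vox + min_margin_vox

    # sample positions on the membrane surface
    half = phantom.box // 2
    margin = half + min_margin_vox
    placed = []
    attempts = 0
    if positions_vox is None:
        positions_vox = []
        while len(positions_vox) < n_copies and attempts < 2000:
            attempts += 1
            px = rng.uniform(margin, shape[0] - margin)
            py = rng.uniform(margin, shape[1] - margin)
            x_nm = (px - center[0]) * voxel_size / 10.0
            y_nm = (py - center[1]) * voxel_size / 10.0
            zc_nm = membrane.center_nm[2]
            z_nm = zc_nm + _spheroid_surface_z(membrane, x_nm, y_nm)
            pz = center[2] + z_nm * 10.0 / voxel_size
            if not (margin <= pz <= shape[2] - margin):
                continue
            if all(np.linalg.norm(np.array([px, py, pz]) - np.array(q)) >= min_sep
                   for q in positions_vox):
                positions_vox.append((px, py, pz))
        if len(positions_vox) < n_copies:
            raise PlacementError([("unplaceable", n_copies)])
    else:
        positions_vox = [tuple(map(float, p)) for p in positions_vox]
        pairs = [(i, j) for i in range(len(positions_vox))
                 for j in range(i + 1, len(positions_vox))
                 if np.linalg.norm(np.array(positions_vox[i])
                                   - np.array(positions_vox[j])) < min_sep]
        if pairs:
            raise PlacementError(pairs)

    base = make_npc_density(phantom)

    # membrane shells: distance to the spheroid surface approximated along z
    gx = (np.arange(shape[0]) - center[0]) * voxel_size / 10.0
    gy = (np.arange(shape[1]) - center[1]) * voxel_size / 10.0
    gz = (np.arange(shape[2]) - center[2]) * voxel_size / 10.0
    surf = membrane.center_nm[2] + _spheroid_surface_z(
        membrane, gx[:, None], gy[None, :])
    dz = gz[None, None, :] - surf[:, :, None]
    sig = membrane.shell_sigma_nm
    h = membrane.lumen_height_nm / 2.0
    mem_density = 0.8 * (np.exp(-0.5 * ((dz - h) / sig) ** 2)
                         + np.exp(-0.5 * ((dz + h) / sig) ** 2))
    # carve the pores
    for (px, py, pz) in positions_vox:
        rxy = np.sqrt(((np.arange(shape[0]) - px)[:, None]) ** 2
                      + ((np.arange(shape[1]) - py)[None, :]) ** 2)
        hole = np.clip((rxy * voxel_size / 10.0) / (phantom.ring_diameter_nm / 2.0),
                       0, 1) ** 2
        mem_density *= np.minimum(hole, 1.0)[:, :, None]
    tomo += mem_density.astype(np.float32)

    table = new_particle_table(len(positions_vox))
    normals = []
    for i, (px, py, pz) in enumerate(positions_vox):
        x_nm = (px - center[0]) * voxel_size / 10.0
        y_nm = (py - center[1]) * voxel_size / 10.0
        z_nm = (pz - center[2]) * voxel_size / 10.0 - membrane.center_nm[2]
        normal = _spheroid_normal(membrane, x_nm, y_nm, z_nm)
        if normal[2] < 0:
            normal = -normal
        normals.append(normal)
        tilt = np.degrees(np.arccos(np.clip(normal[2], -1, 1)))
        tilt = min(tilt, tilt_cap_deg)
        az = np.degrees(np.arctan2(normal[1], normal[0]))
        psi_inplane = rng.uniform(0.0, 360.0)
        # orientation: pore axis along the normal, then in-plane spin
        rot = Rotation.from_euler(
            "ZXZ", [az + 90.0, tilt, psi_inplane], degrees=True)
        t_ref_to_tomo = RigidTransform.from_matrix(rot.as_matrix())
        # embed: resample the phantom under the pose and paste
        posed = apply_transform(base.data, t_ref_to_tomo, cval=0.0)
        lo = [int(round(p)) - half for p in (px, py, pz)]
        sl_t, sl_p = [], []
        for ax in range(3):
            t0 = max(lo[ax], 0)
            t1 = min(lo[ax] + phantom.box, shape[ax])
            sl_t.append(slice(t0, t1))
            sl_p.append(slice(t0 - lo[ax], t1 - lo[ax]))
        tomo[tuple(sl_t)] += posed[tuple(sl_p)]
        table.loc[i, ["x", "y", "z"]] = [px, py, pz]
        t_align = t_ref_to_tomo.inverse()  # maps raw crop -> reference frame
        table.loc[i, ["phi", "theta", "psi"]] = list(t_align.angles())
        table.loc[i, ["dx", "dy", "dz"]] = list(t_align.shift)
    return Volume(tomo, voxel_size), table, np.array(normals)


# ---------------------------------------------------------------------------
# Benchmark subtomograms (direct, no tilt-series round trip)
# ---------------------------------------------------------------------------

def make_subtomograms(n_particles: int, box: int = 64,
                      voxel_size: float = BENCH_VOXEL_A, snr: float = 0.5,
                      tilt_range=(-60.0, 60.0), seed: int = 0,
                      angle_spread=(25.0, 10.0, 25.0), shift_spread: float = 2.0,
                      phantom: PorePhantom | None = None,
                      variable_domain: tuple | None = None,
                      reference: Volume | None = None):
    """Wedge-filtered, noisy particles at known poses.

    Each particle is the reference density resampled under the inverse of a
    random pose, Fourier-masked to the ±60° wedge in its own frame, and
    degraded with white Gaussian noise scaled so that
    ``var(signal)/var(noise) = snr`` inside the particle envelope.

    Returns ``(particles, true_transforms, wedge)``; each true transform
    maps the raw particle into the reference frame (the quantity alignment
    must recover).
    """
    rng = np.random.default_rng(seed)
    if reference is None:
        phantom = phantom or PorePhantom(box=box, voxel_size=voxel_size)
        reference = make_npc_density(phantom)
    ref = reference.data
    wedge = WedgeMask(tilt_range[0], tilt_range[1], ref.shape)
    envelope = soft_sphere_mask(ref.shape, radius=box * 0.45, edge_width=2)
    env = envelope > 0.5
    particles, transforms = [], []
    for _ in range(n_particles):
        phi = rng.uniform(-angle_spread[0], angle_spread[0])
        theta = rng.uniform(0.0, angle_spread[1])
        psi = rng.uniform(-angle_spread[2], angle_spread[2])
        shift = rng.uniform(-shift_spread, shift_spread, 3)
        t_true = RigidTransform(phi, theta, psi, shift)  # raw -> reference
        src = ref
        if variable_domain is not None:
            src = add_variable_domain(ref, variable_domain[0],
                                      variable_domain[1], rng)
        raw = apply_transform(src, t_true.inverse())
        if snr and np.isfinite(snr):
            sig_var = float(raw[env].var())
            raw = raw + rng.normal(0.0, np.sqrt(sig_var / snr), raw.shape)
        # wedge-filter signal AND noise: a reconstruction cannot contain
        # out-of-wedge content, and that emptiness is exactly what biases
        # wedge-ignorant correlation
        raw = np.fft.ifftn(np.fft.fftn(raw) * wedge.grid).real
        particles.append(Volume(raw.astype(np.float32), voxel_size))
        transforms.append(t_true)
    return particles, transforms, wedge


def c8_angular_error(found: RigidTransform, true: RigidTransform,
                     n_fold: int = 8) -> float:
    """Smallest rotation angle between two poses modulo the C_n symmetry."""
    errs = []
    for k in range(n_fold):
        sym = RigidTransform(360.0 * k / n_fold, 0.0, 0.0)
        errs.append(rotation_angle_deg(sym.compose(found), true))
    return float(min(errs))
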