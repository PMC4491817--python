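"""NPC-specific scaffolding around the generic alignment engine.

Covers the geometric starting template (eight 40 nm spheres on a 90 nm
circle), oblate-spheroid fits to nuclear-envelope points with normal-based
orientation verification, extraction of the eight C8 protomers and their
three subprotomers with exact transform bookkeeping (crops stay raw; only
transforms are composed), soft alignment masks (nuclear-envelope/lumen slab
and the <17 nm central-channel exclusion), top-view balancing, eightfold
model assembly, and simple pore metrics including the central-channel
cylinder volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .particles import set_transform, transform_of
from .phantom import RING_DIAMETER_NM, SPHERE_DIAMETER_NM, _add_soft_sphere
from .transforms import RigidTransform, apply_transform
from .volume import Volume, soft_sphere_mask

__all__ = [
    "SpheroidModel", "ProtomerSpec", "FitError", "BoundaryError",
    "make_geometric_template", "fit_spheroid", "normal_at",
    "verify_orientation", "verify_orientations", "extract_protomers",
    "balance_views", "subdivide_subprotomers", "make_masks",
    "assemble_model", "measure_pore_metrics", "cylinder_volume_nm3",
]


class FitError(ValueError):
    """Spheroid fit is degenerate (coplanar or insufficient points)."""


class BoundaryError(ValueError):
    """A crop would leave its source volume; carries the offending indices."""

    def __init__(self, indices, message="crop outside volume"):
        self.indices = list(indices)
        super().__init__(f"{message}: {self.indices}")


# ---------------------------------------------------------------------------
# Geometric template
# ---------------------------------------------------------------------------

def make_geometric_template(box: int, voxel_size: float,
                            ring_diameter_nm: float = RING_DIAMETER_NM,
                            sphere_diameter_nm: float = SPHERE_DIAMETER_NM,
                            n_fold: int = 8,
                            edge_vox: float | None = None) -> Volume:
    """Starting reference: soft solid spheres on a circle in the mid-z plane.

    The raised-cosine edge defaults to a third of the sphere radius so a 45°
    trilinear resampling keeps the template's C8 self-correlation >= 0.999.
    """
    ring_r = ring_diameter_nm * 10.0 / 2.0 / voxel_size
    sph_r = sphere_diameter_nm * 10.0 / 2.0 / voxel_size
    if 2 * (ring_r + sph_r) + 2 > box:
        raise ValueError(
            f"template geometry (diameter {2 * (ring_r + sph_r):.1f} voxels) "
            f"exceeds box {box}")
    data = np.zeros((box, box, box), dtype=np.float32)
    c = box // 2
    for k in range(n_fold):
        a = 2.0 * np.pi * k / n_fold
        _add_soft_sphere(data, (c + ring_r * np.cos(a), c + ring_r * np.sin(a), c),
                         sph_r, 1.0, edge_vox=edge_vox)
    return Volume(data, voxel_size)


# ---------------------------------------------------------------------------
# Spheroid fits and orientation verification
# ---------------------------------------------------------------------------

@dataclass
class SpheroidModel:
    """Oblate spheroid fitted to nuclear-envelope points.

    ``axis`` is the polar (c) axis direction; ``a`` the equatorial and ``c``
    the polar semi-axis, in the units of the fitted points.  ``oblate`` is a
    flag, not an enforced constraint — fits on small patches may invert.
    """

    center: np.ndarray
    a: float
    c: float
    axis: np.ndarray
    quadric: np.ndarray  # 3x3 matrix A with (p-center)^T A (p-center) = 1

    @property
    def oblate(self) -> bool:
        return self.a >= self.c


def fit_spheroid(points) -> SpheroidModel:
    """Least-squares quadric fit constrained to a spheroid (a = b).

    Fits the general quadric p^T A p + b.p = 1, extracts center and
    principal axes, then averages the two closest eigenvalues to impose
    rotational symmetry.  Raises :class:`FitError` for coplanar or
    otherwise degenerate point sets (needs >= 9 non-coplanar points).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 9:
        raise FitError("need at least 9 points of dimension 3")
    x, y, z = pts.T
    design = np.column_stack([x * x, y * y, z * z, x * y, x * z, y * z, x, y, z])
    coef, _, rank, _ = np.linalg.lstsq(design, np.ones(len(pts)), rcond=None)
    if rank < 9:
        raise FitError(f"degenerate point set (design rank {rank} < 9); "
                       "are the points coplanar?")
    a1, a2, a3, a4, a5, a6, b1, b2, b3 = coef
    amat = np.array([[a1, a4 / 2, a5 / 2],
                     [a4 / 2, a2, a6 / 2],
                     [a5 / 2, a6 / 2, a3]])
    bvec = np.array([b1, b2, b3])
    try:
        center = -0.5 * np.linalg.solve(amat, bvec)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular quadric: {exc}") from exc
    s = 1.0 + center @ amat @ center + bvec @ center
    evals, evecs = np.linalg.eigh(amat / s)
    if np.any(evals <= 0):
        # a partial surface cap leaves the general quadric free to pick a
        # hyperboloid; fall back to the axis-aligned spheroid (a = b, polar
        # axis z), which is linear in 5 parameters and always well posed
        return _fit_spheroid_axis_z(pts)
    # spheroid constraint: merge the two closest eigenvalues into the
    # equatorial pair; the remaining one defines the polar axis
    gaps = [abs(evals[1] - evals[2]), abs(evals[0] - evals[2]),
            abs(evals[0] - evals[1])]
    polar = int(np.argmin(gaps))  # index of the odd one out
    eq_idx = [i for i in range(3) if i != polar]
    lam_eq = evals[eq_idx].mean()
    lam_po = evals[polar]
    axis = evecs[:, polar] / np.linalg.norm(evecs[:, polar])
    amat_sym = sum(lam_eq * np.outer(evecs[:, i], evecs[:, i]) for i in eq_idx) \
        + lam_po * np.outer(axis, axis)
    return SpheroidModel(center=center, a=float(1.0 / np.sqrt(lam_eq)),
                         c=float(1.0 / np.sqrt(lam_po)), axis=axis,
                         quadric=amat_sym)


def _fit_spheroid_axis_z(pts: np.ndarray) -> SpheroidModel:
    """Axis-aligned spheroid fit, scale fixed on the quadratic terms.

    Solves p1 (x²+y²) + p2 z² + p3 x + p4 y + p5 z = k with p1 + p2 = 1
    (substituting p2 = 1 − p1 gives an unconstrained linear problem); the
    usual "… = 1" normalization degenerates whenever the surface passes
    near the coordinate origin, which is the rule for a membrane patch.
    """
    x, y, z = pts.T
    r2 = x * x + y * y
    z2 = z * z
    design = np.column_stack([r2 - z2, x, y, z, np.ones(len(pts))])
    coef, _, rank, _ = np.linalg.lstsq(design, -z2, rcond=None)
    if rank < 5:
        raise FitError("degenerate point set for the constrained fit")
    p1, p3, p4, p5, negk = coef
    p2 = 1.0 - p1
    k = -negk
    if p1 <= 0 or p2 <= 0:
        raise FitError("constrained fit is not an ellipsoid")
    center = np.array([-p3 / (2 * p1), -p4 / (2 * p1), -p5 / (2 * p2)])
    s = k + p3 ** 2 / (4 * p1) + p4 ** 2 / (4 * p1) + p5 ** 2 / (4 * p2)
    if s <= 0:
        raise FitError("constrained fit is degenerate")
    lam_eq, lam_po = p1 / s, p2 / s
    axis = np.array([0.0, 0.0, 1.0])
    quad = np.diag([lam_eq, lam_eq, lam_po])
    return SpheroidModel(center=center, a=float(1.0 / np.sqrt(lam_eq)),
                         c=float(1.0 / np.sqrt(lam_po)), axis=axis,
                         quadric=quad)


def normal_at(model: SpheroidModel, position) -> np.ndarray:
    """Outward unit surface normal of the spheroid at (or near) *position*."""
    p = np.asarray(position, dtype=float) - model.center
    grad = 2.0 * model.quadric @ p
    norm = np.linalg.norm(grad)
    if norm == 0:
        raise ValueError("normal undefined at the spheroid center")
    n = grad / norm
    if np.dot(n, p) < 0:
        n = -n
    return n


def pore_axis_of(transform: RigidTransform) -> np.ndarray:
    """Direction of the pore axis in the raw (tomogram) frame.

    The transform maps raw particle to reference; the reference pore axis is
    +z, so the raw-frame axis is R^T z."""
    return transform.matrix.T @ np.array([0.0, 0.0, 1.0])


def verify_orientation(particle_transform: RigidTransform, spheroid_normal,
                       threshold_deg: float = 20.0):
    """Compare the aligned pore axis with the membrane normal.

    The axis is treated as unsigned (the flip is resolved by the recorded
    outward normal, not here).  Returns ``(keep, mismatch_deg)``; the
    particle is kept when the mismatch is <= threshold (strict > excludes).
    """
    normal = np.asarray(spheroid_normal, dtype=float)
    nn = np.linalg.norm(normal)
    if nn == 0:
        raise ValueError("zero-length spheroid normal")
    axis = pore_axis_of(particle_transform)
    cosang = abs(float(np.dot(axis, normal / nn)))
    mismatch = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    # strict > excludes; the epsilon keeps an exactly-threshold mismatch kept
    # despite arccos round-off
    return mismatch <= threshold_deg + 1e-9, mismatch


def verify_orientations(table: pd.DataFrame, normals,
                        threshold_deg: float = 20.0) -> pd.DataFrame:
    """Table-level orientation check: mismatches > threshold are excluded
    with reason ``normal_mismatch``."""
    out = table.copy()
    mismatches = []
    for i, (_, row) in enumerate(out.iterrows()):
        keep, mis = verify_orientation(transform_of(row), normals[i],
                                       threshold_deg)
        mismatches.append(mis)
        if not keep and out.iloc[i]["keep"]:
            out.iloc[i, out.columns.get_loc("keep")] = False
            out.iloc[i, out.columns.get_loc("reason")] = "normal_mismatch"
    out["normal_mismatch_deg"] = mismatches
    return out


# ---------------------------------------------------------------------------
# Protomer / subprotomer extraction
# ---------------------------------------------------------------------------

@dataclass
class ProtomerSpec:
    """Geometry of the C8 protomer hierarchy (dimensions in nm, boxes in
    voxels at the working voxel size).

    Box sizes default to fixed physical extents — 76 nm protomer boxes
    (just containing the ±22 nm subprotomer centers plus their half-boxes)
    and 26.4 nm subprotomer boxes (the reference 80-voxel box at 3.3 Å) —
    so the hierarchy is self-consistent at any sampling.
    """

    voxel_size: float
    n_fold: int = 8
    protomer_box: int | None = None
    subprotomer_box: int | None = None
    protomer_radius_nm: float = RING_DIAMETER_NM / 2.0  # center at ring radius
    protomer_z_nm: float = 0.0
    subprotomer_radius_nm: float = 33.0
    subprotomer_z_nm: tuple = (22.0, -22.0, 0.0)  # CPR, NPR, SR+CCR
    subprotomer_names: tuple = ("cpr", "npr", "sr_ccr")

    def __post_init__(self) -> None:
        if self.protomer_box is None:
            self.protomer_box = 2 * int(round(760.0 / self.voxel_size / 2.0))
        if self.subprotomer_box is None:
            self.subprotomer_box = 2 * int(round(264.0 / self.voxel_size / 2.0))

    def protomer_offset_vox(self) -> np.ndarray:
        return np.array([self.protomer_radius_nm * 10.0 / self.voxel_size, 0.0,
                         self.protomer_z_nm * 10.0 / self.voxel_size])

    def subprotomer_offsets_vox(self) -> dict:
        dr = (self.subprotomer_radius_nm - self.protomer_radius_nm) * 10.0 \
            / self.voxel_size
        return {name: np.array([dr, 0.0, z * 10.0 / self.voxel_size])
                for name, z in zip(self.subprotomer_names,
                                   self.subprotomer_z_nm)}


def _crop_with_transform(volume: np.ndarray, t_global: RigidTransform,
                         rot_ref: np.ndarray, offset_ref_vox: np.ndarray,
                         crop_box: int):
    """Crop the raw region that maps to a sub-frame of the reference.

    The sub-frame is the reference frame rotated by ``rot_ref`` (a matrix
    acting in the reference frame) with its origin at reference-center +
    offset.  Returns ``(crop, transform)`` where the transform maps the raw
    crop into the sub-frame; raises :class:`BoundaryError` when the crop
    leaves the volume.
    """
    n = volume.shape[0]
    c_n = np.array([s // 2 for s in volume.shape], dtype=float)
    c_m = np.full(3, crop_box // 2, dtype=float)
    rg, tg = t_global.matrix, t_global.shift
    p_ref = c_n + rot_ref @ offset_ref_vox
    y = rg.T @ (p_ref - c_n - tg) + c_n  # sub-frame origin in raw coords
    o = np.round(y).astype(int) - crop_box // 2
    if np.any(o < 0) or np.any(o + crop_box > np.array(volume.shape)):
        raise BoundaryError([tuple(o)])
    crop = volume[o[0]:o[0] + crop_box, o[1]:o[1] + crop_box,
                  o[2]:o[2] + crop_box].copy()
    r_p = rot_ref.T @ rg
    t_p = -r_p @ (y - np.round(y))
    return crop, RigidTransform.from_matrix(r_p, t_p)


def extract_protomers(particle_volume, t_global: RigidTransform,
                      spec: ProtomerSpec):
    """Extract the eight asymmetric-unit crops of a globally aligned pore.

    Protomer k's transform composes the global transform with a −45°·k
    rotation about the pore axis plus the radial offset to the protomer
    center, so every crop (still raw data) maps into one shared protomer
    frame; the missing wedge follows the transform automatically and hence
    differs from protomer 0 by exactly 45°·k about the pore axis.

    Returns a list of ``(crop: Volume, transform, k)``; raises
    :class:`BoundaryError` (listing k) when a crop leaves the volume.
    """
    vol = particle_volume.data if isinstance(particle_volume, Volume) \
        else np.asarray(particle_volume, dtype=np.float32)
    voxel = (particle_volume.voxel_size
             if isinstance(particle_volume, Volume) else spec.voxel_size)
    out, bad = [], []
    offset = spec.protomer_offset_vox()
    for k in range(spec.n_fold):
        rot_k = RigidTransform(phi=360.0 * k / spec.n_fold).matrix
        try:
            crop, t_p = _crop_with_transform(vol, t_global, rot_k, offset,
                                             spec.protomer_box)
        except BoundaryError:
            bad.append(k)
            continue
        out.append((Volume(crop, voxel), t_p, k))
    if bad:
        raise BoundaryError(bad, "protomer crop outside tomogram for k")
    return out


def subdivide_subprotomers(protomer_volume, t_protomer: RigidTransform,
                           spec: ProtomerSpec):
    """Cut one protomer into its three named subprotomer crops.

    Each crop rotates about its own box center; transforms are re-centered
    accordingly.  Returns ``{name: (crop, transform)}``.
    """
    vol = protomer_volume.data if isinstance(protomer_volume, Volume) \
        else np.asarray(protomer_volume, dtype=np.float32)
    voxel = (protomer_volume.voxel_size
             if isinstance(protomer_volume, Volume) else spec.voxel_size)
    eye = np.eye(3)
    out = {}
    bad = []
    for name, off in spec.subprotomer_offsets_vox().items():
        try:
            crop, t_s = _crop_with_transform(vol, t_protomer, eye, off,
                                             spec.subprotomer_box)
        except BoundaryError:
            bad.append(name)
            continue
        out[name] = (Volume(crop, voxel), t_s)
    if bad:
        raise BoundaryError(bad, "subprotomer crop outside protomer box for")
    return out


def protomer_consistency(protomers) -> np.ndarray:
    """Pairwise correlation of aligned protomer crops against protomer 0.

    Each crop is resampled under its transform and compared within the
    inscribed soft sphere (voxels outside it can be out-of-field fill from
    the rotation and are undefined by contract).
    """
    aligned = [apply_transform(v.data, t) for v, t, _k in protomers]
    box = aligned[0].shape[0]
    mask = soft_sphere_mask((box,) * 3, radius=box / 2 - 1, edge_width=2) > 0.5
    ccs = []
    a0 = aligned[0][mask] - aligned[0][mask].mean()
    for a in aligned[1:]:
        ai = a[mask] - a[mask].mean()
        den = np.sqrt((a0 ** 2).sum() * (ai ** 2).sum())
        ccs.append(float((a0 * ai).sum() / den) if den else 0.0)
    return np.array(ccs)


# ---------------------------------------------------------------------------
# View balancing
# ---------------------------------------------------------------------------

def balance_views(table: pd.DataFrame, bin_size_deg: float = 15.0,
                  cap: int = 50, score_column: str = "score") -> pd.DataFrame:
    """Limit over-represented pore-axis view directions.

    Particles are binned by the polar angle of their pore axis; within each
    bin only the *cap* highest-scoring particles stay, the rest are excluded
    with reason ``view_balance``.
    """
    out = table.copy()
    polar = []
    for _, row in out.iterrows():
        axis = pore_axis_of(transform_of(row))
        polar.append(np.degrees(np.arccos(np.clip(abs(axis[2]), -1, 1))))
    out["view_polar_deg"] = polar
    bins = (np.asarray(polar) / bin_size_deg).astype(int)
    scores = out[score_column] if score_column in out.columns \
        else pd.Series(np.zeros(len(out)), index=out.index)
    for b in np.unique(bins):
        idx = out.index[(bins == b) & out["keep"].to_numpy()]
        if len(idx) > cap:
            ranked = scores.loc[idx].sort_values(ascending=False)
            drop = ranked.index[cap:]
            out.loc[drop, "keep"] = False
            out.loc[drop, "reason"] = "view_balance"
    return out


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

def _soft_step(r: np.ndarray, r0: float, edge: float) -> np.ndarray:
    """1 below r0, raised-cosine down to 0 at r0 + edge."""
    t = np.clip((r - r0) / max(edge, 1e-6), 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def make_masks(box: int, voxel_size: float, axis_xy_vox=(None, None),
               channel_diameter_nm: float = 17.0,
               ne_z_halfwidth_nm: float = 25.0,
               ne_inner_radius_nm: float = 52.0,
               edge_vox: float = 2.0) -> dict:
    """Soft alignment masks (values in [0, 1]).

    ``channel``   : excludes densities at diameters < 17 nm around the pore
                    axis (the uncharted central-channel region).
    ``ne_lumen``  : excludes the nuclear envelope and its lumen — a z-slab
                    at radii outside the pore wall.
    ``combined``  : product of the two.
    The pore axis crosses the x-y plane at ``axis_xy_vox`` (box center by
    default; protomer-frame masks pass the off-center axis position).
    """
    c = box // 2
    ax = axis_xy_vox[0] if axis_xy_vox[0] is not None else c
    ay = axis_xy_vox[1] if axis_xy_vox[1] is not None else c
    xs = np.arange(box, dtype=np.float32)
    rxy = np.sqrt((xs[:, None] - ax) ** 2 + (xs[None, :] - ay) ** 2)
    chan_r = channel_diameter_nm * 10.0 / 2.0 / voxel_size
    chan2d = 1.0 - _soft_step(rxy, chan_r - edge_vox, edge_vox)
    channel = np.repeat(chan2d[:, :, None], box, axis=2).astype(np.float32)

    zprof = _soft_step(np.abs(xs - c), ne_z_halfwidth_nm * 10.0 / voxel_size,
                       edge_vox)
    ne_r = ne_inner_radius_nm * 10.0 / voxel_size
    radial = _soft_step(rxy, ne_r, edge_vox)  # 1 inside pore wall
    ne = radial[:, :, None] + (1.0 - radial[:, :, None]) * zprof[None, None, :]
    ne_lumen = ne.astype(np.float32)
    return {"channel": channel, "ne_lumen": ne_lumen,
            "combined": (channel * ne_lumen).astype(np.float32)}


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

def _lowpass(data: np.ndarray, voxel_size: float, resolution_A: float,
             edge_shells: float = 2.0) -> np.ndarray:
    """Raised-cosine low-pass whose support ends exactly at 1/resolution.

    Per-shell correlation measures are insensitive to amplitude scaling, so
    the band limit a filtered map *reports* is where the filter support
    ends; placing the edge inside the cutoff guarantees the filtered map is
    never finer than the nominal resolution.
    """
    n = data.shape[0]
    k = np.fft.fftfreq(n, d=voxel_size)
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    kr = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
    kc = 1.0 / resolution_A
    width = max(edge_shells / (n * voxel_size), 1e-9)
    t = np.clip((kr - (kc - width)) / width, 0.0, 1.0)
    filt = 0.5 * (1.0 + np.cos(np.pi * t))
    return np.fft.ifftn(np.fft.fftn(data) * filt).real


def assemble_model(subprotomer_averages: dict, spec: ProtomerSpec,
                   npc_box: int, filter_resolution_A: float | None = None,
                   weight_radius_frac: float = 0.45,
                   return_coverage: bool = False):
    """Assemble subprotomer averages into the eightfold-symmetric pore map.

    Each average is placed back at its protomer-frame position with a soft
    spherical weight; overlaps are blended by normalized weights; the
    protomer is then replicated 45° apart about the pore axis (C8 imposed
    by averaging the eight rotations) and optionally low-pass filtered to
    the target resolution.

    The three subprotomer boxes sample the ring moieties, not the whole
    protomer; with ``return_coverage=True`` the C8-replicated blending
    weight is returned alongside the map so callers can restrict
    comparisons to the sampled region.
    """
    voxels = {name: v.voxel_size for name, v in subprotomer_averages.items()}
    vals = list(voxels.values())
    if max(vals) - min(vals) > 1e-6:
        raise ValueError(f"inconsistent voxel sizes: {voxels}")
    voxel_size = vals[0]
    offsets = spec.subprotomer_offsets_vox()
    num = np.zeros((npc_box,) * 3, dtype=np.float64)
    den = np.zeros((npc_box,) * 3, dtype=np.float64)
    c_npc = npc_box // 2
    p_off = spec.protomer_offset_vox()
    sb = spec.subprotomer_box
    w = soft_sphere_mask((sb,) * 3, radius=sb * weight_radius_frac,
                         edge_width=2.0).astype(np.float64)
    for name, vol in subprotomer_averages.items():
        data = vol.data.astype(np.float64)
        center = c_npc + p_off + offsets[name]
        o = np.round(center).astype(int) - sb // 2
        if np.any(o < 0) or np.any(o + sb > npc_box):
            raise BoundaryError([name], "subprotomer does not fit npc box")
        sl = tuple(slice(o[i], o[i] + sb) for i in range(3))
        num[sl] += data * w
        den[sl] += w
    protomer_in_npc = np.where(den > 1e-6, num / np.maximum(den, 1e-6), 0.0)

    out = np.zeros_like(protomer_in_npc)
    cov = np.zeros_like(protomer_in_npc)
    for k in range(spec.n_fold):
        rot = RigidTransform(phi=360.0 * k / spec.n_fold)
        out += apply_transform(protomer_in_npc.astype(np.float32), rot,
                               cval=0.0)
        cov += apply_transform(np.minimum(den, 1.0).astype(np.float32), rot,
                               cval=0.0)
    out /= spec.n_fold
    if filter_resolution_A is not None:
        out = _lowpass(out, voxel_size, filter_resolution_A)
    model = Volume(out.astype(np.float32), voxel_size)
    if return_coverage:
        return model, Volume(np.clip(cov, 0, None).astype(np.float32),
                             voxel_size)
    return model


# ---------------------------------------------------------------------------
# Pore metrics
# ---------------------------------------------------------------------------

def cylinder_volume_nm3(diameter_nm: float, height_nm: float) -> float:
    """Volume of the cylinder the selective phase could occupy: π (d/2)² h."""
    if diameter_nm <= 0 or height_nm <= 0:
        raise ValueError("cylinder dimensions must be positive")
    return float(np.pi * (diameter_nm / 2.0) ** 2 * height_nm)


def ring_radius_nm(volume: Volume, z_halfwidth_nm: float = 10.0,
                   r_range_nm=(20.0, 70.0), n_fold: int = 8) -> float:
    """Radial position of the ring density in an equatorial annulus (nm).

    Measured as the density-weighted centroid radius within each of the
    ``n_fold`` azimuthal sectors, averaged over sectors.  (A plain radial
    histogram peak is biased by the arc-coverage/area factors of an annulus;
    the per-sector centroid of a blob-like ring unit is not.)
    """
    data = volume.data
    n = data.shape
    c = [s // 2 for s in n]
    vox = volume.voxel_size
    zhw = max(int(round(z_halfwidth_nm * 10.0 / vox)), 1)
    slab = np.clip(data[:, :, c[2] - zhw:c[2] + zhw + 1], 0, None).sum(axis=2)
    xs = (np.arange(n[0]) - c[0]) * vox / 10.0
    ys = (np.arange(n[1]) - c[1]) * vox / 10.0
    r = np.sqrt(xs[:, None] ** 2 + ys[None, :] ** 2)
    theta = np.arctan2(ys[None, :], xs[:, None])
    band = (r >= r_range_nm[0]) & (r <= r_range_nm[1])
    radii = []
    for k in range(n_fold):
        th0 = 2.0 * np.pi * k / n_fold
        sector = np.abs(np.angle(np.exp(1j * (theta - th0)))) < np.pi / n_fold
        w = slab * (sector & band)
        total = w.sum()
        if total > 0:
            radii.append(float((w * r).sum() / total))
    if not radii:
        raise ValueError("no density found in the annulus band")
    return float(np.mean(radii))


def measure_pore_metrics(map_volume: Volume | None = None,
                         ccr_height_nm: float = 26.0,
                         pore_diameter_nm: float = 37.0) -> dict:
    """Metrics record: central-channel cylinder volume and, when a map is
    given, the measured template-ring radius with the z-range used."""
    rec = {
        "ccr_height_nm": ccr_height_nm,
        "pore_diameter_nm": pore_diameter_nm,
        "cylinder_volume_nm3": cylinder_volume_nm3(pore_diameter_nm,
                                                   ccr_height_nm),
    }
    if map_volume is not None:
        rec["ring_radius_nm"] = ring_radius_nm(map_volume)
        rec["ring_z_halfwidth_nm"] = 10.0
    return rec
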