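"""Rigid-body docking of a component density into a map region.

Global search: many random starts (uniform random rotation, best
in-region translation by FFT correlation), each refined by local
multi-resolution cross-correlation hill climbing (20° → 12° → 4° angle
steps on binned maps, then 1° → 0.25° at full resolution).  Solutions are ranked by correlation,
de-duplicated greedily, annotated with plausibility flags (body mass
outside density, clashes with an exclusion mask), and scored against radial
restraints — anchor points in the body whose distance from the pore axis is
known independently (super-resolution-style radial positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .transforms import RigidTransform, apply_transform, rotation_angle_deg
from .volume import Volume

__all__ = ["DockingSolution", "RestraintSet", "dock_global", "deduplicate",
           "plausibility_flags", "restraint_distances", "rank_report"]


@dataclass
class DockingSolution:
    """One docking pose: rotation about the body center plus the position
    (voxels, map frame) the body center is placed at."""

    rotation: RigidTransform
    position: np.ndarray
    cc: float
    rank: int = 0
    flags: dict = field(default_factory=dict)

    def copy(self) -> "DockingSolution":
        return DockingSolution(self.rotation, self.position.copy(), self.cc,
                               self.rank, dict(self.flags))


@dataclass
class RestraintSet:
    """label -> (anchor position in the body frame, voxels; radial target, nm)."""

    anchors_vox: dict          # label -> 3-vector (body-frame coordinates)
    radial_targets_nm: dict    # label -> radius from the pore axis

    def __post_init__(self) -> None:
        if set(self.anchors_vox) != set(self.radial_targets_nm):
            raise ValueError("anchor labels and radial targets must match")
        if len(self.anchors_vox) == 0:
            raise ValueError("empty restraint set")
        bad = [k for k, v in self.radial_targets_nm.items() if v <= 0]
        if bad:
            raise ValueError(f"non-positive radial targets: {bad}")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

class _Scorer:
    """Weighted local cross-correlation of a body at integer positions.

    The body's soft support (a smooth ramp of its own density) is rotated
    along with it and used as a continuous weight for the correlation, so
    the score varies smoothly with rotation — a hard support mask would
    pepper the landscape with discretization maxima and stall hill
    climbing.  Mean and norm of both body and map patch are taken under
    the same weights; the score is a proper correlation in [-1, 1].
    """

    def __init__(self, map_volume: Volume, body: Volume,
                 support_threshold: float = 0.05):
        self.map = map_volume.data.astype(np.float64)
        self.body = body.data.astype(np.float64)
        self.nb = self.body.shape[0]
        thr = support_threshold * float(self.body.max())
        self.support0 = np.clip(self.body / max(thr * 4.0, 1e-12), 0.0, 1.0)
        # body center of mass relative to the box center: rotation moves are
        # taken about the COM so they do not drag the mass sideways
        grids = np.meshgrid(*[np.arange(s, dtype=float)
                              for s in self.body.shape], indexing="ij")
        mass = self.body.sum()
        self.com = np.array([(g * self.body).sum() / mass for g in grids]) \
            - np.array([s // 2 for s in self.body.shape], dtype=float)
        self._cache: dict = {}

    def rotated(self, rotation: RigidTransform):
        key = (round(rotation.phi, 4), round(rotation.theta, 4),
               round(rotation.psi, 4))
        if key not in self._cache:
            if len(self._cache) > 512:
                self._cache.clear()
            from scipy.ndimage import affine_transform
            stack = np.stack([self.body, self.support0])
            rinv = rotation.matrix.T
            center = np.array([s // 2 for s in self.body.shape], dtype=float)
            mat4 = np.zeros((4, 4))
            mat4[0, 0] = 1.0
            mat4[1:, 1:] = rinv
            offset = np.concatenate([[0.0], center - rinv @ center])
            rot_stack = affine_transform(stack, mat4, offset=offset, order=1,
                                         mode="constant", cval=0.0,
                                         prefilter=False)
            rb = rot_stack[0]
            w = np.clip(rot_stack[1], 0.0, 1.0)
            wsum = w.sum()
            if wsum < 8:
                self._cache[key] = None
            else:
                bc = rb - (w * rb).sum() / wsum
                norm = np.sqrt((w * bc * bc).sum())
                self._cache[key] = (w * bc, w, norm, wsum)
        return self._cache[key]

    def score(self, rotation: RigidTransform, position) -> float:
        entry = self.rotated(rotation)
        if entry is None:
            return -np.inf
        wbc, w, bnorm, wsum = entry
        o = np.round(np.asarray(position, dtype=float)).astype(int) \
            - self.nb // 2
        if np.any(o < 0) or np.any(o + self.nb > np.array(self.map.shape)):
            return -np.inf
        patch = self.map[o[0]:o[0] + self.nb, o[1]:o[1] + self.nb,
                         o[2]:o[2] + self.nb]
        pmean = (w * patch).sum() / wsum
        pc = patch - pmean
        pnorm = np.sqrt((w * pc * pc).sum())
        if pnorm == 0 or bnorm == 0:
            return 0.0
        return float((wbc * pc).sum() / (bnorm * pnorm))


_ROT_AXES = np.array(
    [[1, 0, 0], [0, 1, 0], [0, 0, 1],
     [1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1], [0, 1, 1], [0, 1, -1]],
    dtype=float)
_ROT_AXES /= np.linalg.norm(_ROT_AXES, axis=1, keepdims=True)


def _bin2(data: np.ndarray) -> np.ndarray:
    """2x block-mean binning (even dimensions assumed)."""
    s = [d - d % 2 for d in data.shape]
    d = data[:s[0], :s[1], :s[2]]
    return d.reshape(s[0] // 2, 2, s[1] // 2, 2, s[2] // 2, 2).mean(
        axis=(1, 3, 5))


def _hill_climb(scorer_fine: _Scorer, rotation: RigidTransform, position,
                scorer_coarse: _Scorer | None = None,
                max_steps: int = 200, cc_tol: float = 1e-4,
                fine_stages_only: bool = False):
    """Multi-resolution coordinate ascent.

    Coarse (binned, smoothed) scoring carries the wide-basin stages
    (12° and 4° angle steps); the original maps carry the 1° and 0.25°
    stages.  One step is a full coordinate sweep; a stage stops when a
    sweep gains less than *cc_tol* or after *max_steps* sweeps in total.
    """
    pos = np.asarray(position, dtype=float)
    sweeps = 0
    stages = [(20.0, 3.0, "c"), (12.0, 2.0, "c"), (4.0, 1.0, "c"),
              (1.0, 1.0, "f"), (0.25, 0.25, "f")]
    if fine_stages_only:
        stages = [(4.0, 1.0, "f"), (1.0, 1.0, "f"), (0.25, 0.25, "f")]
    elif scorer_coarse is None:
        stages = [(s[0], s[1], "f") for s in stages]
    elif scorer_fine is None:
        stages = [s for s in stages if s[2] == "c"]
    best = None
    for ang_step, sh_step, level in stages:
        if level == "c":
            scorer, scale = scorer_coarse, 0.5
        else:
            scorer, scale = scorer_fine, 1.0
        best = scorer.score(rotation, pos * scale)
        improved = True
        while improved and sweeps < max_steps:
            improved = False
            sweeps += 1
            com = scorer_fine.com if scorer_fine is not None \
                else scorer_coarse.com * 2.0
            for axis in _ROT_AXES:
                for sgn in (1.0, -1.0):
                    # rotations about Cartesian plus face-diagonal map axes:
                    # Euler-offset moves would collapse phi and psi onto the
                    # same z rotation, and pure coordinate axes stall on
                    # oblique ridges.  Each move pivots about the body's
                    # center of mass (the compensating translation keeps the
                    # mass in place) so rotation and translation decouple.
                    rv = np.deg2rad(sgn * ang_step) * axis
                    dmat = Rotation.from_rotvec(rv).as_matrix()
                    cand = RigidTransform.from_matrix(dmat @ rotation.matrix)
                    cpos = pos + (np.eye(3) - dmat) @ (rotation.matrix @ com)
                    sc = scorer.score(cand, cpos * scale)
                    if sc > best + cc_tol:
                        rotation, pos, best, improved = cand, cpos, sc, True
            for ax in range(3):
                for sgn in (1.0, -1.0):
                    p = pos.copy()
                    p[ax] += sgn * sh_step
                    sc = scorer.score(rotation, p * scale)
                    if sc > best + cc_tol:
                        pos, best, improved = p, sc, True
    if scorer_fine is None:
        return rotation, pos, best
    return rotation, pos, scorer_fine.score(rotation, pos)


class _TranslationSearch:
    """FFT correlation of a rotated body against the whole map.

    Gives each random start its best in-region translation before local
    refinement — the translational analogue of a very large random-start
    count, which a desk-scale 500-start budget cannot match by position
    sampling alone.
    """

    def __init__(self, map_volume: Volume, body_box: int, region_lo, region_hi):
        self.shape = map_volume.shape
        m = map_volume.data.astype(np.float64)
        self.f_map = np.fft.rfftn(m)
        self.f_map2 = np.fft.rfftn(m * m)
        self.nb = body_box
        n = self.shape[0]
        # valid body-center positions: body inside the map and inside region
        ctr = np.arange(n) - body_box // 2  # origin offset per center coord
        self.valid = np.ones(self.shape, dtype=bool)
        for ax in range(3):
            coord = np.arange(self.shape[ax])
            ok = (coord - body_box // 2 >= 0) \
                & (coord - body_box // 2 + body_box <= self.shape[ax]) \
                & (coord >= region_lo[ax]) & (coord < region_hi[ax])
            sh = [1, 1, 1]
            sh[ax] = -1
            self.valid &= ok.reshape(sh)

    def best_position(self, bms_sup: np.ndarray, sup: np.ndarray,
                      bnorm: float, nsup: float):
        n = self.shape
        emb_b = np.zeros(n)
        emb_s = np.zeros(n)
        nb = self.nb
        emb_b[:nb, :nb, :nb] = bms_sup
        emb_s[:nb, :nb, :nb] = sup
        axes = (0, 1, 2)
        corr_b = np.fft.irfftn(self.f_map * np.conj(np.fft.rfftn(emb_b)),
                               s=n, axes=axes)
        s1 = np.fft.irfftn(self.f_map * np.conj(np.fft.rfftn(emb_s)),
                           s=n, axes=axes)
        s2 = np.fft.irfftn(self.f_map2 * np.conj(np.fft.rfftn(emb_s)),
                           s=n, axes=axes)
        var = np.maximum(s2 - s1 * s1 / nsup, 1e-12)
        cc = corr_b / (np.sqrt(var) * max(bnorm, 1e-12))
        # index o corresponds to the body origin at o; center = o + nb//2
        cc_center = np.roll(cc, nb // 2, axis=(0, 1, 2))
        cc_center[~self.valid] = -np.inf
        idx = np.unravel_index(int(np.argmax(cc_center)), cc_center.shape)
        return np.array(idx, dtype=float), float(cc_center[idx])


def dock_global(map_volume: Volume, body: Volume, search_region,
                n_starts: int = 2000, seed: int = 0,
                max_steps: int = 200, refine_fraction: float = 0.2) -> list:
    """Global docking by random restarts with local CC hill climbing.

    ``search_region`` is ``(lo, hi)`` voxel bounds (inclusive/exclusive) for
    the body center position.  Each start draws a uniform random rotation
    and a uniform position; the position is first replaced by the best
    in-region translation of that rotated body (FFT correlation over the
    whole region), then rotation and position are refined jointly by local
    hill climbing.  Deterministic under a fixed seed; solutions are sorted
    by correlation (ranks before de-duplication).
    """
    lo = np.asarray(search_region[0], dtype=float)
    hi = np.asarray(search_region[1], dtype=float)
    if np.any(hi <= lo):
        raise ValueError(f"empty search region: {search_region}")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter
    scorer = _Scorer(map_volume, body)
    cmap = Volume(gaussian_filter(_bin2(map_volume.data), 1.0).astype(
        np.float32), map_volume.voxel_size * 2)
    cbody = Volume(gaussian_filter(_bin2(body.data), 1.0).astype(np.float32),
                   body.voxel_size * 2)
    scorer_c = _Scorer(cmap, cbody)
    tsearch = _TranslationSearch(cmap, cbody.shape[0], lo / 2, hi / 2)
    # pass 1: coarse translation search + coarse climb for every start
    coarse = []
    for i in range(n_starts):
        quat = rng.normal(size=4)
        rot = Rotation.from_quat(quat / np.linalg.norm(quat))
        rotation = RigidTransform.from_matrix(rot.as_matrix())
        pos = lo + rng.uniform(size=3) * (hi - lo)
        entry = scorer_c.rotated(rotation)
        if entry is not None:
            bms_sup, sup, bnorm, nsup = entry
            cpos, _cc0 = tsearch.best_position(bms_sup, sup, bnorm, nsup)
            pos = cpos * 2.0
        rotation, pos, cc_c = _hill_climb(None, rotation, pos,
                                          scorer_coarse=scorer_c,
                                          max_steps=max_steps)
        coarse.append((cc_c if np.isfinite(cc_c) else -np.inf, rotation, pos))
    # pass 2: full-resolution refinement of the most promising starts
    coarse.sort(key=lambda t: -t[0])
    n_refine = max(10, int(np.ceil(refine_fraction * n_starts)))
    solutions = []
    for j, (cc_c, rotation, pos) in enumerate(coarse):
        if j < n_refine:
            rotation, pos, cc = _hill_climb(scorer, rotation, pos,
                                            max_steps=max_steps,
                                            fine_stages_only=True)
        else:
            cc = scorer.score(rotation, pos)
        if np.isfinite(cc):
            solutions.append(DockingSolution(rotation, pos, cc))
    solutions.sort(key=lambda s: -s.cc)
    for r, s in enumerate(solutions, start=1):
        s.rank = r
    return solutions


def refine_local(map_volume: Volume, body: Volume,
                 solution: DockingSolution, max_steps: int = 200):
    """Hill-climb from a given pose (used for fixed-point and registration
    checks)."""
    scorer = _Scorer(map_volume, body)
    rot, pos, cc = _hill_climb(scorer, solution.rotation, solution.position,
                               max_steps=max_steps)
    return DockingSolution(rot, pos, cc)


# ---------------------------------------------------------------------------
# Redundancy removal and plausibility
# ---------------------------------------------------------------------------

def deduplicate(solutions, rot_tol_deg: float = 5.0,
                trans_tol_vox: float = 2.0) -> list:
    """Greedy removal of redundant poses by descending correlation.

    A solution within both tolerances of an already kept one is flagged
    redundant and dropped; ranks are reassigned afterwards.
    """
    if rot_tol_deg <= 0 or trans_tol_vox <= 0:
        raise ValueError("tolerances must be > 0")
    kept = []
    for s in sorted(solutions, key=lambda s: -s.cc):
        redundant = False
        for k in kept:
            dang = rotation_angle_deg(s.rotation, k.rotation)
            dpos = float(np.linalg.norm(s.position - k.position))
            if dang <= rot_tol_deg and dpos <= trans_tol_vox:
                redundant = True
                break
        if not redundant:
            kept.append(s.copy())
    for r, s in enumerate(kept, start=1):
        s.rank = r
        s.flags["redundant"] = False
    return kept


def plausibility_flags(solution: DockingSolution, map_volume: Volume,
                       body: Volume, density_threshold: float,
                       exclusion_mask: np.ndarray | None = None,
                       outside_cap: float = 0.10,
                       clash_cap: float = 0.05) -> dict:
    """Flag poses protruding outside the density or clashing with a region.

    ``outside_density``: fraction of body mass landing where the map is
    below *density_threshold* exceeds ``outside_cap``.  ``clash``: body-mass
    overlap with the exclusion mask exceeds ``clash_cap``.
    """
    nb = body.shape[0]
    placed = apply_transform(body.data, solution.rotation, cval=0.0)
    o = np.round(solution.position).astype(int) - nb // 2
    full = np.zeros(map_volume.shape, dtype=np.float64)
    sl_m, sl_b = [], []
    for ax in range(3):
        lo = max(o[ax], 0)
        hi = min(o[ax] + nb, map_volume.shape[ax])
        sl_m.append(slice(lo, hi))
        sl_b.append(slice(lo - o[ax], hi - o[ax]))
    full[tuple(sl_m)] = placed[tuple(sl_b)]
    mass = full.sum()
    placed_mass = placed.sum()
    outside_map = 1.0 - (mass / placed_mass if placed_mass > 0 else 0.0)
    low = (map_volume.data < density_threshold)
    frac_outside = float((full * low).sum() / placed_mass) + max(outside_map, 0.0)
    flags = {"outside_density": frac_outside > outside_cap,
             "outside_fraction": frac_outside}
    if exclusion_mask is not None:
        overlap = float((full * (exclusion_mask > 0.5)).sum() / placed_mass)
        flags["clash"] = overlap > clash_cap
        flags["clash_fraction"] = overlap
    else:
        flags["clash"] = False
    return flags


# ---------------------------------------------------------------------------
# Restraints
# ---------------------------------------------------------------------------

def restraint_distances(solution: DockingSolution, restraints: RestraintSet,
                        voxel_size: float, pore_axis_xy_vox=(0.0, 0.0)) -> dict:
    """Radial-restraint deviations of a docked pose.

    Each anchor is transformed by the solution, its distance from the pore
    axis (a line along z through ``pore_axis_xy_vox``) is taken in nm, and
    the absolute deviation from the target radius is reported per label with
    mean, sample s.d. (n−1) and the maximum with its label.  Axial (z)
    components are projected out, matching the radial nature of the
    measurements.
    """
    labels = sorted(restraints.anchors_vox)
    rot = solution.rotation.matrix
    center = None
    per_label = {}
    for lab in labels:
        a = np.asarray(restraints.anchors_vox[lab], dtype=float)
        placed = rot @ a + np.asarray(solution.position, dtype=float) \
            + solution.rotation.shift
        dx = (placed[0] - pore_axis_xy_vox[0]) * voxel_size / 10.0
        dy = (placed[1] - pore_axis_xy_vox[1]) * voxel_size / 10.0
        radial = float(np.hypot(dx, dy))
        per_label[lab] = abs(radial - restraints.radial_targets_nm[lab])
    vals = np.array([per_label[lab] for lab in labels])
    imax = int(np.argmax(vals))
    return {
        "per_label_nm": per_label,
        "mean_nm": float(vals.mean()),
        "sd_nm": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        "max_nm": float(vals[imax]),
        "max_label": labels[imax],
    }


def rank_report(solutions, restraints: RestraintSet | None = None,
                voxel_size: float = 1.0, pore_axis_xy_vox=(0.0, 0.0),
                top_k: int = 8) -> pd.DataFrame:
    """Top-k solution table: cc, flags, restraint statistics.

    Flagged solutions stay in the table (annotated, never dropped).
    """
    if len(solutions) == 0:
        raise ValueError("no solutions to report")
    rows = []
    for s in solutions[:top_k]:
        row = {
            "rank": s.rank, "cc": s.cc,
            "phi": s.rotation.phi, "theta": s.rotation.theta,
            "psi": s.rotation.psi,
            "x": s.position[0], "y": s.position[1], "z": s.position[2],
            "outside_density": bool(s.flags.get("outside_density", False)),
            "clash": bool(s.flags.get("clash", False)),
        }
        if restraints is not None:
            stats = restraint_distances(s, restraints, voxel_size,
                                        pore_axis_xy_vox)
            row.update(restraint_mean_nm=stats["mean_nm"],
                       restraint_sd_nm=stats["sd_nm"],
                       restraint_max_nm=stats["max_nm"],
                       restraint_max_label=stats["max_label"])
        rows.append(row)
    return pd.DataFrame(rows)
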