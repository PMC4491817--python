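"""Configuration-driven orchestration of the full analysis.

Stages: simulate → project/corrupt → CTF estimate & correct → reconstruct
(WBP) → pick → global alignment to the geometric template → orientation
verification against the fitted membrane spheroid → protomer extraction and
refinement (exclusions at window limits, top-view balancing) → subprotomer
refinement under masks → half-set averages and FSC → eightfold model
assembly → local resolution → metrics → report.

Each stage writes into its own subdirectory of the run directory and reads
only earlier stages' outputs; the run log (JSON lines) records particle
counts, exclusion tallies and resolutions.  A fixed config + seed is fully
deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align as al
from . import ctf as ctfmod
from . import geometry as geo
from . import imaging as img
from . import localres as lr
from . import phantom as ph
from .particles import new_particle_table, set_transform, transform_of, \
    write_particles
from .transforms import RigidTransform
from .volume import Volume, read_mrc, write_mrc

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "report",
           "PAPER_PRESET"]

#: the reference acquisition/processing constants, kept as one audited table
PAPER_PRESET = {
    "voxel_size_A": 3.3,
    "final_voxel_size_A": 6.6,
    "npc_box": 512,
    "subprotomer_box": 80,
    "tilt_range_deg": (-60.0, 60.0, 3.0),
    "defocus_um": -6.0,
    "protomer_window_deg": (30.0, 12.0, 30.0),
    "refine_window_deg": (4.0, 4.0, 4.0),
    "subprotomer_window_deg": (2.0, 2.0, 2.0),
    "normal_mismatch_deg": 20.0,
    "channel_mask_diameter_nm": 17.0,
    "localres_grid": 4,
    "localres_subpart": 20,
    "fsc_criteria": ("fsc_0.5", "cross_0.14"),
    "docking_starts": 100000,
    "final_filter_A": 20.0,
}


class ConfigError(ValueError):
    """Invalid pipeline configuration (carries the offending key)."""


@dataclass
class SimulateConfig:
    n_copies: int = 3
    tomo_box: int = 160
    voxel_size: float = ph.BENCH_VOXEL_A
    npc_box: int = 64
    noise_sigma: float = 0.5
    tilt_min: float = -60.0
    tilt_max: float = 60.0
    tilt_step: float = 3.0
    defocus_um: float = -6.0


@dataclass
class AlignConfig:
    global_window: tuple = (22.5, 12.0, 22.5)
    global_step: float = 7.5
    refine_window: tuple = (4.0, 4.0, 4.0)
    refine_step: float = 2.0
    refine_iterations: int = 2
    subprotomer_window: tuple = (2.0, 2.0, 2.0)
    subprotomer_step: float = 1.0
    shift_bound: float = 4.0


@dataclass
class GeometryConfig:
    normal_mismatch_deg: float = 20.0
    view_bin_deg: float = 15.0
    view_cap: int = 50
    channel_mask_diameter_nm: float = 17.0


@dataclass
class LocalResConfig:
    grid_spacing: int = 4
    subpart_size: int = 10
    criterion: str = "fsc_0.5"


@dataclass
class PipelineConfig:
    seed: int = 0
    scale: str = "desk"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    localres: LocalResConfig = field(default_factory=LocalResConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        return _build(cls, raw, path="")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(dc_type, raw: dict, path: str):
    if not isinstance(raw, dict):
        raise ConfigError(f"section {path or '<root>'} must be a mapping")
    known = {f.name: f for f in fields(dc_type)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown configuration key(s) {sorted(unknown)} in "
            f"section {path or '<root>'}")
    kwargs = {}
    for name, f in known.items():
        if name not in raw:
            continue
        default = (f.default_factory()
                   if f.default_factory is not dataclasses.MISSING
                   else f.default)
        if dataclasses.is_dataclass(default):
            kwargs[name] = _build(type(default), raw[name],
                                  f"{path}.{name}" if path else name)
        else:
            value = raw[name]
            if isinstance(value, list):
                value = tuple(value)
            kwargs[name] = value
    return dc_type(**kwargs)


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _log(run_dir: Path, record: dict) -> None:
    with open(run_dir / "run_log.jsonl", "a") as fh:
        fh.write(json.dumps(record, default=str) + "\n")


def _crop(volume: np.ndarray, center, box: int):
    o = np.round(np.asarray(center, dtype=float)).astype(int) - box // 2
    o = np.clip(o, 0, np.array(volume.shape) - box)
    return volume[o[0]:o[0] + box, o[1]:o[1] + box, o[2]:o[2] + box].copy()


def pick_particles(tomogram: Volume, template: Volume, n_expected: int,
                   min_separation: float | None = None) -> np.ndarray:
    """Simple template-matching picker: FFT cross-correlation peaks.

    Correlates the tomogram with the (zero-mean) template and returns the
    ``n_expected`` strongest non-overlapping peak positions (voxels).
    """
    tpl = template.data - template.data.mean()
    n = tomogram.shape
    emb = np.zeros(n, dtype=np.float64)
    tb = tpl.shape[0]
    emb[:tb, :tb, :tb] = tpl
    cc = np.fft.irfftn(np.fft.rfftn(tomogram.data.astype(np.float64))
                       * np.conj(np.fft.rfftn(emb)), s=n)
    cc = np.roll(cc, tb // 2, axis=(0, 1, 2))
    if min_separation is None:
        min_separation = tb / 2
    picks = []
    flat = cc.copy()
    for _ in range(n_expected):
        idx = np.array(np.unravel_index(int(np.argmax(flat)), flat.shape))
        picks.append(idx.astype(float))
        lo = np.maximum(idx - int(min_separation), 0)
        hi = np.minimum(idx + int(min_separation) + 1, np.array(n))
        flat[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = -np.inf
    return np.array(picks)


def _counts(table: pd.DataFrame) -> dict:
    reasons = table.loc[~table["keep"], "reason"].value_counts().to_dict()
    return {"total": int(len(table)), "kept": int(table["keep"].sum()),
            "excluded_by_reason": {k: int(v) for k, v in reasons.items()}}


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute all stages; returns the run directory.

    Every stage writes its artifacts once (write-once run directory) and a
    JSON-lines log accumulates per-stage particle accounting and resolution
    summaries.  Rerunning with the same config and seed reproduces every
    artifact bit for bit.
    """
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg = config
    sim = cfg.simulate
    rng_seed = cfg.seed
    (run_dir / "provenance.json").write_text(
        json.dumps({"config": cfg.to_dict(), "seed": cfg.seed}, indent=2))

    # -- stage 1: simulate ---------------------------------------------------
    stage = run_dir / "01_simulate"
    stage.mkdir(exist_ok=True)
    phantom = ph.PorePhantom(box=sim.npc_box, voxel_size=sim.voxel_size)
    tomo_truth, truth_table, normals = ph.build_phantom(
        n_copies=sim.n_copies, tomo_shape=(sim.tomo_box,) * 3,
        voxel_size=sim.voxel_size, phantom=phantom, seed=rng_seed)
    write_mrc(tomo_truth, stage / "tomogram_truth.mrc")
    write_particles(truth_table, stage / "ground_truth.tsv")
    _log(run_dir, {"stage": "simulate", "n_copies": sim.n_copies,
                   "tomo_box": sim.tomo_box, "voxel_size": sim.voxel_size})

    # -- stage 2: tilt series + corruption ------------------------------------
    stage2 = run_dir / "02_tiltseries"
    stage2.mkdir(exist_ok=True)
    acq = img.AcquisitionSpec(tilt_min=sim.tilt_min, tilt_max=sim.tilt_max,
                              tilt_step=sim.tilt_step,
                              defocus_nominal=sim.defocus_um,
                              pixel_size=sim.voxel_size,
                              dose_noise_sigma=sim.noise_sigma, seed=rng_seed)
    model = ctfmod.CtfModel(defocus_um=sim.defocus_um)
    ts = img.project_tilt_series(tomo_truth, acq)
    ts_corrupt = img.corrupt(ts, acq, model)
    _log(run_dir, {"stage": "tiltseries", "n_projections": len(ts.tilt_angles)})

    # -- stage 3: CTF correction ----------------------------------------------
    try:
        est_defocus, corr = ctfmod.estimate_mean_defocus(ts_corrupt, model)
        defocus_source = "estimated"
    except ctfmod.EstimationFailedError:
        est_defocus, corr = sim.defocus_um, float("nan")
        defocus_source = "nominal_fallback"
    ts_corrected = ts_corrupt.copy()
    for i, ang in enumerate(ts_corrected.tilt_angles):
        dfs = ctfmod.defocus_gradient(ts_corrected.images.shape[1],
                                      ts_corrected.pixel_size, ang,
                                      est_defocus)
        flipped = ctfmod.phase_flip(ts_corrected.images[i], dfs,
                                    ts_corrected.pixel_size, model)
        ts_corrected.images[i] = ctfmod.mtf_correct(
            flipped, ts_corrected.pixel_size, model)
    _log(run_dir, {"stage": "ctf", "defocus_um": est_defocus,
                   "source": defocus_source, "correlation": corr})

    # -- stage 4: reconstruction ----------------------------------------------
    stage4 = run_dir / "04_reconstruct"
    stage4.mkdir(exist_ok=True)
    tomo_rec = img.weighted_backprojection(ts_corrected)
    write_mrc(tomo_rec, stage4 / "tomogram.mrc")
    _log(run_dir, {"stage": "reconstruct", "box": tomo_rec.shape[0]})

    # -- stage 5: pick --------------------------------------------------------
    template = geo.make_geometric_template(sim.npc_box, sim.voxel_size)
    picks = pick_particles(tomo_rec, template, sim.n_copies)
    # match picks to ground truth order for bookkeeping
    table = new_particle_table(len(picks))
    table["score"] = 0.0
    table["at_window_limit"] = False
    truth_pos = truth_table[["x", "y", "z"]].to_numpy()
    order = []
    for p in picks:
        order.append(int(np.argmin(np.linalg.norm(truth_pos - p, axis=1))))
    table[["x", "y", "z"]] = picks
    pick_err = [float(np.linalg.norm(picks[i] - truth_pos[order[i]]))
                for i in range(len(picks))]
    _log(run_dir, {"stage": "pick", "n_picked": len(picks),
                   "match_error_vox": pick_err})

    # -- stage 6: subtomograms ------------------------------------------------
    particles = [Volume(_crop(tomo_rec.data, table.loc[i, ["x", "y", "z"]],
                              sim.npc_box), sim.voxel_size)
                 for i in range(len(table))]
    wedge = al.WedgeMask(sim.tilt_min, sim.tilt_max, (sim.npc_box,) * 3)
    wedges = [wedge] * len(particles)

    # -- stage 7: global alignment against the template -----------------------
    stage7 = run_dir / "07_global"
    stage7.mkdir(exist_ok=True)
    spheroid_pts = _membrane_points(tomo_truth, sim, rng_seed)
    spheroid = geo.fit_spheroid(spheroid_pts)
    center_vox = np.array([s // 2 for s in tomo_truth.shape], dtype=float)
    init = []
    for i in range(len(table)):
        pos_nm = (table.loc[i, ["x", "y", "z"]].to_numpy(dtype=float)
                  - center_vox) * sim.voxel_size / 10.0
        normal = geo.normal_at(spheroid, pos_nm)
        az = np.degrees(np.arctan2(normal[1], normal[0]))
        tilt = np.degrees(np.arccos(np.clip(normal[2], -1, 1)))
        t0 = RigidTransform(az + 90.0, tilt, 0.0).inverse()
        init.append(t0)
    window = al.AngularWindow(*cfg.align.global_window, cfg.align.global_step)
    results = al.align_particles(particles, template, window, wedges=wedges,
                                 current=init,
                                 shift_bound=sim.npc_box / 4)
    for i, (t_new, score, at_limit) in enumerate(results):
        set_transform(table, i, t_new)
        table.loc[i, "score"] = score
        table.loc[i, "at_window_limit"] = at_limit
    # refinement iterations against the running average
    window_r = al.AngularWindow(*cfg.align.refine_window, cfg.align.refine_step)
    for _ in range(cfg.align.refine_iterations):
        current = [transform_of(table.loc[i]) for i in range(len(table))]
        avg = al.average(particles, current, wedges)
        results = al.align_particles(particles, avg, window_r, wedges=wedges,
                                     current=current,
                                     shift_bound=cfg.align.shift_bound)
        for i, (t_new, score, at_limit) in enumerate(results):
            set_transform(table, i, t_new)
            table.loc[i, "score"] = score
            table.loc[i, "at_window_limit"] = at_limit
    global_avg = al.average(
        particles, [transform_of(table.loc[i]) for i in range(len(table))],
        wedges)
    write_mrc(global_avg, stage7 / "global_average.mrc")

    # -- stage 8: orientation verification ------------------------------------
    pick_normals = []
    for i in range(len(table)):
        pos_nm = (table.loc[i, ["x", "y", "z"]].to_numpy(dtype=float)
                  - center_vox) * sim.voxel_size / 10.0
        pick_normals.append(geo.normal_at(spheroid, pos_nm))
    table = geo.verify_orientations(table, pick_normals,
                                    cfg.geometry.normal_mismatch_deg)
    write_particles(table, stage7 / "particles_global.tsv")
    _log(run_dir, {"stage": "global_align", **_counts(table)})

    # -- stage 9: protomers ---------------------------------------------------
    stage9 = run_dir / "09_protomer"
    stage9.mkdir(exist_ok=True)
    pspec = geo.ProtomerSpec(voxel_size=sim.voxel_size)
    # protomer crops of tilted/shifted pores need margin beyond the
    # alignment box; re-crop a padded volume about the same center
    pad_box = min(sim.npc_box + 16, sim.tomo_box)
    padded = [Volume(_crop(tomo_rec.data, table.loc[i, ["x", "y", "z"]],
                           pad_box), sim.voxel_size)
              for i in range(len(table))]
    prot_vols, prot_rows = [], []
    for i in range(len(table)):
        if not table.loc[i, "keep"]:
            continue
        try:
            prots = geo.extract_protomers(padded[i],
                                          transform_of(table.loc[i]), pspec)
        except geo.BoundaryError as exc:
            table.loc[i, "keep"] = False
            table.loc[i, "reason"] = "boundary"
            continue
        for vol, t_p, k in prots:
            prot_vols.append(vol)
            prot_rows.append({"parent": int(table.loc[i, "particle_id"]),
                              "k": k, "transform": t_p})
    prot_table = new_particle_table(len(prot_vols))
    prot_table["score"] = 0.0
    prot_table["at_window_limit"] = False
    prot_wedge = al.WedgeMask(sim.tilt_min, sim.tilt_max,
                              (pspec.protomer_box,) * 3)
    for j, row in enumerate(prot_rows):
        prot_table.loc[j, "tomo_id"] = row["parent"]
        set_transform(prot_table, j, row["transform"])
    window_p = al.AngularWindow(*cfg.align.refine_window, cfg.align.refine_step)
    current = [transform_of(prot_table.loc[j]) for j in range(len(prot_table))]
    avg_p = al.average(prot_vols, current, [prot_wedge] * len(prot_vols))
    results = al.align_particles(prot_vols, avg_p, window_p,
                                 wedges=[prot_wedge] * len(prot_vols),
                                 current=current,
                                 shift_bound=cfg.align.shift_bound)
    for j, (t_new, score, at_limit) in enumerate(results):
        set_transform(prot_table, j, t_new)
        prot_table.loc[j, "score"] = score
        prot_table.loc[j, "at_window_limit"] = at_limit
    prot_table = al.exclude_at_limits(prot_table)
    prot_table = geo.balance_views(prot_table, cfg.geometry.view_bin_deg,
                                   cfg.geometry.view_cap)
    write_particles(prot_table, stage9 / "protomers.tsv")
    _log(run_dir, {"stage": "protomer", **_counts(prot_table)})

    # -- stage 10: subprotomers ----------------------------------------------
    stage10 = run_dir / "10_subprotomer"
    stage10.mkdir(exist_ok=True)
    sub_vols = {name: [] for name in pspec.subprotomer_names}
    sub_trans = {name: [] for name in pspec.subprotomer_names}
    kept = [j for j in range(len(prot_table)) if prot_table.loc[j, "keep"]]
    for j in kept:
        try:
            subs = geo.subdivide_subprotomers(
                prot_vols[j], transform_of(prot_table.loc[j]), pspec)
        except geo.BoundaryError:
            continue
        for name, (vol, t_s) in subs.items():
            sub_vols[name].append(vol)
            sub_trans[name].append(t_s)
    sub_wedge = al.WedgeMask(sim.tilt_min, sim.tilt_max,
                             (pspec.subprotomer_box,) * 3)
    window_s = al.AngularWindow(*cfg.align.subprotomer_window,
                                cfg.align.subprotomer_step)
    masks = geo.make_masks(pspec.subprotomer_box, sim.voxel_size,
                           channel_diameter_nm=
                           cfg.geometry.channel_mask_diameter_nm)
    sub_avgs, halves, resolutions = {}, {}, {}
    for name in pspec.subprotomer_names:
        vols, trans = sub_vols[name], sub_trans[name]
        if len(vols) < 2:
            continue
        wedges_s = [sub_wedge] * len(vols)
        avg0 = al.average(vols, trans, wedges_s)
        results = al.align_particles(vols, avg0, window_s, wedges=wedges_s,
                                     current=trans, shift_bound=2.0,
                                     mask=masks["combined"])
        trans = [r[0] for r in results]
        ids = np.arange(len(vols))
        h1, h2 = al.split_halves(ids)
        a1 = al.average([vols[i] for i in h1], [trans[i] for i in h1],
                        [sub_wedge] * len(h1))
        a2 = al.average([vols[i] for i in h2], [trans[i] for i in h2],
                        [sub_wedge] * len(h2))
        curve = al.fsc(a1, a2, voxel_size=sim.voxel_size)
        res = al.resolution_at(curve, 0.5)
        resolutions[name] = res
        halves[name] = (a1, a2)
        sub_avgs[name] = al.average(vols, trans, [sub_wedge] * len(vols))
        write_mrc(sub_avgs[name], stage10 / f"subprotomer_{name}.mrc")
    _log(run_dir, {"stage": "subprotomer",
                   "n_subprotomers": {k: len(v) for k, v in sub_vols.items()},
                   "fsc_resolution_A": resolutions,
                   "criterion": "fsc_0.5"})

    # -- stage 11: model assembly + local resolution + metrics ----------------
    stage11 = run_dir / "11_model"
    stage11.mkdir(exist_ok=True)
    out = {"resolutions_A": resolutions, "criterion": "fsc_0.5"}
    if len(sub_avgs) == len(pspec.subprotomer_names):
        model_raw = geo.assemble_model(sub_avgs, pspec, sim.npc_box)
        name0 = pspec.subprotomer_names[0]
        lrm = lr.local_resolution(halves[name0][0], halves[name0][1],
                                  grid_spacing=cfg.localres.grid_spacing,
                                  subpart_size=min(cfg.localres.subpart_size,
                                                   pspec.subprotomer_box),
                                  criterion=cfg.localres.criterion)
        write_mrc(lrm.values, stage11 / "local_resolution.mrc")
        out["localres_A"] = {"min": lrm.min(), "median": lrm.median(),
                             "max": lrm.max(), "criterion": lrm.criterion}
        # filter the final map to the finest measured local resolution
        filter_res = max(lrm.min(), 3.0 * sim.voxel_size)
        model = Volume(geo._lowpass(model_raw.data, sim.voxel_size,
                                    filter_res).astype(np.float32),
                       sim.voxel_size)
        out["final_filter_A"] = filter_res
        write_mrc(model, stage11 / "npc_model.mrc")
        metrics = geo.measure_pore_metrics(model)
        out["metrics"] = metrics
    _log(run_dir, {"stage": "model", **{k: v for k, v in out.items()}})
    (run_dir / "summary.json").write_text(json.dumps(out, indent=2,
                                                     default=float))
    return run_dir


def _membrane_points(tomo_truth: Volume, sim: SimulateConfig, seed: int,
                     n_points: int = 60) -> np.ndarray:
    """Sample nuclear-envelope surface points (nm) for the spheroid fit.

    Stands in for manual membrane annotation: points are drawn on the
    simulated spheroid surface with a small jitter.
    """
    mem = ph.MembraneSpec()
    rng = np.random.default_rng(seed + 101)
    # annotations span the envelope well beyond one tomogram: a narrow,
    # nearly flat patch would leave the quadric fit unconstrained
    half_nm = max(400.0,
                  tomo_truth.shape[0] // 2 * sim.voxel_size / 10.0 * 0.8)
    x = rng.uniform(-half_nm, half_nm, n_points)
    y = rng.uniform(-half_nm, half_nm, n_points)
    z = mem.center_nm[2] + ph._spheroid_surface_z(mem, x, y) \
        + rng.normal(0, 1.0, n_points)
    return np.column_stack([x, y, z])


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def report(run_dir) -> dict:
    """Summarize a run: particle accounting, resolutions, metrics.

    Returns the summary dict and writes both machine-readable
    (``report.json``) and human-readable (``report.txt``) renderings whose
    fields agree one for one.  An incomplete run yields a partial report
    with the missing stages marked.
    """
    run_dir = Path(run_dir)
    log_path = run_dir / "run_log.jsonl"
    entries = []
    if log_path.exists():
        with open(log_path) as fh:
            entries = [json.loads(line) for line in fh if line.strip()]
    summary: dict = {"stages": {}, "incomplete": []}
    expected = ["simulate", "tiltseries", "ctf", "reconstruct", "pick",
                "global_align", "protomer", "subprotomer", "model"]
    seen = {e["stage"]: e for e in entries}
    for name in expected:
        if name in seen:
            summary["stages"][name] = {k: v for k, v in seen[name].items()
                                       if k != "stage"}
        else:
            summary["incomplete"].append(name)
    # particle accounting: kept <= picked at every stage
    accounting = []
    for name in ("pick", "global_align", "protomer", "subprotomer"):
        e = seen.get(name)
        if not e:
            continue
        if name == "pick":
            accounting.append({"stage": name, "count": e.get("n_picked")})
        elif "kept" in e:
            accounting.append({"stage": name, "count": e.get("kept"),
                               "excluded": e.get("excluded_by_reason", {})})
        elif "n_subprotomers" in e:
            total = sum(e["n_subprotomers"].values())
            accounting.append({"stage": name, "count": total})
    summary["particle_accounting"] = accounting
    sub = seen.get("subprotomer", {})
    summary["fsc_resolution_A"] = sub.get("fsc_resolution_A", {})
    summary["criterion"] = sub.get("criterion")
    model = seen.get("model", {})
    summary["metrics"] = model.get("metrics", {})
    summary["localres_A"] = model.get("localres_A", {})

    (run_dir / "report.json").write_text(json.dumps(summary, indent=2,
                                                    default=float))
    lines = ["npctomo run report", "=" * 40]
    for item in accounting:
        lines.append(f"{item['stage']:>14}: {item['count']}"
                     + (f"  excluded {item['excluded']}"
                        if item.get("excluded") else ""))
    if summary["fsc_resolution_A"]:
        lines.append(f"FSC resolutions ({summary['criterion']}): "
                     + ", ".join(f"{k}={v:.1f} A"
                                 for k, v in summary["fsc_resolution_A"].items()))
    if summary["metrics"]:
        m = summary["metrics"]
        lines.append(f"cylinder volume: {m.get('cylinder_volume_nm3', 0):.0f} nm^3")
        if "ring_radius_nm" in m:
            lines.append(f"ring radius: {m['ring_radius_nm']:.1f} nm "
                         f"(z half-width {m.get('ring_z_halfwidth_nm')} nm)")
    if summary["incomplete"]:
        lines.append("MISSING stages: " + ", ".join(summary["incomplete"]))
    (run_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return summary
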