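import numpy as np
import pytest

from npctomo.docking import (DockingSolution, RestraintSet, deduplicate,
                             dock_global, plausibility_flags, rank_report,
                             refine_local, restraint_distances)
from npctomo.phantom import DESK_VOXEL_A, make_y_body
from npctomo.transforms import RigidTransform, apply_transform, \
    rotation_angle_deg
from npctomo.volume import Volume

VOX = DESK_VOXEL_A


@pytest.fixture(scope="module")
def planted_problem():
    body = make_y_body(40, VOX)
    rng = np.random.default_rng(50)
    true_rot = RigidTransform(*rng.uniform(-180, 180, 1),
                              *rng.uniform(0, 180, 1),
                              *rng.uniform(-180, 180, 1))
    true_pos = np.round(rng.uniform(26, 38, 3))
    data = np.zeros((64, 64, 64), np.float32)
    placed = apply_transform(body.data, true_rot, cval=0.0)
    o = np.round(true_pos).astype(int) - 20
    data[o[0]:o[0] + 40, o[1]:o[1] + 40, o[2]:o[2] + 40] += placed
    data += 0.05 * rng.normal(size=data.shape).astype(np.float32)
    return Volume(data, VOX), body, true_rot, true_pos


class TestDockGlobal:
    def test_fixed_point_from_truth(self, planted_problem):
        map_vol, body, rot, pos = planted_problem
        sol = refine_local(map_vol, body, DockingSolution(rot, pos, 0.0))
        assert rotation_angle_deg(sol.rotation, rot) <= 1.0
        assert np.linalg.norm(sol.position - pos) <= 0.5
        assert sol.cc >= 0.98

    def test_deterministic_under_seed(self, planted_problem):
        map_vol, body, _, _ = planted_problem
        a = dock_global(map_vol, body, ((24, 24, 24), (40, 40, 40)),
                        n_starts=5, seed=3)
        b = dock_global(map_vol, body, ((24, 24, 24), (40, 40, 40)),
                        n_starts=5, seed=3)
        for sa, sb in zip(a, b):
            assert sa.cc == sb.cc
            np.testing.assert_array_equal(sa.position, sb.position)
            assert rotation_angle_deg(sa.rotation, sb.rotation) == 0.0

    def test_empty_region_rejected(self, planted_problem):
        map_vol, body, _, _ = planted_problem
        with pytest.raises(ValueError):
            dock_global(map_vol, body, ((30, 30, 30), (20, 30, 30)), 1, 0)


class TestDeduplicate:
    def test_exact_copies_collapse(self):
        s = DockingSolution(RigidTransform(10, 20, 30), np.array([5., 5., 5.]),
                            0.9)
        kept = deduplicate([s, s.copy()], 5, 2)
        assert len(kept) == 1 and kept[0].rank == 1

    def test_distant_rotations_kept(self):
        a = DockingSolution(RigidTransform(0, 0, 0), np.zeros(3), 0.9)
        b = DockingSolution(RigidTransform(30, 0, 0), np.zeros(3), 0.8)
        kept = deduplicate([a, b], rot_tol_deg=10, trans_tol_vox=2)
        assert len(kept) == 2
        assert [s.rank for s in kept] == [1, 2]
        assert kept[0].cc >= kept[1].cc

    def test_matches_brute_force_clustering(self):
        rng = np.random.default_rng(4)
        sols = []
        for _ in range(20):
            rot = RigidTransform(rng.uniform(-20, 20), 0, 0)
            pos = rng.uniform(0, 4, 3)
            sols.append(DockingSolution(rot, pos, rng.uniform(0, 1)))
        kept = deduplicate(sols, 5, 2)
        # oracle: every dropped solution is near a kept one with higher cc,
        # and kept solutions are pairwise separated
        for s in sols:
            near = [k for k in kept
                    if rotation_angle_deg(s.rotation, k.rotation) <= 5
                    and np.linalg.norm(s.position - k.position) <= 2
                    and k.cc >= s.cc - 1e-12]
            assert near or any(
                abs(s.cc - k.cc) < 1e-12 for k in kept)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert rotation_angle_deg(a.rotation, b.rotation) > 5 \
                    or np.linalg.norm(a.position - b.position) > 2

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            deduplicate([], rot_tol_deg=0, trans_tol_vox=1)


class TestPlausibility:
    def test_body_inside_density_unflagged(self, planted_problem):
        map_vol, body, rot, pos = planted_problem
        flags = plausibility_flags(DockingSolution(rot, pos, 1.0), map_vol,
                                   body, density_threshold=0.02)
        assert not flags["outside_density"] and not flags["clash"]

    def test_displaced_body_flagged_outside(self, planted_problem):
        map_vol, body, rot, _ = planted_problem
        far = DockingSolution(rot, np.array([50.0, 20.0, 50.0]), 0.0)
        flags = plausibility_flags(far, map_vol, body, density_threshold=0.02)
        assert flags["outside_density"]

    def test_fraction_matches_voxel_count_oracle(self, planted_problem):
        map_vol, body, rot, pos = planted_problem
        sol = DockingSolution(rot, pos + np.array([6.0, 0, 0]), 0.0)
        flags = plausibility_flags(sol, map_vol, body, density_threshold=0.02)
        placed = apply_transform(body.data, rot, cval=0.0)
        full = np.zeros(map_vol.shape)
        o = np.round(sol.position).astype(int) - 20
        full[o[0]:o[0] + 40, o[1]:o[1] + 40, o[2]:o[2] + 40] = placed
        oracle = (full * (map_vol.data < 0.02)).sum() / placed.sum()
        assert flags["outside_fraction"] == pytest.approx(oracle, abs=1e-6)

    def test_clash_mask(self, planted_problem):
        map_vol, body, rot, pos = planted_problem
        exclusion = np.ones(map_vol.shape)
        flags = plausibility_flags(DockingSolution(rot, pos, 1.0), map_vol,
                                   body, 0.02, exclusion_mask=exclusion)
        assert flags["clash"]


class TestRestraints:
    def test_exact_anchors_give_zero(self):
        rng = np.random.default_rng(3)
        rot = RigidTransform(33, 21, -57)
        pos = np.array([40.0, 29.0, 33.0])
        anchors = {f"a{i}": rng.uniform(-8, 8, 3) for i in range(6)}
        targets = {}
        for lab, a in anchors.items():
            p = rot.matrix @ a + pos
            targets[lab] = float(np.hypot((p[0] - 32) * VOX / 10,
                                          (p[1] - 32) * VOX / 10))
        rset = RestraintSet(anchors, targets)
        stats = restraint_distances(DockingSolution(rot, pos, 1.0), rset,
                                    VOX, (32, 32))
        assert stats["mean_nm"] == pytest.approx(0.0, abs=1e-9)
        assert stats["sd_nm"] == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_anchor(self):
        rset = RestraintSet({"x": np.array([10.0, 0, 0])},
                            {"x": 10 * VOX / 10 + 3.0})
        sol = DockingSolution(RigidTransform(), np.array([32.0, 32.0, 32.0]),
                              1.0)
        stats = restraint_distances(sol, rset, VOX, (32, 32))
        assert stats["mean_nm"] == pytest.approx(3.0)
        assert stats["max_nm"] == pytest.approx(3.0)
        assert stats["max_label"] == "x"

    def test_closed_form_statistics_under_perturbation(self):
        # radial displacement of the whole body changes each anchor's radius
        # by a closed-form amount
        anchors = {f"a{i}": np.array([5.0 * np.cos(w), 5.0 * np.sin(w), i])
                   for i, w in enumerate(np.linspace(0, 2 * np.pi, 6,
                                                     endpoint=False))}
        pos0 = np.array([32.0, 32.0, 32.0])
        targets = {}
        for lab, a in anchors.items():
            p = a + pos0
            targets[lab] = float(np.hypot((p[0] - 32) * VOX / 10,
                                          (p[1] - 32) * VOX / 10))
        rset = RestraintSet(anchors, targets)
        shift = np.array([3.0, 0.0, 0.0])
        sol = DockingSolution(RigidTransform(), pos0 + shift, 1.0)
        stats = restraint_distances(sol, rset, VOX, (32, 32))
        expected = []
        for lab, a in anchors.items():
            p = a + pos0 + shift
            r = np.hypot((p[0] - 32) * VOX / 10, (p[1] - 32) * VOX / 10)
            expected.append(abs(r - targets[lab]))
        assert stats["mean_nm"] == pytest.approx(np.mean(expected))
        assert stats["sd_nm"] == pytest.approx(np.std(expected, ddof=1))
        assert stats["max_nm"] == pytest.approx(np.max(expected))

    def test_invariant_under_scene_rotation(self):
        rng = np.random.default_rng(8)
        anchors = {f"a{i}": rng.uniform(-6, 6, 3) for i in range(5)}
        targets = {lab: float(rng.uniform(10, 40)) for lab in anchors}
        rset = RestraintSet(anchors, targets)
        rot = RigidTransform(17, 9, -40)
        pos = np.array([36.0, 30.0, 32.0])
        base = restraint_distances(DockingSolution(rot, pos, 1), rset, VOX,
                                   (32, 32))
        spin = RigidTransform(phi=73.0)
        rot2 = spin.compose(rot)
        rel = pos - np.array([32, 32, 32.0])
        pos2 = np.array([32, 32, 32.0]) + spin.matrix @ rel
        out = restraint_distances(DockingSolution(rot2, pos2, 1), rset, VOX,
                                  (32, 32))
        assert out["mean_nm"] == pytest.approx(base["mean_nm"], abs=1e-9)
        assert out["sd_nm"] == pytest.approx(base["sd_nm"], abs=1e-9)

    def test_empty_restraints_rejected(self):
        with pytest.raises(ValueError):
            RestraintSet({}, {})


class TestRankReport:
    def _solutions(self, n=8):
        rng = np.random.default_rng(5)
        sols = []
        for i in range(n):
            s = DockingSolution(RigidTransform(*rng.uniform(-90, 90, 3)),
                                rng.uniform(20, 44, 3), 1.0 - 0.05 * i,
                                rank=i + 1)
            if i == 2:
                s.flags["outside_density"] = True
            sols.append(s)
        return sols

    def test_top_k_table(self):
        tbl = rank_report(self._solutions(), top_k=8)
        assert len(tbl) == 8
        assert tbl.loc[0, "rank"] == 1
        assert tbl["cc"].iloc[0] == tbl["cc"].max()

    def test_flagged_solutions_annotated_not_dropped(self):
        tbl = rank_report(self._solutions(), top_k=8)
        assert tbl["outside_density"].sum() == 1
        assert len(tbl) == 8

    def test_restraint_discrimination_two_sites(self):
        # constructed two-pose scenario: the restraint-consistent pose shows
        # a small mean deviation, the decoy a large one (the 4.5 vs 9.5 nm
        # style of discrimination)
        anchors = {f"a{i}": np.array([6.0 * np.cos(w), 6.0 * np.sin(w), 0.0])
                   for i, w in enumerate(np.linspace(0, np.pi, 4))}
        pos_true = np.array([42.0, 32.0, 32.0])
        targets = {}
        for lab, a in anchors.items():
            p = a + pos_true
            targets[lab] = float(np.hypot((p[0] - 32) * VOX / 10,
                                          (p[1] - 32) * VOX / 10))
        rset = RestraintSet(anchors, targets)
        good = DockingSolution(RigidTransform(), pos_true, 0.95, rank=1)
        decoy = DockingSolution(RigidTransform(),
                                pos_true + np.array([6.0, 0, 0]), 0.90,
                                rank=2)
        tbl = rank_report([good, decoy], rset, VOX, (32, 32))
        assert tbl.loc[0, "restraint_mean_nm"] < tbl.loc[1, "restraint_mean_nm"]
        assert tbl.loc[0, "restraint_mean_nm"] < 1.0

    def test_no_solutions_rejected(self):
        with pytest.raises(ValueError):
            rank_report([])
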