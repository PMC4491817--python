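import numpy as np
import pandas as pd
import pytest

from npctomo.align import normalized_cc
from npctomo.geometry import (BoundaryError, FitError, ProtomerSpec,
                              assemble_model, balance_views,
                              cylinder_volume_nm3, extract_protomers,
                              fit_spheroid, make_geometric_template,
                              make_masks, measure_pore_metrics, normal_at,
                              protomer_consistency, ring_radius_nm,
                              subdivide_subprotomers, verify_orientation,
                              verify_orientations)
from npctomo.particles import new_particle_table, set_transform
from npctomo.phantom import (BENCH_VOXEL_A, DESK_VOXEL_A, PorePhantom,
                             make_npc_density)
from npctomo.transforms import RigidTransform, apply_transform
from npctomo.volume import Volume, soft_sphere_mask


@pytest.fixture(scope="module")
def desk_phantom():
    return make_npc_density(PorePhantom(box=128, voxel_size=DESK_VOXEL_A))


@pytest.fixture(scope="module")
def desk_spec():
    return ProtomerSpec(voxel_size=DESK_VOXEL_A)


class TestGeometricTemplate:
    def test_c8_by_construction(self):
        tpl = make_geometric_template(64, BENCH_VOXEL_A)
        rot = apply_transform(tpl.data, RigidTransform(phi=45), cval=0.0)
        assert normalized_cc(rot, tpl.data) >= 0.999

    def test_sphere_centers_on_45nm_circle(self):
        tpl = make_geometric_template(64, BENCH_VOXEL_A)
        assert ring_radius_nm(tpl) == pytest.approx(
            45.0, abs=BENCH_VOXEL_A / 10.0 / 2)

    def test_adjacent_sphere_spacing_chord(self):
        # chord length between neighbouring sphere centers:
        # 90 sin(22.5 deg) ≈ 34.4 nm, measured from sector centroids
        tpl = make_geometric_template(112, DESK_VOXEL_A)
        data, c = tpl.data, 56
        x, y = np.meshgrid(*(np.arange(112, dtype=float) - c,) * 2,
                           indexing="ij")
        theta = np.arctan2(y, x)
        centers = []
        core = data >= 0.95 * data.max()  # sphere plateaus, no neighbour leak
        for k in range(8):
            d = np.angle(np.exp(1j * (theta - 2 * np.pi * k / 8)))
            w = (data * core) * (np.abs(d) < np.pi / 8)[:, :, None]
            cx = (w * x[:, :, None]).sum() / w.sum()
            cy = (w * y[:, :, None]).sum() / w.sum()
            centers.append((cx, cy))
        spacing = np.linalg.norm(np.array(centers[0]) - np.array(centers[1]))
        assert spacing * DESK_VOXEL_A / 10 == pytest.approx(
            90 * np.sin(np.pi / 8), abs=1.0)

    def test_geometry_exceeding_box_rejected(self):
        with pytest.raises(ValueError):
            make_geometric_template(32, BENCH_VOXEL_A)


class TestSpheroidFit:
    def test_sphere_special_case(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(200, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        m = fit_spheroid(pts * 123.0)
        assert m.a == pytest.approx(123.0, rel=0.01)
        assert m.c == pytest.approx(123.0, rel=0.01)

    def test_oblate_pole_normal(self):
        rng = np.random.default_rng(1)
        th = rng.uniform(0, np.pi, 300)
        ph = rng.uniform(0, 2 * np.pi, 300)
        pts = np.stack([200 * np.sin(th) * np.cos(ph),
                        200 * np.sin(th) * np.sin(ph),
                        100 * np.cos(th)], axis=1)
        m = fit_spheroid(pts)
        assert m.a == pytest.approx(200, rel=0.01)
        assert m.c == pytest.approx(100, rel=0.01)
        n = normal_at(m, (0, 0, 100.0))
        angle = np.degrees(np.arccos(abs(n[2])))
        assert angle < 0.5

    def test_coplanar_points_rejected(self):
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.normal(size=(8, 2)), np.zeros(8)])
        with pytest.raises(FitError):
            fit_spheroid(pts)


class TestVerifyOrientation:
    @pytest.mark.parametrize("theta, expect_keep", [
        (0.0, True), (25.0, False), (20.0, True), (19.9, True), (20.1, False),
    ])
    def test_threshold(self, theta, expect_keep):
        keep, mis = verify_orientation(RigidTransform(0, theta, 0), (0, 0, 1))
        assert keep == expect_keep
        assert mis == pytest.approx(theta, abs=1e-6)

    def test_zero_normal_rejected(self):
        with pytest.raises(ValueError):
            verify_orientation(RigidTransform(), (0, 0, 0))

    def test_table_exclusion_reasons(self):
        table = new_particle_table(3)
        set_transform(table, 1, RigidTransform(0, 30, 0))
        out = verify_orientations(table, [(0, 0, 1)] * 3)
        assert list(out["keep"]) == [True, False, True]
        assert out.loc[1, "reason"] == "normal_mismatch"


class TestProtomerHierarchy:
    def test_eight_protomers_pairwise_consistent(self, desk_phantom,
                                                 desk_spec):
        prots = extract_protomers(desk_phantom, RigidTransform(), desk_spec)
        assert len(prots) == 8
        assert protomer_consistency(prots).min() >= 0.99

    def test_wedge_bookkeeping_by_45_degrees(self, desk_phantom, desk_spec):
        prots = extract_protomers(desk_phantom, RigidTransform(), desk_spec)
        r0 = prots[0][1].matrix
        for _, t_k, k in prots:
            rel = t_k.matrix @ r0.T
            expected = RigidTransform(phi=-45.0 * k).matrix
            np.testing.assert_allclose(rel, expected, atol=1e-9)

    def test_boundary_error_lists_k(self, desk_spec):
        small = Volume(np.zeros((64, 64, 64), np.float32), DESK_VOXEL_A)
        with pytest.raises(BoundaryError) as err:
            extract_protomers(small, RigidTransform(), desk_spec)
        assert len(err.value.indices) > 0

    def test_subprotomer_recentered_transform_consistency(self, desk_phantom,
                                                          desk_spec):
        prots = extract_protomers(desk_phantom, RigidTransform(), desk_spec)
        vol, t_p, _ = prots[0]
        subs = subdivide_subprotomers(vol, t_p, desk_spec)
        assert set(subs) == {"cpr", "npr", "sr_ccr"}
        al_prot = apply_transform(vol.data, t_p)
        sb = desk_spec.subprotomer_box
        mask = soft_sphere_mask((sb,) * 3, radius=sb / 2 - 1, edge_width=2) \
            > 0.5
        for name, (crop, t_s) in subs.items():
            al_sub = apply_transform(crop.data, t_s)
            off = desk_spec.subprotomer_offsets_vox()[name]
            o = np.round(desk_spec.protomer_box // 2 + off).astype(int) \
                - sb // 2
            region = al_prot[o[0]:o[0] + sb, o[1]:o[1] + sb, o[2]:o[2] + sb]
            a = al_sub[mask] - al_sub[mask].mean()
            b = region[mask] - region[mask].mean()
            cc = (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())
            assert cc >= 0.98

    def test_subprotomer_box_is_80_at_paper_scale(self):
        spec = ProtomerSpec(voxel_size=3.3)
        assert spec.subprotomer_box == 80


class TestBalanceViews:
    def _table(self, thetas, scores):
        table = new_particle_table(len(thetas))
        for i, th in enumerate(thetas):
            set_transform(table, i, RigidTransform(0, th, 0))
        table["score"] = scores
        return table

    def test_below_cap_unchanged(self):
        table = self._table([0, 5, 40, 80], [1, 2, 3, 4])
        out = balance_views(table, cap=10)
        assert out["keep"].all()

    def test_top_views_capped_with_reason(self):
        table = self._table([0.0] * 30, np.arange(30.0))
        out = balance_views(table, cap=10)
        assert out["keep"].sum() == 10
        assert (out.loc[~out["keep"], "reason"] == "view_balance").all()

    def test_kept_subset_has_maximal_scores(self):
        scores = np.random.default_rng(0).permutation(30).astype(float)
        table = self._table([0.0] * 30, scores)
        out = balance_views(table, cap=10)
        kept = set(out.loc[out["keep"], "score"])
        assert kept == set(sorted(scores)[-10:])


class TestMasks:
    def test_values_in_unit_interval(self):
        masks = make_masks(48, BENCH_VOXEL_A)
        for m in masks.values():
            assert m.min() >= 0.0 and m.max() <= 1.0

    def test_central_cylinder_excluded(self):
        masks = make_masks(48, BENCH_VOXEL_A)
        c = 24
        chan_r_vox = 17.0 * 10 / 2 / BENCH_VOXEL_A
        inner = int(chan_r_vox - 2.5)
        assert np.all(masks["channel"][c - inner:c + inner,
                                       c - inner:c + inner, :][
            np.sqrt(np.add.outer(np.arange(-inner, inner) ** 2,
                                 np.arange(-inner, inner) ** 2))
            < inner] == 0.0)

    def test_masked_cc_ignores_excluded_region(self):
        masks = make_masks(48, BENCH_VOXEL_A)
        rng = np.random.default_rng(1)
        a = rng.normal(size=(48,) * 3).astype(np.float32)
        b = a.copy()
        excluded = masks["channel"] < 1e-6
        b[excluded] += 5 * rng.normal(size=int(excluded.sum()))
        assert normalized_cc(a * masks["channel"], b * masks["channel"]) == \
            pytest.approx(1.0, abs=1e-6)


class TestAssembleModel:
    def _crops(self, phantom, spec):
        sb = spec.subprotomer_box
        c_npc = phantom.shape[0] // 2
        out = {}
        for name, off in spec.subprotomer_offsets_vox().items():
            center = np.round(c_npc + spec.protomer_offset_vox()
                              + off).astype(int)
            o = center - sb // 2
            out[name] = Volume(phantom.data[o[0]:o[0] + sb, o[1]:o[1] + sb,
                                            o[2]:o[2] + sb],
                               phantom.voxel_size)
        return out

    def test_round_trip_reproduces_phantom(self, desk_phantom, desk_spec):
        crops = self._crops(desk_phantom, desk_spec)
        model, cov = assemble_model(crops, desk_spec, 128,
                                    return_coverage=True)
        sel = cov.data >= 0.5
        a = model.data[sel] - model.data[sel].mean()
        b = desk_phantom.data[sel] - desk_phantom.data[sel].mean()
        assert (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()) >= 0.98

    def test_c8_imposed(self, desk_phantom, desk_spec):
        crops = self._crops(desk_phantom, desk_spec)
        model = assemble_model(crops, desk_spec, 128,
                               filter_resolution_A=3 * DESK_VOXEL_A)
        rot = apply_transform(model.data, RigidTransform(phi=45), cval=0.0)
        assert normalized_cc(rot, model.data) >= 0.999

    def test_final_filter_limits_resolution(self, desk_phantom, desk_spec):
        from npctomo.align import fsc, resolution_at
        crops = self._crops(desk_phantom, desk_spec)
        sharp = assemble_model(crops, desk_spec, 128, filter_resolution_A=None)
        filt = assemble_model(crops, desk_spec, 128,
                              filter_resolution_A=60.0)
        res = resolution_at(fsc(filt, sharp, voxel_size=DESK_VOXEL_A), 0.5)
        assert res >= 60.0 * 0.95

    def test_voxel_size_mismatch_rejected(self, desk_phantom, desk_spec):
        crops = self._crops(desk_phantom, desk_spec)
        name = next(iter(crops))
        crops[name] = Volume(crops[name].data, 99.0)
        with pytest.raises(ValueError):
            assemble_model(crops, desk_spec, 128)


class TestPoreMetrics:
    def test_reported_cylinder_volume(self):
        # height 26 nm, diameter 37 nm: pi (37/2)^2 * 26 = 27,956 nm^3
        assert cylinder_volume_nm3(37, 26) == pytest.approx(27956, abs=1)

    def test_unit_cylinder(self):
        assert cylinder_volume_nm3(2, 1) == pytest.approx(np.pi)

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            cylinder_volume_nm3(-1, 5)

    def test_metrics_record(self, desk_phantom):
        rec = measure_pore_metrics(desk_phantom)
        assert rec["cylinder_volume_nm3"] == pytest.approx(27956, abs=1)
        assert rec["ring_radius_nm"] == pytest.approx(45.0, abs=1.5)
        assert "ring_z_halfwidth_nm" in rec
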