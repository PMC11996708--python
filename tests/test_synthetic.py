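"""Synthetic wrist generator: shapes, pose model, effects, cohort accounting."""

import numpy as np
import pytest

from wristkin import geometry as g
from wristkin import synthetic as syn
from wristkin.kinematics import decompose_rotation


class TestBoneMesh:
    def test_sphere_like_volume(self):
        tpl = syn.BoneTemplate("capitate", (5.02, 5.01, 5.0), (2.0, 2.0),
                               np.zeros(3), np.eye(3), "distal_row")
        mesh = syn.make_bone_mesh(tpl, subdivision=4)
        exact = 4.0 / 3.0 * np.pi * 5.0 * 5.01 * 5.02
        assert g.mesh_volume(mesh) == pytest.approx(exact, rel=0.02)

    def test_centred_at_volumetric_centroid(self, templates):
        mesh = syn.make_bone_mesh(templates["scaphoid"], subdivision=3)
        assert np.abs(g.volumetric_centroid(mesh)).max() < 1e-9

    def test_ellipsoid_axes_align_with_coordinates(self):
        tpl = syn.BoneTemplate("lunate", (3.0, 2.0, 1.0), (2.0, 2.0),
                               np.zeros(3), np.eye(3), "proximal_row")
        mesh = syn.make_bone_mesh(tpl, subdivision=3)
        axes = g.principal_axes(g.inertia_tensor(mesh), reference=np.eye(3))
        # longest semi-axis (local x) carries the smallest moment -> row 0
        assert axes == pytest.approx(np.eye(3), abs=1e-6)

    def test_invalid_templates_rejected(self):
        with pytest.raises(syn.InvalidTemplateError):
            syn.BoneTemplate("lunate", (3.0, -2.0, 1.0), (2.0, 2.0),
                             np.zeros(3), np.eye(3), "proximal_row")
        with pytest.raises(syn.InvalidTemplateError):
            syn.BoneTemplate("lunate", (3.0, 3.0, 1.0), (2.0, 2.0),
                             np.zeros(3), np.eye(3), "proximal_row")

    def test_subdivision_floor(self, templates):
        with pytest.raises(ValueError):
            syn.make_bone_mesh(templates["lunate"], subdivision=1)


class TestPoseModel:
    def test_neutral_is_identity(self, templates):
        draw = syn.draw_specimen(syn.RowModel(), syn.default_effects(),
                                 np.random.default_rng(0))
        t = syn.pose_model("neutral", "transected", syn.default_effects(),
                           draw, templates["scaphoid"])
        assert t.rotation == pytest.approx(np.eye(3))
        assert t.translation == pytest.approx(np.zeros(3))

    def test_zero_effects_conditions_match(self, templates):
        """With no increments the transected transform equals the intact one
        for the same scan amplitude."""
        effects = syn.zero_effects()
        draw = syn.SpecimenDraw({("flexion", "intact"): 55.0,
                                 ("flexion", "transected"): 55.0}, {})
        for bone in syn.BONES:
            ti = syn.pose_model("flexion", "intact", effects, draw, templates[bone])
            tt = syn.pose_model("flexion", "transected", effects, draw,
                                templates[bone])
            assert ti.as_matrix() == pytest.approx(tt.as_matrix(), abs=1e-12)

    def test_proximal_row_share(self, templates):
        draw = syn.SpecimenDraw({("flexion", "intact"): 60.0}, {})
        t = syn.pose_model("flexion", "intact", syn.zero_effects(), draw,
                           templates["lunate"], syn.RowModel(proximal_row_share=0.5))
        rx, rz, ry = decompose_rotation(t.rotation)
        assert rx == pytest.approx(30.0, abs=1e-9)
        assert (rz, ry) == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_unknown_pose_rejected(self, templates):
        draw = syn.SpecimenDraw({}, {})
        with pytest.raises(ValueError):
            syn.pose_model("dorsiflexion", "intact", syn.zero_effects(), draw,
                           templates["lunate"])

    def test_neutral_increment_rejected(self):
        with pytest.raises(ValueError):
            syn.EffectConfig((syn.EffectIncrement(
                "scaphoid", "neutral", "x", "rotation", 1.0),))


class TestSpecimen:
    def test_noise_free_vertices_match_ground_truth(self, noise_free_specimen,
                                                    templates):
        sp = noise_free_specimen
        neutral = sp.meshes[("neutral", "intact")]
        for (pose, condition) in (("flexion", "transected"),
                                  ("ulnar_deviation", "intact")):
            for bone in ("scaphoid", "mc5", "radius"):
                t = sp.ground_truth.transform(bone, pose, condition)
                expected = t.apply(neutral[bone].vertices.view(np.ndarray))
                got = sp.meshes[(pose, condition)][bone].vertices.view(np.ndarray)
                assert np.abs(got - expected).max() < 1e-9

    def test_same_seed_is_byte_identical(self):
        a = syn.generate_specimen("S1", seed=5, subdivision=2)
        b = syn.generate_specimen("S1", seed=5, subdivision=2)
        for key in a.meshes:
            for bone in a.meshes[key]:
                assert np.array_equal(a.meshes[key][bone].vertices,
                                      b.meshes[key][bone].vertices)

    def test_vertex_noise_rms_matches_chi_expectation(self, templates):
        """Isotropic Gaussian sd 0.05 mm gives per-vertex RMS 0.05·sqrt(3)."""
        sd = 0.05
        effects = syn.zero_effects(vertex_noise_sd=sd)
        clean = syn.generate_specimen("S1", effects=syn.zero_effects(), seed=2,
                                      subdivision=5)
        noisy = syn.generate_specimen("S1", effects=effects, seed=2,
                                      subdivision=5)
        a = clean.meshes[("neutral", "intact")]["radius"].vertices
        b = noisy.meshes[("neutral", "intact")]["radius"].vertices
        assert len(a) >= 10_000
        rms = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert 0.04 * np.sqrt(3) <= rms <= 0.06 * np.sqrt(3)

    def test_duplicate_bone_ids_rejected(self, templates):
        bad = dict(templates)
        bad["scaphoid_copy"] = templates["scaphoid"]  # same bone_id inside
        with pytest.raises(ValueError, match="duplicate"):
            syn.generate_specimen("S1", templates=bad, seed=0, subdivision=2)


class TestVoxelize:
    def test_sphere_voxel_volume(self):
        import trimesh

        sphere = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
        vol = syn.voxelize({"capitate": sphere}, spacing_mm=0.5)
        inside = vol.data > 300
        assert inside.sum() * 0.5 ** 3 == pytest.approx(
            4.0 / 3.0 * np.pi * 125.0, rel=0.03)

    def test_empty_mesh_list_is_background(self):
        vol = syn.voxelize({}, spacing_mm=1.0, background_hu=-50.0)
        assert (vol.data == -50.0).all()

    def test_two_level_image_segments_exactly(self):
        import trimesh

        from wristkin.segmentation import threshold_segment

        sphere = trimesh.creation.icosphere(subdivisions=3, radius=4.0)
        vol = syn.voxelize({"lunate": sphere}, spacing_mm=0.8, bone_hu=700.0,
                           background_hu=-50.0, noise_sd_hu=0.0)
        labels = threshold_segment(vol, hu_min=300.0)
        assert set(np.unique(labels.labels)) == {0, 1}
        assert ((labels.labels > 0) == (vol.data > 300.0)).all()

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            syn.voxelize({}, spacing_mm=-1.0)
        with pytest.raises(ValueError):
            syn.voxelize({}, bone_hu=-100.0, background_hu=0.0)


class TestCohort:
    def test_scan_accounting_default_study(self):
        manifest, _ = syn.generate_cohort(21, materialize=False, seed=0)
        assert len(manifest.scan_entries("transected")) == 105
        assert len(manifest.scan_entries()) == 210
        assert manifest.poses[0] == "neutral" and len(manifest.poses) == 5

    def test_single_specimen_accounting(self):
        manifest, _ = syn.generate_cohort(1, materialize=False, seed=0)
        assert len(manifest.scan_entries("transected")) == 5

    def test_manifest_determinism(self):
        a, _ = syn.generate_cohort(3, materialize=False, seed=9)
        b, _ = syn.generate_cohort(3, materialize=False, seed=9)
        assert a.entries == b.entries and a.specimens == b.specimens

    def test_output_collision_rejected(self, tmp_path):
        (tmp_path / "taken").mkdir()
        (tmp_path / "taken" / "x").write_text("")
        with pytest.raises(FileExistsError):
            syn.generate_cohort(1, out_dir=tmp_path / "taken", subdivision=2)

    def test_mean_difference_converges_to_increment(self):
        """Law of large numbers: at n=200 the cohort-level transected−intact
        difference sits within 3 standard errors of the injected 12 deg."""
        effects = syn.EffectConfig(
            (syn.EffectIncrement("scaphoid", "flexion", "x", "rotation", 12.0),),
            between_specimen_sd_rot=4.0)
        df = syn.simulate_motion_records(200, effects=effects, seed=77)
        sel = df[(df.bone == "scaphoid") & (df.pose == "flexion")]
        intact = sel[sel.condition == "intact"]["rot_x_deg"].to_numpy()
        trans = sel[sel.condition == "transected"]["rot_x_deg"].to_numpy()
        diff = trans.mean() - intact.mean()
        se = np.sqrt(trans.var(ddof=1) / len(trans) + intact.var(ddof=1) / len(intact))
        assert abs(diff - 12.0) < 3.0 * se
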