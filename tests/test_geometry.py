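"""Divergence-theorem mass properties, principal axes and plane cropping."""

import numpy as np
import pytest
import trimesh

from wristkin import geometry as g
from wristkin.synthetic import superellipsoid_radius

from conftest import random_rotation


class TestMassProperties:
    def test_unit_cube_closed_forms(self, unit_cube):
        assert g.mesh_volume(unit_cube) == pytest.approx(1.0, abs=1e-12)
        assert g.volumetric_centroid(unit_cube) == pytest.approx([0.5] * 3, abs=1e-12)
        inertia = g.inertia_tensor(unit_cube)
        assert inertia == pytest.approx(np.eye(3) / 6.0, abs=1e-12)

    def test_translation_invariance(self, unit_cube):
        moved = unit_cube.copy()
        moved.apply_translation([17.0, -4.0, 9.0])
        assert g.mesh_volume(moved) == pytest.approx(g.mesh_volume(unit_cube),
                                                     rel=1e-9)

    def test_icosphere_volume_below_analytic(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
        vol = g.mesh_volume(sphere)
        exact = 4.0 / 3.0 * np.pi * 125.0
        assert vol < exact  # inscribed polyhedron
        assert vol == pytest.approx(exact, rel=5e-3)

    def test_l_prism_centroid_is_composite_average(self):
        box_a = trimesh.creation.box(extents=(2.0, 1.0, 1.0))
        box_a.apply_translation([1.0, 0.5, 0.5])
        box_b = trimesh.creation.box(extents=(1.0, 2.0, 1.0))
        box_b.apply_translation([0.5, 2.0, 0.5])
        l_mesh = trimesh.util.concatenate([box_a, box_b])
        # disjoint-union solid: mass-weighted average of the box centroids
        expected = (2.0 * np.array([1.0, 0.5, 0.5])
                    + 2.0 * np.array([0.5, 2.0, 0.5])) / 4.0
        assert g.volumetric_centroid(l_mesh) == pytest.approx(expected, abs=1e-9)

    def test_centroid_rotation_equivariance(self, unit_cube):
        rot = random_rotation(np.random.default_rng(11))
        rotated = unit_cube.copy()
        rotated.vertices = unit_cube.vertices @ rot.T
        assert g.volumetric_centroid(rotated) == pytest.approx(
            rot @ g.volumetric_centroid(unit_cube), abs=1e-9)

    def test_ellipsoid_inertia_matches_closed_form(self):
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        mesh.apply_scale([3.0, 2.0, 1.0])
        inertia = g.inertia_tensor(mesh)
        mass = g.mesh_volume(mesh)
        expected = mass / 5.0 * np.diag([4.0 + 1.0, 9.0 + 1.0, 9.0 + 4.0])
        assert np.abs(np.diag(inertia) / np.diag(expected) - 1).max() < 0.01
        # independent route: trimesh's own mass properties
        assert inertia == pytest.approx(mesh.moment_inertia, rel=1e-6)

    def test_parallel_axis_theorem_identity(self, unit_cube):
        point = np.array([2.0, -1.0, 3.0])
        mass = g.mesh_volume(unit_cube)
        d = g.volumetric_centroid(unit_cube) - point
        shift = mass * (np.dot(d, d) * np.eye(3) - np.outer(d, d))
        assert g.inertia_tensor(unit_cube, about=point) == pytest.approx(
            g.inertia_tensor(unit_cube) + shift, abs=1e-9)

    def test_non_closed_mesh_rejected(self, unit_cube):
        broken = trimesh.Trimesh(unit_cube.vertices,
                                 unit_cube.faces[:-1], process=False)
        with pytest.raises(g.NonClosedMeshError):
            g.mesh_volume(broken)

    def test_rigid_equivariance_random_transforms(self):
        """Volume invariant, centroid equivariant, inertia conjugated."""
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        mesh.apply_scale([3.0, 2.0, 1.0])
        vol = g.mesh_volume(mesh)
        cen = g.volumetric_centroid(mesh)
        inertia = g.inertia_tensor(mesh)
        rng = np.random.default_rng(7)
        for _ in range(100):
            rot = random_rotation(rng)
            t = rng.uniform(-10, 10, 3)
            moved = mesh.copy()
            moved.vertices = mesh.vertices @ rot.T + t
            assert g.mesh_volume(moved) == pytest.approx(vol, rel=1e-9)
            assert g.volumetric_centroid(moved) == pytest.approx(
                rot @ cen + t, abs=1e-8)
            assert g.inertia_tensor(moved) == pytest.approx(
                rot @ inertia @ rot.T, rel=1e-7, abs=1e-8)

    def test_monte_carlo_oracle_superellipsoid(self):
        """Divergence-theorem volume vs implicit-function Monte Carlo."""
        rng = np.random.default_rng(42)
        semi = rng.uniform(3.0, 8.0, 3)
        semi = tuple(np.sort(semi)[::-1] + np.array([0.2, 0.1, 0.0]))
        exps = tuple(rng.uniform(1.6, 2.4, 2))
        base = trimesh.creation.icosphere(subdivisions=5, radius=1.0)
        u = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)
        r = superellipsoid_radius(u, semi, exps)
        mesh = g.as_mesh(u * r[:, None], base.faces)
        vol = g.mesh_volume(mesh)
        n = 200_000
        pts = rng.uniform(-1.0, 1.0, (n, 3)) * semi
        inside = superellipsoid_radius(
            pts / np.linalg.norm(pts, axis=1, keepdims=True), semi, exps) \
            >= np.linalg.norm(pts, axis=1)
        box = 8.0 * semi[0] * semi[1] * semi[2]
        p = inside.mean()
        mc = p * box
        se = box * np.sqrt(p * (1 - p) / n)
        assert abs(vol - mc) < 3.0 * se


class TestPrincipalAxes:
    def test_diagonal_inertia_gives_identity(self):
        assert g.principal_axes(np.diag([1.0, 2.0, 3.0]),
                                reference=np.eye(3)) == pytest.approx(np.eye(3))

    def test_reference_sign_rule_and_handedness(self):
        ref = np.diag([-1.0, 1.0, 1.0])
        axes = g.principal_axes(np.diag([1.0, 2.0, 3.0]), reference=ref)
        assert axes[0] == pytest.approx([-1.0, 0.0, 0.0])
        assert np.linalg.det(axes) == pytest.approx(1.0)

    def test_degenerate_inertia_rejected(self):
        with pytest.raises(g.DegenerateInertiaError):
            g.principal_axes(np.eye(3))

    def test_equivariance_under_known_rotation(self):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        mesh.apply_scale([3.0, 2.0, 1.0])
        axes0 = g.principal_axes(g.inertia_tensor(mesh), reference=np.eye(3))
        rot = random_rotation(np.random.default_rng(5))
        rotated = mesh.copy()
        rotated.vertices = mesh.vertices @ rot.T
        expected = axes0 @ rot.T
        axes1 = g.principal_axes(g.inertia_tensor(rotated), reference=expected)
        angles = np.degrees(np.arccos(np.clip(
            np.einsum("ij,ij->i", axes1, expected), -1, 1)))
        assert angles.max() < 0.1

    def test_idempotent_in_own_principal_frame(self):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        mesh.apply_scale([3.0, 2.0, 1.0])
        rot = random_rotation(np.random.default_rng(19))
        mesh.vertices = mesh.vertices @ rot.T
        axes = g.principal_axes(g.inertia_tensor(mesh))
        realigned = mesh.copy()
        realigned.vertices = mesh.vertices @ axes.T
        axes2 = g.principal_axes(g.inertia_tensor(realigned), reference=np.eye(3))
        assert axes2 == pytest.approx(np.eye(3), abs=1e-6)


class TestCropByPlane:
    def test_cube_midplane_half_volume(self, unit_cube):
        half = g.crop_by_plane(unit_cube, [0.5, 0.5, 0.5], [0.0, 0.0, 1.0])
        assert g.mesh_volume(half) == pytest.approx(0.5, abs=1e-9)
        assert half.is_watertight

    def test_plane_missing_mesh_returns_input(self, unit_cube):
        out = g.crop_by_plane(unit_cube, [0.0, 0.0, 5.0], [0.0, 0.0, 1.0])
        assert out is unit_cube

    def test_entirely_discarded_raises(self, unit_cube):
        with pytest.raises(ValueError):
            g.crop_by_plane(unit_cube, [0.0, 0.0, -1.0], [0.0, 0.0, 1.0])

    def test_sphere_cap_complement_volume(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
        cut = g.crop_by_plane(sphere, [0.0, 0.0, 2.0], [0.0, 0.0, 1.0])
        h = 3.0
        cap = np.pi * h * h * (3 * 5.0 - h) / 3.0
        expected = 4.0 / 3.0 * np.pi * 125.0 - cap
        assert g.mesh_volume(cut) == pytest.approx(expected, rel=0.01)


class TestContainment:
    def test_points_in_sphere(self):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
        pts = np.array([[0, 0, 0], [0, 0, 4.8], [0, 0, 5.2], [6, 6, 6]], float)
        assert list(g.points_in_mesh(sphere, pts)) == [True, True, False, False]

    def test_rasterized_sphere_volume(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
        spacing = 0.5
        mask = g.rasterize_mesh(sphere, np.full(3, -6.0), spacing, (24, 24, 24))
        vol = mask.sum() * spacing ** 3
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 125.0, rel=0.03)
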