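"""Per-bone rigid transforms across wrist poses and their anatomical
decomposition.

Each pose's radius is registered to the neutral reference radius (the
forearm is the fixed body), every bone's pose object frame is mapped through
that alignment, and the frame-to-frame transform relative to neutral is
expressed in the referential coordinate system.  Rotations are factored
intrinsically as X → Z → Y, matching the anatomical reading: flexion(+)/
extension(−) about X, ulnar(+)/radial(−) deviation about Z, pronation(+)/
supination(−) about Y.  Translations report the motion of the bone's
volumetric centre along the referential axes (radial+, proximal+, dorsal+).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from . import geometry
from .frames import Landmarks, build_object_frame, build_referential_frame
from .transforms import Frame, RigidTransform, orthonormalize

MOTION_COLUMNS = ["specimen", "bone", "pose", "condition",
                  "rot_x_deg", "rot_z_deg", "rot_y_deg",
                  "trans_x_mm", "trans_y_mm", "trans_z_mm"]


class RegistrationError(RuntimeError):
    pass


def decompose_rotation(rotation: np.ndarray) -> tuple[float, float, float]:
    """Intrinsic X·Z·Y Euler factorization, degrees.

    Returns ``(rot_x, rot_z, rot_y)`` for ``R = Rx(rot_x) Rz(rot_z) Ry(rot_y)``
    with rot_x, rot_y in (−180, 180] and rot_z in [−90, 90].  Near gimbal
    lock (|cos rot_z| ≈ 0) the Y angle is set to zero and the residual is
    absorbed into the X angle.
    """
    r = np.asarray(rotation, dtype=float)
    if r.shape != (3, 3) or not np.allclose(r.T @ r, np.eye(3), atol=1e-6) \
            or np.linalg.det(r) < 0:
        raise ValueError("input is not a rotation matrix")
    sin_g = -r[0, 1]
    gamma = np.arcsin(np.clip(sin_g, -1.0, 1.0))
    if abs(np.cos(gamma)) < 1e-8:
        beta = 0.0
        alpha = np.arctan2(-r[1, 2], r[2, 2])
    else:
        alpha = np.arctan2(r[2, 1], r[1, 1])
        beta = np.arctan2(r[0, 2], r[0, 0])
    return (float(np.degrees(alpha)), float(np.degrees(gamma)),
            float(np.degrees(beta)))


def compose_rotation(rot_x_deg: float, rot_z_deg: float, rot_y_deg: float) -> np.ndarray:
    """Inverse of :func:`decompose_rotation`."""
    from .transforms import rot_x, rot_y, rot_z

    return rot_x(rot_x_deg) @ rot_z(rot_z_deg) @ rot_y(rot_y_deg)


def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid motion mapping paired source points onto target."""
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    h = (source - sc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, tc - rot @ sc)


def register_radius(moving: trimesh.Trimesh, reference: trimesh.Trimesh,
                    max_iterations: int = 200, tol: float = 1e-6,
                    fail_rms: float = 0.5) -> RigidTransform:
    """Rigid transform mapping ``moving`` into ``reference`` coordinates.

    Initialization aligns volumetric centres and sign-consistent principal
    axes; refinement is nearest-neighbour iterative closest point with a
    Kabsch update per sweep, stopped when the RMS distance changes by less
    than ``tol`` mm.
    """
    geometry.require_closed(moving)
    geometry.require_closed(reference)
    ref_centroid = geometry.volumetric_centroid(reference)
    ref_axes = geometry.principal_axes(
        geometry.inertia_tensor(reference, about=ref_centroid))
    mov_centroid = geometry.volumetric_centroid(moving)
    mov_axes = geometry.principal_axes(
        geometry.inertia_tensor(moving, about=mov_centroid), reference=ref_axes)
    rot0 = orthonormalize(ref_axes.T @ mov_axes)
    transform = RigidTransform(rot0, ref_centroid - rot0 @ mov_centroid)
    tree = cKDTree(reference.vertices.view(np.ndarray))
    mov = moving.vertices.view(np.ndarray)
    last_rms = np.inf
    for _ in range(max_iterations):
        moved = transform.apply(mov)
        dist, idx = tree.query(moved)
        rms = float(np.sqrt(np.mean(dist ** 2)))
        if abs(last_rms - rms) < tol:
            return transform
        last_rms = rms
        transform = _kabsch(mov, reference.vertices.view(np.ndarray)[idx])
    if last_rms > fail_rms:
        raise RegistrationError(
            f"radius registration did not converge: RMS {last_rms:.3f} mm "
            f"after {max_iterations} iterations")
    return transform


def transform_frame(frame: Frame, transform: RigidTransform) -> Frame:
    """Map a frame through a rigid motion."""
    return Frame(transform.apply(frame.origin),
                 frame.axes @ transform.rotation.T)


def bone_transform(bone_neutral_frame: Frame, bone_pose_frame: Frame,
                   radius_alignment: RigidTransform,
                   referential: Frame) -> RigidTransform:
    """Rigid motion taking the bone's neutral frame to its (radius-aligned)
    pose frame, expressed in referential coordinates."""
    aligned = transform_frame(bone_pose_frame, radius_alignment)
    rot_world = orthonormalize(aligned.axes.T @ bone_neutral_frame.axes)
    t_world = aligned.origin - rot_world @ bone_neutral_frame.origin
    return referential.express_transform(RigidTransform(rot_world, t_world))


def surface_rms(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh) -> float:
    """Symmetric nearest-vertex RMS distance — the cross-check that a
    recovered transform really superimposes the scanned surfaces."""
    ta = cKDTree(mesh_a.vertices.view(np.ndarray))
    tb = cKDTree(mesh_b.vertices.view(np.ndarray))
    da, _ = tb.query(mesh_a.vertices.view(np.ndarray))
    db, _ = ta.query(mesh_b.vertices.view(np.ndarray))
    return float(np.sqrt(np.mean(np.concatenate([da, db]) ** 2)))


@dataclass
class SpecimenScans:
    """One specimen's input to the kinematics stage.

    ``meshes`` maps (pose, condition) to {bone: mesh}; ``landmarks`` maps
    (pose, condition) to a landmark dict or :class:`Landmarks`.
    """

    specimen_id: str
    meshes: dict
    landmarks: dict
    handedness: str = "right"


def _as_landmarks(obj) -> Landmarks:
    if isinstance(obj, Landmarks):
        return obj
    return Landmarks.from_dict({k: np.asarray(v, dtype=float)
                                for k, v in obj.items()})


def run_kinematics(specimens, poses: list[str] | None = None,
                   crop_distance: float = 60.0) -> "pandas.DataFrame":
    """Motion records for every (specimen, bone, pose≠neutral, condition).

    Each condition uses its own neutral scan as the reference; specimens
    whose neutral scan is missing are skipped with a warning.
    """
    import pandas as pd

    rows = []
    for spec in specimens:
        scans = spec.meshes
        conditions = sorted({c for (_, c) in scans})
        pose_list = poses or sorted({p for (p, _) in scans})
        for condition in conditions:
            if ("neutral", condition) not in scans:
                warnings.warn(f"{spec.specimen_id}: missing neutral scan for "
                              f"{condition}; specimen skipped", stacklevel=2)
                continue
            neutral_bones = scans[("neutral", condition)]
            landmarks = _as_landmarks(spec.landmarks[("neutral", condition)])
            referential = build_referential_frame(
                neutral_bones["radius"], landmarks, crop_distance)
            neutral_frames = {
                bone: build_object_frame(mesh, referential.axes)
                for bone, mesh in neutral_bones.items()}
            for pose in pose_list:
                if pose == "neutral" or (pose, condition) not in scans:
                    continue
                pose_bones = scans[(pose, condition)]
                alignment = register_radius(pose_bones["radius"],
                                            neutral_bones["radius"])
                for bone, mesh in pose_bones.items():
                    pose_frame = build_object_frame(
                        mesh, neutral_frames[bone].axes)
                    t = bone_transform(neutral_frames[bone], pose_frame,
                                       alignment, referential)
                    rx, rz, ry = decompose_rotation(t.rotation)
                    aligned_origin = alignment.apply(pose_frame.origin)
                    trans = referential.axes @ (aligned_origin
                                                - neutral_frames[bone].origin)
                    rows.append({"specimen": spec.specimen_id, "bone": bone,
                                 "pose": pose, "condition": condition,
                                 "rot_x_deg": rx, "rot_z_deg": rz,
                                 "rot_y_deg": ry,
                                 "trans_x_mm": trans[0],
                                 "trans_y_mm": trans[1],
                                 "trans_z_mm": trans[2]})
    return pd.DataFrame(rows, columns=MOTION_COLUMNS)
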