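"""Radius-based referential frame and per-bone inertia-axis object frames.

The referential wrist frame is anchored on the distal radius: its origin is
the midpoint between the palmar and dorsal edges of the ulnar notch, the
Y-axis runs proximally along the longitudinal inertia axis of the radius
(cropped to a fixed distance proximal to the radial styloid), the Z-axis is
the dorsal normal of the plane spanned by the Y-axis and the cropped
radius' volumetric centre, and X = Y × Z points radially (right hand).

Object frames use each bone's volumetric centre as origin and its solid
inertia axes, sign-aligned against a reference triad so they keep pointing
the same way across poses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from . import geometry
from .transforms import Frame

DEFAULT_CROP_DISTANCE_MM = 60.0


@dataclass(frozen=True)
class Landmarks:
    """Interactively placed radius landmarks (world mm)."""

    ulnar_notch_palmar: np.ndarray
    ulnar_notch_dorsal: np.ndarray
    radial_styloid_tip: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ulnar_notch_palmar", "ulnar_notch_dorsal", "radial_styloid_tip"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float).reshape(3))
        if np.allclose(self.ulnar_notch_palmar, self.ulnar_notch_dorsal):
            raise ValueError("palmar and dorsal notch edges coincide")
        for name in ("ulnar_notch_palmar", "ulnar_notch_dorsal"):
            if np.allclose(self.radial_styloid_tip, getattr(self, name)):
                raise ValueError("styloid tip coincides with a notch edge")

    @classmethod
    def from_dict(cls, d: dict) -> "Landmarks":
        return cls(np.asarray(d["ulnar_notch_palmar"], dtype=float),
                   np.asarray(d["ulnar_notch_dorsal"], dtype=float),
                   np.asarray(d["radial_styloid_tip"], dtype=float))

    def to_dict(self) -> dict:
        return {"ulnar_notch_palmar": self.ulnar_notch_palmar.tolist(),
                "ulnar_notch_dorsal": self.ulnar_notch_dorsal.tolist(),
                "radial_styloid_tip": self.radial_styloid_tip.tolist()}


def ulnar_notch_midpoint(landmarks: Landmarks) -> np.ndarray:
    """Arithmetic midpoint of the palmar and dorsal notch edges."""
    return 0.5 * (landmarks.ulnar_notch_palmar + landmarks.ulnar_notch_dorsal)


def _longitudinal_axis(mesh: trimesh.Trimesh) -> tuple[np.ndarray, np.ndarray]:
    """(unit longitudinal inertia axis, volumetric centroid) of a mesh."""
    centroid = geometry.volumetric_centroid(mesh)
    inertia = geometry.inertia_tensor(mesh, about=centroid)
    axes = geometry.principal_axes(inertia)
    return axes[0], centroid


def crop_radius(radius_mesh: trimesh.Trimesh, landmarks: Landmarks,
                crop_distance: float = DEFAULT_CROP_DISTANCE_MM) -> trimesh.Trimesh:
    """Distal radius segment up to ``crop_distance`` proximal to the styloid.

    Two-pass: the longitudinal inertia axis of the *uncropped* radius places
    the cut plane; downstream frame building re-derives the axis from the
    cropped mesh.
    """
    axis, centroid = _longitudinal_axis(radius_mesh)
    styloid = landmarks.radial_styloid_tip
    if np.dot(centroid - styloid, axis) < 0:
        axis = -axis  # orient proximally: away from the styloid
    proj = (radius_mesh.vertices.view(np.ndarray) - styloid) @ axis
    length = float(proj.max() - min(proj.min(), 0.0))
    if proj.max() < crop_distance - 1e-6:
        raise ValueError(
            f"radius too short to crop: {length:.1f} mm along the longitudinal "
            f"axis, need at least {crop_distance:g} mm proximal to the styloid")
    plane_point = styloid + crop_distance * axis
    return geometry.crop_by_plane(radius_mesh, plane_point, axis)


def build_referential_frame(radius_mesh: trimesh.Trimesh, landmarks: Landmarks,
                            crop_distance: float = DEFAULT_CROP_DISTANCE_MM) -> Frame:
    """Referential frame from the (neutral) radius and its landmarks."""
    cropped = crop_radius(radius_mesh, landmarks, crop_distance)
    y_axis, centroid = _longitudinal_axis(cropped)
    if np.dot(centroid - landmarks.radial_styloid_tip, y_axis) < 0:
        y_axis = -y_axis  # proximal: from the styloid toward the volumetric centre
    origin = ulnar_notch_midpoint(landmarks)
    in_plane = centroid - origin
    normal = np.cross(y_axis, in_plane)
    if np.linalg.norm(normal) < 1e-9 * max(np.linalg.norm(in_plane), 1.0):
        raise ValueError("degenerate referential plane: volumetric centre is "
                         "collinear with the origin and the longitudinal axis")
    z_axis = normal / np.linalg.norm(normal)
    dorsal = landmarks.ulnar_notch_dorsal - landmarks.ulnar_notch_palmar
    if np.dot(z_axis, dorsal) < 0:
        z_axis = -z_axis
    x_axis = np.cross(y_axis, z_axis)
    return Frame(origin, np.vstack([x_axis, y_axis, z_axis]))


def build_object_frame(bone_mesh: trimesh.Trimesh,
                       reference_axes: Frame | np.ndarray) -> Frame:
    """Volumetric-centre origin plus sign-consistent solid inertia axes."""
    centroid = geometry.volumetric_centroid(bone_mesh)
    inertia = geometry.inertia_tensor(bone_mesh, about=centroid)
    axes = geometry.principal_axes(inertia, reference=reference_axes)
    return Frame(centroid, axes)


def estimate_styloid(radius_mesh: trimesh.Trimesh,
                     radial_hint: np.ndarray | None = None) -> np.ndarray:
    """Approximate styloid-tip guess: the extreme vertex along the distal
    longitudinal direction, biased toward the radial side when a hint
    direction is given.  A fallback for data without landmark files; real
    analyses should supply measured landmarks."""
    axis, centroid = _longitudinal_axis(radius_mesh)
    verts = radius_mesh.vertices.view(np.ndarray)
    proj = (verts - centroid) @ axis
    distal = axis if abs(proj.max()) >= abs(proj.min()) else -axis
    score = (verts - centroid) @ distal
    if radial_hint is not None:
        hint = np.asarray(radial_hint, dtype=float)
        hint = hint / np.linalg.norm(hint)
        score = score + 0.25 * ((verts - centroid) @ hint)
    return verts[int(np.argmax(score))]
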