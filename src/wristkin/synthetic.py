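"""Synthetic wrist cohort generator with known ground-truth kinematics.

Stands in for cadaver CT data: 15 bones (radius, ulna, eight carpals, five
metacarpals) are modelled as superellipsoids laid out in a right-handed
referential frame (X radial, Y proximal, Z dorsal, origin at the ulnar-notch
midpoint of the distal radius).  Wrist poses follow a carpal-row kinematic
model: forearm bones stay fixed (the ulna gets a small fixed offset), the
proximal carpal row receives a configurable share of the global pose angle
and the distal row plus metacarpals the full angle.  Ligament-transection
effects are injected as per-bone rotation/translation increments composed
after the intact pose transform, with per-specimen variability.

Every generated mesh carries an exact ground-truth rigid transform, so the
full reconstruction pipeline can be validated end to end.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from . import geometry
from .transforms import Frame, RigidTransform, axis_rotation, rot_x, rot_y, rot_z

BONES = [
    "radius", "ulna",
    "scaphoid", "lunate", "triquetrum", "pisiform",
    "trapezium", "trapezoid", "capitate", "hamate",
    "mc1", "mc2", "mc3", "mc4", "mc5",
]

ROWS = {
    "radius": "forearm", "ulna": "forearm",
    "scaphoid": "proximal_row", "lunate": "proximal_row",
    "triquetrum": "proximal_row", "pisiform": "proximal_row",
    "trapezium": "distal_row", "trapezoid": "distal_row",
    "capitate": "distal_row", "hamate": "distal_row",
    "mc1": "metacarpal", "mc2": "metacarpal", "mc3": "metacarpal",
    "mc4": "metacarpal", "mc5": "metacarpal",
}

POSES = ["neutral", "flexion", "extension", "ulnar_deviation", "radial_deviation"]
CONDITIONS = ["intact", "transected"]

#: rotation axis and sign of each non-neutral pose in the referential frame
#: (flexion positive about X, ulnar deviation positive about Z)
POSE_AXIS = {
    "flexion": ("x", +1.0),
    "extension": ("x", -1.0),
    "ulnar_deviation": ("z", +1.0),
    "radial_deviation": ("z", -1.0),
}

AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

#: referential-frame landmark coordinates of the synthetic radius (mm)
LANDMARK_POINTS = {
    "ulnar_notch_palmar": np.array([3.0, 2.0, -7.0]),
    "ulnar_notch_dorsal": np.array([3.0, 2.0, 7.0]),
    "radial_styloid_tip": np.array([14.0, -2.0, 0.0]),
}


class InvalidTemplateError(ValueError):
    pass


@dataclass(frozen=True)
class BoneTemplate:
    """Superellipsoid stand-in for one bone.

    ``semi_axes`` are the local half-extents (mm) in descending order so the
    longitudinal axis is local x; ``exponents`` are the two superellipsoid
    shape exponents (2, 2 gives an ellipsoid).  ``neutral_orientation`` maps
    local to referential axes, ``neutral_position`` is the centroid position
    at neutral.
    """

    bone_id: str
    semi_axes: tuple[float, float, float]
    exponents: tuple[float, float]
    neutral_position: np.ndarray
    neutral_orientation: np.ndarray
    row: str

    def __post_init__(self) -> None:
        sa = np.asarray(self.semi_axes, dtype=float)
        if (sa <= 0).any():
            raise InvalidTemplateError(f"{self.bone_id}: semi-axes must be positive")
        if len({round(float(s), 9) for s in sa}) != 3:
            raise InvalidTemplateError(
                f"{self.bone_id}: semi-axes must be pairwise distinct "
                "(degenerate inertia otherwise)")
        if np.asarray(self.exponents, dtype=float).min() <= 0:
            raise InvalidTemplateError(f"{self.bone_id}: exponents must be positive")
        object.__setattr__(self, "semi_axes", tuple(float(s) for s in sa))
        object.__setattr__(self, "neutral_position",
                           np.asarray(self.neutral_position, dtype=float).reshape(3))
        rot = np.asarray(self.neutral_orientation, dtype=float)
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-9) or np.linalg.det(rot) < 0:
            raise InvalidTemplateError(f"{self.bone_id}: orientation must be a rotation")
        object.__setattr__(self, "neutral_orientation", rot)


def _tilt(ax: float, ay: float, az: float) -> np.ndarray:
    return rot_z(az) @ rot_y(ay) @ rot_x(ax)


_ALONG_Y = rot_z(90.0)          # forearm long axis exactly proximal
_MC_TILT = rot_z(72.0)          # metacarpal long axis 18 deg off proximal


def default_templates() -> dict[str, BoneTemplate]:
    """The 15-bone synthetic wrist (right hand, referential coordinates)."""
    params = {
        # bone: (semi_axes, exponents, position, orientation)
        "radius": ((70.0, 11.0, 9.0), (2.0, 2.2), (14.0, 68.0, 0.0), _ALONG_Y),
        "ulna": ((65.0, 8.0, 7.0), (2.0, 2.2), (-16.0, 66.0, 0.0), _ALONG_Y),
        "scaphoid": ((9.0, 6.5, 5.0), (1.8, 2.2), (28.0, -14.0, 0.0), _tilt(7, 9, 12)),
        "lunate": ((8.0, 6.0, 4.5), (1.9, 2.1), (8.0, -14.0, 0.0), _tilt(-6, 8, -10)),
        "triquetrum": ((7.5, 5.5, 4.2), (1.8, 2.3), (-8.0, -14.0, 0.0), _tilt(9, -7, 11)),
        "pisiform": ((6.0, 4.8, 3.8), (2.0, 2.2), (-22.0, -14.0, -8.0), _tilt(-8, 6, 9)),
        "trapezium": ((8.0, 6.0, 4.6), (1.9, 2.2), (28.0, -34.0, 0.0), _tilt(10, 8, -9)),
        "trapezoid": ((7.0, 5.4, 4.1), (1.8, 2.1), (12.0, -34.0, 0.0), _tilt(-7, -9, 12)),
        "capitate": ((8.0, 7.0, 5.5), (1.9, 2.3), (-4.0, -34.0, 0.0), _tilt(8, 10, 7)),
        "hamate": ((7.5, 6.2, 4.9), (1.8, 2.2), (-20.0, -34.0, 0.0), _tilt(-9, 7, -11)),
        "mc1": ((25.0, 7.0, 5.6), (1.9, 2.3), (34.0, -76.0, 0.0), _MC_TILT),
        "mc2": ((32.0, 6.5, 5.2), (2.0, 2.2), (16.0, -76.0, 0.0), _MC_TILT),
        "mc3": ((31.0, 6.0, 4.8), (1.9, 2.2), (0.0, -76.0, 0.0), _MC_TILT),
        "mc4": ((28.0, 5.5, 4.4), (1.8, 2.3), (-15.0, -76.0, 0.0), _MC_TILT),
        "mc5": ((26.0, 5.3, 4.2), (1.9, 2.1), (-28.0, -76.0, 0.0), _MC_TILT),
    }
    return {
        bone: BoneTemplate(bone, sa, ex, np.array(pos), orient, ROWS[bone])
        for bone, (sa, ex, pos, orient) in params.items()
    }


def superellipsoid_radius(directions: np.ndarray, semi_axes, exponents) -> np.ndarray:
    """Radial distance of the superellipsoid surface along unit directions.

    Implicit form ``((|x/a|^p + |y/b|^p)^(q/p) + |z/c|^q) = 1`` is
    homogeneous of degree one in the radial coordinate, so the surface
    radius has the closed form ``1 / f(u)``.
    """
    a, b, c = semi_axes
    p, q = exponents
    u = np.abs(np.asarray(directions, dtype=float))
    s = (np.power(u[:, 0] / a, p) + np.power(u[:, 1] / b, p)) ** (1.0 / p)
    f = (np.power(s, q) + np.power(u[:, 2] / c, q)) ** (1.0 / q)
    return 1.0 / f


def make_bone_mesh(template: BoneTemplate, subdivision: int = 3,
                   seed: int = 0) -> trimesh.Trimesh:
    """Closed superellipsoid mesh in local coordinates, centred at its
    volumetric centroid.  ``seed`` is accepted for interface symmetry with
    the stochastic generator stages; the mesh itself is deterministic.
    """
    if subdivision < 2:
        raise ValueError("subdivision must be >= 2")
    base = trimesh.creation.icosphere(subdivisions=subdivision, radius=1.0)
    u = base.vertices.view(np.ndarray)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    r = superellipsoid_radius(u, template.semi_axes, template.exponents)
    mesh = geometry.as_mesh(u * r[:, None], base.faces)
    mesh.vertices -= geometry.volumetric_centroid(mesh)
    geometry.require_closed(mesh)
    return mesh


def neutral_mesh(template: BoneTemplate, subdivision: int = 3) -> trimesh.Trimesh:
    """Bone mesh posed at neutral in referential coordinates."""
    local = make_bone_mesh(template, subdivision)
    verts = local.vertices.view(np.ndarray) @ template.neutral_orientation.T
    return geometry.as_mesh(verts + template.neutral_position, local.faces)


# --------------------------------------------------------------------------
# effect configuration


@dataclass(frozen=True)
class EffectIncrement:
    bone_id: str
    pose: str
    axis: str            # referential axis: x, y or z
    channel: str         # "rotation" (deg) or "translation" (mm)
    value: float


@dataclass
class EffectConfig:
    """Condition-specific increments added in the transected condition."""

    increments: tuple[EffectIncrement, ...] = ()
    between_specimen_sd_rot: float = 4.0     # deg, per configured rotation effect
    between_specimen_sd_trans: float = 1.5   # mm, per configured translation effect
    vertex_noise_sd: float = 0.05            # mm, i.i.d. on mesh vertices

    def __post_init__(self) -> None:
        for inc in self.increments:
            if inc.pose == "neutral":
                raise ValueError("condition increments at neutral must be zero")
            if inc.pose not in POSE_AXIS:
                raise ValueError(f"unknown pose {inc.pose!r}")
            if inc.bone_id not in BONES:
                raise ValueError(f"unknown bone {inc.bone_id!r}")
            if inc.axis not in AXIS_INDEX or inc.channel not in ("rotation", "translation"):
                raise ValueError("bad increment axis/channel")
        if self.between_specimen_sd_rot < 0 or self.between_specimen_sd_trans < 0 \
                or self.vertex_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    def for_bone_pose(self, bone_id: str, pose: str) -> list[EffectIncrement]:
        return [i for i in self.increments
                if i.bone_id == bone_id and i.pose == pose]


def zero_effects(vertex_noise_sd: float = 0.0) -> EffectConfig:
    return EffectConfig((), between_specimen_sd_rot=0.0,
                        between_specimen_sd_trans=0.0,
                        vertex_noise_sd=vertex_noise_sd)


def default_effects() -> EffectConfig:
    """Transection effects: the two published rotation magnitudes (scaphoid
    +11.71 deg in flexion, fifth metacarpal 9.13 deg further into extension)
    plus 5 mm / 3 mm placeholder magnitudes for the translation effects
    reported significant (palmar = -z, proximal = +y, ulnar = -x) and a
    5 deg placeholder for the first-metacarpal rotation increase."""
    e = EffectIncrement
    inc = (
        # flexion: rotations
        e("scaphoid", "flexion", "x", "rotation", 11.71),
        e("mc1", "flexion", "x", "rotation", 5.0),
        # flexion: palmar translation of trapezoid + metacarpals, mc5 proximal
        e("trapezoid", "flexion", "z", "translation", -3.0),
        e("mc1", "flexion", "z", "translation", -5.0),
        e("mc2", "flexion", "z", "translation", -5.0),
        e("mc3", "flexion", "z", "translation", -5.0),
        e("mc4", "flexion", "z", "translation", -5.0),
        e("mc5", "flexion", "z", "translation", -5.0),
        e("mc5", "flexion", "y", "translation", 3.0),
        # extension: mc5 rotates further into extension; mc2-4 move proximally
        e("mc5", "extension", "x", "rotation", -9.13),
        e("mc2", "extension", "y", "translation", 5.0),
        e("mc3", "extension", "y", "translation", 5.0),
        e("mc4", "extension", "y", "translation", 5.0),
        # ulnar deviation: mc1/mc2 ulnar translation, mc4/mc5 proximal
        e("mc1", "ulnar_deviation", "x", "translation", -5.0),
        e("mc2", "ulnar_deviation", "x", "translation", -3.0),
        e("mc4", "ulnar_deviation", "y", "translation", 3.0),
        e("mc5", "ulnar_deviation", "y", "translation", 5.0),
        # radial deviation: no significant effects
    )
    return EffectConfig(inc)


# --------------------------------------------------------------------------
# row-based pose model


@dataclass
class RowModel:
    """Kinematic study design: global pose amplitudes and row shares."""

    amplitude_mean: dict = field(default_factory=lambda: {
        "flexion": 60.0, "extension": 50.0,
        "ulnar_deviation": 30.0, "radial_deviation": 20.0})
    amplitude_sd: dict = field(default_factory=lambda: {
        "flexion": 8.0, "extension": 8.0,
        "ulnar_deviation": 5.0, "radial_deviation": 4.0})
    proximal_row_share: float = 0.5
    ulna_fixed_deg: float = 1.0

    def row_share(self, row: str) -> float:
        if row == "forearm":
            return 0.0
        if row == "proximal_row":
            return self.proximal_row_share
        return 1.0


@dataclass
class SpecimenDraw:
    """Per-specimen random state: one signed global pose angle per
    (pose, condition) scan — each scan is an independent physical
    repositioning to "maximal extent" — and per-effect deviations."""

    amplitudes: dict          # (pose, condition) -> signed angle (deg)
    effect_deviations: dict   # EffectIncrement index -> deviation


def draw_specimen(model: RowModel, effects: EffectConfig,
                  rng: np.random.Generator) -> SpecimenDraw:
    amplitudes = {}
    for pose in POSES:
        if pose == "neutral":
            continue
        axis, direction = POSE_AXIS[pose]
        for condition in CONDITIONS:
            amp = rng.normal(model.amplitude_mean[pose], model.amplitude_sd[pose])
            amplitudes[(pose, condition)] = direction * amp
    deviations = {}
    for k, inc in enumerate(effects.increments):
        sd = (effects.between_specimen_sd_rot if inc.channel == "rotation"
              else effects.between_specimen_sd_trans)
        deviations[k] = rng.normal(0.0, sd)
    return SpecimenDraw(amplitudes, deviations)


def pose_model(pose: str, condition: str, effects: EffectConfig,
               specimen_draw: SpecimenDraw, bone: BoneTemplate,
               model: RowModel | None = None) -> RigidTransform:
    """Ground-truth rigid transform of one bone in the referential frame.

    Rotations act about the bone's neutral centroid; transection increments
    are composed after the intact pose transform.
    """
    model = model or RowModel()
    if pose == "neutral":
        return RigidTransform.identity()
    if pose not in POSE_AXIS:
        raise ValueError(f"unknown pose {pose!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    axis, _ = POSE_AXIS[pose]
    if bone.bone_id == "ulna":
        _, direction = POSE_AXIS[pose]
        rot = axis_rotation(axis, model.ulna_fixed_deg * direction)
    else:
        angle = specimen_draw.amplitudes[(pose, condition)] * model.row_share(bone.row)
        rot = axis_rotation(axis, angle)
    extra = np.zeros(3)
    if condition == "transected":
        for k, inc in enumerate(effects.increments):
            if inc.bone_id != bone.bone_id or inc.pose != pose:
                continue
            value = inc.value + specimen_draw.effect_deviations.get(k, 0.0)
            if inc.channel == "rotation":
                rot = axis_rotation(inc.axis, value) @ rot
            else:
                extra[AXIS_INDEX[inc.axis]] += value
    return RigidTransform.about_point(rot, bone.neutral_position, extra)


# --------------------------------------------------------------------------
# specimen / cohort generation


@dataclass
class GroundTruth:
    """Exact transforms (referential frame) and landmarks per scan."""

    transforms: dict     # (bone, pose, condition) -> RigidTransform
    landmarks: dict      # (pose, condition) -> {name: 3-vector}

    def transform(self, bone: str, pose: str, condition: str) -> RigidTransform:
        return self.transforms[(bone, pose, condition)]


@dataclass
class Specimen:
    specimen_id: str
    handedness: str
    meshes: dict         # (pose, condition) -> {bone: trimesh.Trimesh}
    ground_truth: GroundTruth

    @property
    def landmarks(self) -> dict:
        """Per-scan landmark dicts (same layout the kinematics stage reads)."""
        return self.ground_truth.landmarks


def generate_specimen(specimen_id: str, templates: dict[str, BoneTemplate] | None = None,
                      effects: EffectConfig | None = None, seed: int = 0,
                      subdivision: int = 3, model: RowModel | None = None) -> Specimen:
    templates = templates or default_templates()
    effects = default_effects() if effects is None else effects
    model = model or RowModel()
    ids = [t.bone_id for t in templates.values()]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate bone ids in templates")
    rng = np.random.default_rng([seed, 101])
    draw = draw_specimen(model, effects, rng)
    neutral = {bone: neutral_mesh(t, subdivision) for bone, t in templates.items()}
    meshes: dict = {}
    transforms: dict = {}
    landmarks: dict = {}
    for pose in POSES:
        for condition in CONDITIONS:
            bone_meshes = {}
            for bone, template in templates.items():
                t = pose_model(pose, condition, effects, draw, template, model)
                transforms[(bone, pose, condition)] = t
                verts = t.apply(neutral[bone].vertices.view(np.ndarray))
                if effects.vertex_noise_sd > 0:
                    noise_rng = np.random.default_rng(
                        [seed, 7, ids.index(template.bone_id), POSES.index(pose),
                         CONDITIONS.index(condition)])
                    verts = verts + noise_rng.normal(
                        0.0, effects.vertex_noise_sd, size=verts.shape)
                bone_meshes[bone] = geometry.as_mesh(verts, neutral[bone].faces)
            meshes[(pose, condition)] = bone_meshes
            radius_t = transforms[("radius", pose, condition)]
            landmarks[(pose, condition)] = {
                name: radius_t.apply(point)
                for name, point in LANDMARK_POINTS.items()}
    return Specimen(specimen_id, "right", meshes, GroundTruth(transforms, landmarks))


@dataclass
class VoxelVolume:
    """CT-like scalar volume: intensities (HU), affine (index -> world mm)."""

    data: np.ndarray
    affine: np.ndarray

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


def voxelize(meshes: dict[str, trimesh.Trimesh], spacing_mm: float = 0.5,
             bone_hu: float = 700.0, background_hu: float = -50.0,
             noise_sd_hu: float = 0.0, seed: int = 0,
             margin_voxels: int = 3) -> VoxelVolume:
    """Rasterize bone meshes into a Hounsfield-like volume.

    Voxel centres inside any mesh get ``bone_hu``, the rest ``background_hu``,
    plus optional i.i.d. Gaussian noise.  Overlapping bones are assigned to
    the smaller bone with a warning.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    if bone_hu <= background_hu:
        raise ValueError("bone HU must exceed background HU")
    if margin_voxels < 2:
        raise ValueError("margin must be at least 2 voxels")
    if meshes:
        bounds = np.array([m.bounds for m in meshes.values()])
        lo = bounds[:, 0, :].min(axis=0) - margin_voxels * spacing_mm
        hi = bounds[:, 1, :].max(axis=0) + margin_voxels * spacing_mm
    else:
        lo, hi = np.zeros(3), np.full(3, 10 * spacing_mm)
    shape = np.ceil((hi - lo) / spacing_mm).astype(int) + 1
    occupancy = np.zeros(tuple(shape), dtype=bool)
    owner = np.full(tuple(shape), -1, dtype=np.int16)
    volumes = {b: geometry.mesh_volume(m) for b, m in meshes.items()}
    order = sorted(meshes, key=lambda b: -volumes[b])  # big first, small overwrite
    overlap_found = False
    for bone in order:
        mesh = meshes[bone]
        blo = np.floor((mesh.bounds[0] - lo) / spacing_mm).astype(int) - 1
        bhi = np.ceil((mesh.bounds[1] - lo) / spacing_mm).astype(int) + 2
        blo = np.clip(blo, 0, shape - 1)
        bhi = np.clip(bhi, 1, shape)
        sub_origin = lo + blo * spacing_mm
        sub_shape = tuple(bhi - blo)
        mask = geometry.rasterize_mesh(mesh, sub_origin, spacing_mm, sub_shape)
        view = tuple(slice(a, b) for a, b in zip(blo, bhi))
        if (occupancy[view] & mask).any():
            overlap_found = True
        occupancy[view] |= mask
        owner[view][mask] = order.index(bone)
    if overlap_found:
        warnings.warn("overlapping bones at some voxels; assigned to the "
                      "smaller-volume bone", stacklevel=2)
    data = np.where(occupancy, bone_hu, background_hu).astype(np.float32)
    if noise_sd_hu > 0:
        rng = np.random.default_rng([seed, 11])
        data = data + rng.normal(0.0, noise_sd_hu, size=data.shape).astype(np.float32)
    affine = np.eye(4)
    affine[:3, :3] *= spacing_mm
    affine[:3, 3] = lo
    return VoxelVolume(data, affine)


@dataclass
class StudyManifest:
    """Accounting of every (specimen, pose, condition) scan in a cohort."""

    specimens: list      # dicts: {id, handedness, conditions}
    poses: list
    entries: list        # dicts: {specimen, pose, condition, mesh_dir, volume}
    seed: int

    def scan_entries(self, condition: str | None = None) -> list:
        if condition is None:
            return list(self.entries)
        return [e for e in self.entries if e["condition"] == condition]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"specimens": self.specimens, "poses": self.poses,
             "entries": self.entries, "seed": self.seed}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyManifest":
        d = json.loads(Path(path).read_text())
        return cls(d["specimens"], d["poses"], d["entries"], d["seed"])


def _write_specimen(specimen: Specimen, out_dir: Path, fmt: str = "stl",
                    volumes: bool = False, spacing: float = 0.5,
                    seed: int = 0) -> list[dict]:
    import nibabel as nib

    entries = []
    for (pose, condition), bone_meshes in specimen.meshes.items():
        scan_dir = out_dir / specimen.specimen_id / f"{pose}_{condition}"
        scan_dir.mkdir(parents=True, exist_ok=True)
        for bone, mesh in bone_meshes.items():
            mesh.export(scan_dir / f"{bone}.{fmt}")
        lm = {name: list(map(float, point))
              for name, point in specimen.ground_truth.landmarks[(pose, condition)].items()}
        (scan_dir / "landmarks.json").write_text(json.dumps(
            {"specimen": specimen.specimen_id, "pose": pose,
             "condition": condition, **lm}, indent=1))
        entry = {"specimen": specimen.specimen_id, "pose": pose,
                 "condition": condition, "mesh_dir": str(scan_dir)}
        if volumes:
            vol = voxelize(bone_meshes, spacing_mm=spacing, seed=seed)
            img = nib.Nifti1Image(vol.data, vol.affine)
            vol_path = scan_dir / "volume.nii.gz"
            nib.save(img, vol_path)
            entry["volume"] = str(vol_path)
        entries.append(entry)
    gt = {f"{b}|{p}|{c}": t.as_matrix().tolist()
          for (b, p, c), t in specimen.ground_truth.transforms.items()}
    (out_dir / specimen.specimen_id / "ground_truth.json").write_text(
        json.dumps(gt, indent=1))
    return entries


def generate_cohort(n_specimens: int, templates: dict[str, BoneTemplate] | None = None,
                    effects: EffectConfig | None = None, seed: int = 0,
                    out_dir: str | Path | None = None, overwrite: bool = False,
                    write_volumes: bool = False, spacing: float = 0.5,
                    subdivision: int = 3, model: RowModel | None = None,
                    materialize: bool = True,
                    ) -> tuple[StudyManifest, dict[str, Specimen]]:
    """Generate the full study: ``n_specimens`` wrists, 5 poses, 2 conditions.

    With ``materialize=False`` only the manifest accounting and ground truth
    draws are produced (no meshes), which is enough for design checks and
    record-level simulation.
    """
    if n_specimens < 1:
        raise ValueError("need at least one specimen")
    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        if out_path.exists() and any(out_path.iterdir()) and not overwrite:
            raise FileExistsError(f"{out_path} exists and is not empty "
                                  "(pass overwrite=True)")
        out_path.mkdir(parents=True, exist_ok=True)
    specimens: dict[str, Specimen] = {}
    entries: list[dict] = []
    spec_meta = []
    for i in range(n_specimens):
        sid = f"S{i + 1:03d}"
        spec_meta.append({"id": sid, "handedness": "right",
                          "conditions": list(CONDITIONS)})
        if materialize:
            specimen = generate_specimen(sid, templates, effects, seed=seed + i,
                                         subdivision=subdivision, model=model)
            specimens[sid] = specimen
            if out_path is not None:
                entries.extend(_write_specimen(specimen, out_path,
                                               volumes=write_volumes,
                                               spacing=spacing, seed=seed + i))
        if out_path is None or not materialize:
            for pose in POSES:
                for condition in CONDITIONS:
                    entries.append({"specimen": sid, "pose": pose,
                                    "condition": condition, "mesh_dir": None})
    manifest = StudyManifest(spec_meta, list(POSES), entries, seed)
    if out_path is not None:
        manifest.to_json(out_path / "manifest.json")
    return manifest, specimens


# --------------------------------------------------------------------------
# record-level simulation (mesh-free path through the same pose model)


def ground_truth_records(specimen_id: str, ground_truth: GroundTruth,
                         templates: dict[str, BoneTemplate]) -> "pandas.DataFrame":
    """Decomposed ground-truth motion records of one specimen."""
    import pandas as pd

    from .kinematics import decompose_rotation

    rows = []
    for (bone, pose, condition), t in ground_truth.transforms.items():
        if pose == "neutral":
            continue
        centroid = templates[bone].neutral_position
        trans = t.apply(centroid) - centroid
        rx, rz, ry = decompose_rotation(t.rotation)
        rows.append({"specimen": specimen_id, "bone": bone, "pose": pose,
                     "condition": condition, "rot_x_deg": rx, "rot_z_deg": rz,
                     "rot_y_deg": ry, "trans_x_mm": trans[0],
                     "trans_y_mm": trans[1], "trans_z_mm": trans[2]})
    return pd.DataFrame(rows)


def simulate_motion_records(n_specimens: int, effects: EffectConfig | None = None,
                            seed: int = 0, model: RowModel | None = None,
                            templates: dict[str, BoneTemplate] | None = None,
                            measurement_noise_rot: float = 0.1,
                            measurement_noise_trans: float = 0.05,
                            ) -> "pandas.DataFrame":
    """Cohort motion table straight from the pose model (no meshes).

    Emulates what the full reconstruction pipeline would measure: the
    ground-truth decomposed rotations/translations plus small Gaussian
    measurement error mimicking segmentation/frame noise.  Used for the
    statistics stage at replication scales where meshing every scan would
    be pointless.
    """
    import pandas as pd

    effects = default_effects() if effects is None else effects
    model = model or RowModel()
    templates = templates or default_templates()
    frames = []
    for i in range(n_specimens):
        sid = f"S{i + 1:03d}"
        rng = np.random.default_rng([seed + i, 101])
        draw = draw_specimen(model, effects, rng)
        transforms = {
            (bone, pose, condition): pose_model(pose, condition, effects, draw,
                                                templates[bone], model)
            for bone in templates for pose in POSES for condition in CONDITIONS}
        df = ground_truth_records(sid, GroundTruth(transforms, {}), templates)
        noise_rng = np.random.default_rng([seed + i, 202])
        n = len(df)
        for col in ("rot_x_deg", "rot_z_deg", "rot_y_deg"):
            df[col] = df[col] + noise_rng.normal(0, measurement_noise_rot, n)
        for col in ("trans_x_mm", "trans_y_mm", "trans_z_mm"):
            df[col] = df[col] + noise_rng.normal(0, measurement_noise_trans, n)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
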