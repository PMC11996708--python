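"""Bone surface reconstruction from CT-like volumes.

Open-algorithm equivalents of the commercial segmentation workflow:
Hounsfield-window thresholding, 26-connected component labelling, marching
cubes isosurfacing and Taubin (volume-preserving) smoothing, plus seeded
assignment of anonymous components to named bones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from . import geometry
from .synthetic import VoxelVolume


class SegmentationError(ValueError):
    pass


@dataclass
class LabelMap:
    """Connected bone components: 0 = background, 1..K by decreasing size."""

    labels: np.ndarray
    affine: np.ndarray
    sizes: dict          # label -> voxel count

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def threshold_segment(volume: VoxelVolume, hu_min: float,
                      hu_max: float = np.inf, min_voxels: int = 1) -> LabelMap:
    """Label 26-connected foreground components inside a HU window."""
    if hu_min >= hu_max:
        raise ValueError("hu_min must be below hu_max")
    fg = (volume.data >= hu_min) & (volume.data <= hu_max)
    if not fg.any():
        raise SegmentationError("no bone voxels in HU window "
                                f"[{hu_min:g}, {hu_max:g}]")
    raw, n = ndimage.label(fg, structure=_CONN26)
    counts = np.bincount(raw.ravel())[1:]  # skip background
    keep = np.flatnonzero(counts >= min_voxels) + 1
    order = keep[np.argsort(-counts[keep - 1], kind="stable")]
    relabel = np.zeros(n + 1, dtype=np.int32)
    relabel[order] = np.arange(1, len(order) + 1)
    labels = relabel[raw]
    sizes = {int(relabel[lab]): int(counts[lab - 1]) for lab in order}
    return LabelMap(labels, volume.affine.copy(), sizes)


def pad_volume(volume: VoxelVolume, pad: int = 2,
               background_hu: float = -1000.0) -> VoxelVolume:
    """Surround the volume with background voxels (affine shifted to match)."""
    data = np.pad(volume.data, pad, constant_values=background_hu)
    affine = volume.affine.copy()
    affine[:3, 3] -= affine[:3, :3] @ np.full(3, pad)
    return VoxelVolume(data, affine)


def label_to_mesh(labelmap: LabelMap, label: int) -> trimesh.Trimesh:
    """Marching-cubes isosurface (level 0.5) of one label, in world mm."""
    if label not in labelmap.sizes:
        raise SegmentationError(f"label {label} not present")
    mask = labelmap.labels == label
    idx = np.argwhere(mask)
    if (idx.min(axis=0) == 0).any() or \
            (idx.max(axis=0) == np.array(mask.shape) - 1).any():
        raise SegmentationError(
            f"label {label} touches the volume boundary; pad the volume first")
    spacing = labelmap.spacing
    lo = idx.min(axis=0) - 1
    hi = idx.max(axis=0) + 2
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    verts, faces, _, _ = measure.marching_cubes(
        sub.astype(np.float32), level=0.5, spacing=tuple(spacing))
    verts = verts + labelmap.affine[:3, 3] + lo * spacing
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_winding_consistent:
        mesh.fix_normals()
    geometry.require_closed(mesh)
    return mesh


def smooth_mesh(mesh: trimesh.Trimesh, iterations: int = 10,
                pass_band: float = 0.1) -> trimesh.Trimesh:
    """Taubin smoothing: a shrink step (λ) followed by an inflate step (µ)
    per iteration, so staircase artefacts fade without the volume loss of
    plain Laplacian smoothing.  ``pass_band`` sets µ via 1/λ + 1/µ = k_pb
    with λ = 0.5; vertex count and topology are unchanged.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    out = mesh.copy()
    if iterations == 0:
        return out
    lamb = 0.5
    mu = 1.0 / (pass_band - 1.0 / lamb)   # negative for pass_band < 2
    trimesh.smoothing.filter_taubin(out, lamb=lamb, nu=abs(mu),
                                    iterations=iterations)
    return out


def match_labels_to_bones(meshes: dict[int, trimesh.Trimesh] | list,
                          seeds: dict[str, np.ndarray]) -> dict[str, trimesh.Trimesh]:
    """Assign anonymous component meshes to named bones via seed points.

    A seed inside exactly one mesh claims it; two seeds inside one mesh mean
    the HU window fused neighbouring bones.  Seeds inside no mesh fall back
    to greedy nearest-centroid assignment among unclaimed meshes.
    """
    if isinstance(meshes, dict):
        items = list(meshes.items())
    else:
        items = list(enumerate(meshes))
    containment: dict[int, list[str]] = {}
    seed_hit: dict[str, int | None] = {}
    for bone, point in seeds.items():
        hit = None
        for key, mesh in items:
            if geometry.points_in_mesh(mesh, np.asarray(point, dtype=float))[0]:
                hit = key
                containment.setdefault(key, []).append(bone)
                break
        seed_hit[bone] = hit
    fused = {k: v for k, v in containment.items() if len(v) > 1}
    if fused:
        names = "; ".join(f"{sorted(v)}" for v in fused.values())
        raise SegmentationError(
            f"fused bones — adjust HU window (one component contains seeds {names})")
    assigned = {bones[0]: dict(items)[key] for key, bones in containment.items()}
    unclaimed = [(key, mesh) for key, mesh in items if key not in containment]
    missing = [b for b, h in seed_hit.items() if h is None]
    for bone in missing:
        if not unclaimed:
            raise SegmentationError(f"no component found for bone {bone!r}")
        point = np.asarray(seeds[bone], dtype=float)
        dists = [np.linalg.norm(geometry.volumetric_centroid(m) - point)
                 for _, m in unclaimed]
        j = int(np.argmin(dists))
        assigned[bone] = unclaimed.pop(j)[1]
    return assigned


def reconstruct_bones(volume: VoxelVolume, seeds: dict[str, np.ndarray],
                      hu_min: float = 300.0, hu_max: float = np.inf,
                      min_voxels: int = 30, smooth_iterations: int = 10,
                      background_hu: float = -1000.0,
                      ) -> dict[str, trimesh.Trimesh]:
    """Full segmentation stage: pad, threshold, mesh, smooth, name."""
    padded = pad_volume(volume, pad=2, background_hu=background_hu)
    labelmap = threshold_segment(padded, hu_min, hu_max, min_voxels)
    meshes = {label: smooth_mesh(label_to_mesh(labelmap, label),
                                 iterations=smooth_iterations)
              for label in labelmap.sizes}
    return match_labels_to_bones(meshes, seeds)
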