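"""Exact volumetric properties of closed triangle meshes.

Volume, solid (uniform-density) centroid and inertia tensor are evaluated by
the divergence theorem: every face spans a signed tetrahedron with the
origin, whose moments have closed forms.  These quantities feed the
inertia-axis object frames, so they are computed here from first principles;
``trimesh`` is used as the mesh container and for generic mesh plumbing.

Meshes are ``trimesh.Trimesh`` objects in world millimetres with outward,
consistent winding.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .transforms import Frame

__all__ = [
    "NonClosedMeshError",
    "DegenerateInertiaError",
    "require_closed",
    "mesh_volume",
    "volumetric_centroid",
    "inertia_tensor",
    "principal_axes",
    "crop_by_plane",
    "points_in_mesh",
    "rasterize_mesh",
]


class NonClosedMeshError(ValueError):
    """The mesh is not watertight / consistently wound."""


class DegenerateInertiaError(ValueError):
    """Inertia eigenvalues too close to define principal axes."""


def as_mesh(vertices: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    return trimesh.Trimesh(vertices=np.asarray(vertices, dtype=float),
                           faces=np.asarray(faces, dtype=np.int64),
                           process=False)


def require_closed(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    if not mesh.is_watertight:
        raise NonClosedMeshError("mesh is not closed (open edges present)")
    if not mesh.is_winding_consistent:
        raise NonClosedMeshError("mesh winding is inconsistent")
    if _signed_volume(mesh) <= 0:
        raise NonClosedMeshError("mesh is inward-oriented (signed volume <= 0)")
    return mesh


def _triangles(mesh: trimesh.Trimesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    v = mesh.vertices.view(np.ndarray)
    f = mesh.faces.view(np.ndarray)
    return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]


def _signed_volume(mesh: trimesh.Trimesh) -> float:
    a, b, c = _triangles(mesh)
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume in mm³ (sum of signed origin-tetrahedra)."""
    require_closed(mesh)
    return _signed_volume(mesh)


def volumetric_centroid(mesh: trimesh.Trimesh) -> np.ndarray:
    """Centroid of the enclosed, uniform-density solid (mm)."""
    require_closed(mesh)
    a, b, c = _triangles(mesh)
    vol_t = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    first_moment = vol_t[:, None] * (a + b + c) / 4.0
    return first_moment.sum(axis=0) / vol_t.sum()


def inertia_tensor(mesh: trimesh.Trimesh, about: np.ndarray | None = None,
                   density: float = 1.0) -> np.ndarray:
    """Uniform-density solid inertia tensor (about the centroid by default).

    Per signed tetrahedron (origin, a, b, c) the second-moment (covariance)
    matrix is ``V/20 · (a aᵀ + b bᵀ + c cᵀ + s sᵀ)`` with ``s = a + b + c``;
    the inertia tensor follows as ``tr(C)·I − C`` and is moved to ``about``
    with the parallel-axis theorem.
    """
    require_closed(mesh)
    a, b, c = _triangles(mesh)
    vol_t = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    s = a + b + c
    cov = np.einsum("t,tij->ij", vol_t,
                    (np.einsum("ti,tj->tij", a, a)
                     + np.einsum("ti,tj->tij", b, b)
                     + np.einsum("ti,tj->tij", c, c)
                     + np.einsum("ti,tj->tij", s, s))) / 20.0
    cov *= density
    inertia_origin = np.trace(cov) * np.eye(3) - cov
    volume = vol_t.sum()
    mass = density * volume
    centroid = (vol_t[:, None] * s / 4.0).sum(axis=0) / volume
    # shift origin -> centroid, then centroid -> about
    inertia_cm = inertia_origin - mass * (
        np.dot(centroid, centroid) * np.eye(3) - np.outer(centroid, centroid))
    if about is None:
        return inertia_cm
    d = centroid - np.asarray(about, dtype=float)
    return inertia_cm + mass * (np.dot(d, d) * np.eye(3) - np.outer(d, d))


def principal_axes(inertia: np.ndarray,
                   reference: Frame | np.ndarray | None = None,
                   gap_tol: float = 1e-6) -> np.ndarray:
    """Sign-consistent principal axes of a symmetric inertia tensor.

    Rows are eigenvectors sorted by ascending eigenvalue, so row 0 is the
    longitudinal axis (smallest moment = longest extent).  Each axis is
    flipped to have a positive dot product with the corresponding row of
    ``reference``; right-handedness is then restored by flipping the last
    axis if needed.  This implements the convention that object axes keep
    pointing "the same way" from pose to pose when the previous (or the
    referential) axes are passed as the reference.
    """
    inertia = np.asarray(inertia, dtype=float)
    if not np.allclose(inertia, inertia.T, atol=1e-9 * max(1.0, abs(inertia).max())):
        raise ValueError("inertia tensor must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(inertia)
    if np.diff(eigvals).min() < gap_tol * np.trace(inertia):
        raise DegenerateInertiaError(
            f"inertia eigenvalues too close: {eigvals} (gap tol {gap_tol:g}·trace)")
    axes = eigvecs.T  # rows
    if reference is not None:
        ref = reference.axes if isinstance(reference, Frame) else np.asarray(reference, dtype=float)
        for i in range(3):
            if np.dot(axes[i], ref[i]) < 0:
                axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes


def _boundary_loops(mesh: trimesh.Trimesh) -> list[list[int]]:
    """Closed vertex loops of directed boundary edges (open-fan winding)."""
    edge_set = set(map(tuple, mesh.edges))
    boundary = [(a, b) for a, b in mesh.edges if (b, a) not in edge_set]
    nxt = dict(boundary)
    loops: list[list[int]] = []
    seen: set[int] = set()
    for start, _ in boundary:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt.get(start)
        while cur is not None and cur != start:
            loop.append(cur)
            seen.add(cur)
            cur = nxt.get(cur)
        if cur == start and len(loop) >= 3:
            loops.append(loop)
    return loops


def crop_by_plane(mesh: trimesh.Trimesh, point: np.ndarray,
                  normal: np.ndarray) -> trimesh.Trimesh:
    """Keep the half-space ``(v − point)·normal ≤ 0`` and cap the cut.

    The planar cut polygon is triangulated as a fan around its centroid so
    the result stays closed (bone cross-sections are star-shaped, which the
    fan requires).
    """
    require_closed(mesh)
    point = np.asarray(point, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    side = (mesh.vertices.view(np.ndarray) - point) @ normal
    if side.max() <= 0:
        return mesh  # already entirely on the kept side
    if side.min() >= 0:
        raise ValueError("mesh lies entirely on the discarded side of the plane")
    open_mesh = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=-normal, plane_origin=point, cap=False)
    open_mesh = trimesh.Trimesh(open_mesh.vertices, open_mesh.faces, process=True)
    open_mesh.merge_vertices(merge_tex=True, merge_norm=True)
    vertices = open_mesh.vertices.view(np.ndarray).copy()
    faces = list(map(list, open_mesh.faces.view(np.ndarray)))
    for loop in _boundary_loops(open_mesh):
        centroid = vertices[loop].mean(axis=0)
        c_idx = len(vertices)
        vertices = np.vstack([vertices, centroid])
        n = len(loop)
        for k in range(n):
            a, b = loop[k], loop[(k + 1) % n]
            # cap triangle carries the reversed directed edge (b -> a)
            faces.append([b, a, c_idx])
    result = trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=True)
    if _signed_volume(result) < 0:
        result.invert()
    require_closed(result)
    return result


# --- point containment / voxel rasterization (parity of +z ray crossings) ---

def _column_crossings(mesh: trimesh.Trimesh, xy: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """For each xy column return z-values where a vertical line crosses the
    surface, as flat arrays (column_index, z)."""
    a, b, c = _triangles(mesh)
    cols: list[np.ndarray] = []
    zs: list[np.ndarray] = []
    # bounding boxes in xy to prune column/triangle pairs
    tri_min = np.minimum(np.minimum(a[:, :2], b[:, :2]), c[:, :2])
    tri_max = np.maximum(np.maximum(a[:, :2], b[:, :2]), c[:, :2])
    order = np.lexsort((xy[:, 1], xy[:, 0]))
    xy_sorted = xy[order]
    xs = xy_sorted[:, 0]
    for t in range(len(a)):
        lo = np.searchsorted(xs, tri_min[t, 0], side="left")
        hi = np.searchsorted(xs, tri_max[t, 0], side="right")
        if hi <= lo:
            continue
        sel = slice(lo, hi)
        pts = xy_sorted[sel]
        inside_y = (pts[:, 1] >= tri_min[t, 1]) & (pts[:, 1] <= tri_max[t, 1])
        if not inside_y.any():
            continue
        pts = pts[inside_y]
        idx = order[sel][inside_y]
        # barycentric test in the xy projection
        v0 = b[t, :2] - a[t, :2]
        v1 = c[t, :2] - a[t, :2]
        det = v0[0] * v1[1] - v0[1] * v1[0]
        if abs(det) < 1e-14:
            continue  # vertical triangle: projects to a line
        d = pts - a[t, :2]
        u = (d[:, 0] * v1[1] - d[:, 1] * v1[0]) / det
        v = (v0[0] * d[:, 1] - v0[1] * d[:, 0]) / det
        hit = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
        if not hit.any():
            continue
        z = (a[t, 2] + u[hit] * (b[t, 2] - a[t, 2]) + v[hit] * (c[t, 2] - a[t, 2]))
        cols.append(idx[hit])
        zs.append(z)
    if not cols:
        return np.empty(0, dtype=np.int64), np.empty(0)
    return np.concatenate(cols), np.concatenate(zs)


_JITTER = 1.2345e-6  # breaks exact vertex/edge alignment of test columns


def points_in_mesh(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Boolean inside test by parity of upward ray crossings."""
    require_closed(mesh)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    scale = float(mesh.scale) or 1.0
    xy = points[:, :2] + _JITTER * scale
    col, z = _column_crossings(mesh, xy)
    inside = np.zeros(len(points), dtype=bool)
    if len(col):
        above = z > points[col, 2]
        counts = np.bincount(col[above], minlength=len(points))
        inside = (counts % 2) == 1
    return inside


def rasterize_mesh(mesh: trimesh.Trimesh, origin: np.ndarray,
                   spacing: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean voxel mask of voxel centres inside the mesh.

    ``origin`` is the world position of voxel index (0,0,0)'s centre; the
    grid is axis-aligned with steps ``spacing``.
    """
    require_closed(mesh)
    origin = np.asarray(origin, dtype=float)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    nx, ny, nz = shape
    ix = np.arange(nx)
    iy = np.arange(ny)
    gx, gy = np.meshgrid(origin[0] + ix * spacing[0] + _JITTER * spacing[0],
                         origin[1] + iy * spacing[1] + _JITTER * spacing[1],
                         indexing="ij")
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    col, z = _column_crossings(mesh, xy)
    mask = np.zeros((nx * ny, nz), dtype=bool)
    if len(col):
        # voxel-centre z of first centre strictly above each crossing
        kz = np.ceil((z - origin[2]) / spacing[2] - 1e-12).astype(np.int64)
        kz = np.clip(kz, 0, nz)  # nz == "beyond the grid" bucket
        counts = np.zeros((nx * ny, nz + 1), dtype=np.int32)
        np.add.at(counts, (col, kz), 1)
        below = np.cumsum(counts[:, :nz], axis=1)
        # crossings at z <= centre: total per column minus those above
        total = counts.sum(axis=1, keepdims=True)
        above = total - below
        mask = (above % 2) == 1
    return mask.reshape(nx, ny, nz)
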