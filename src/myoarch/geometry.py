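"""Segmentation-derived geometry: surface meshes, volumes, long axis, tracking masks.

All world coordinates are in millimetres. Voxel indices are 0-based and a voxel
is "inside" a region when its centre is inside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "LabelVolume",
    "SurfaceMesh",
    "LongAxis",
    "OpenMeshError",
    "build_surface",
    "mesh_volume",
    "muscle_length",
    "auto_long_axis",
    "make_seed_and_boundary_masks",
    "volume_reliability",
]


class OpenMeshError(ValueError):
    """Raised when an operation requiring a closed mesh meets boundary edges."""

    def __init__(self, boundary_edges):
        self.boundary_edges = boundary_edges
        preview = ", ".join(map(str, boundary_edges[:10]))
        more = "" if len(boundary_edges) <= 10 else f" (+{len(boundary_edges) - 10} more)"
        super().__init__(f"mesh is not closed; boundary edges: {preview}{more}")


@dataclass
class LabelVolume:
    """Integer compartment labels on a regular grid (0 = background)."""

    data: np.ndarray  # (X, Y, Z) int
    affine: np.ndarray  # 4x4 voxel -> world (mm)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        for lab in self.labels():
            n_comp = ndimage.label(self.data == lab)[1]
            if n_comp > 1:
                warnings.warn(f"label {lab} has {n_comp} connected components", stacklevel=2)

    def labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.data) if v != 0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_count_volume_mm3(self, label: int) -> float:
        return float((self.data == label).sum()) * self.voxel_volume_mm3


@dataclass
class SurfaceMesh:
    """Triangulated surface in world millimetres."""

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int
    label: int = 0

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    def boundary_edges(self) -> list[tuple[int, int]]:
        """Edges bounding a hole: shared by an odd number of triangles.

        A watertight mesh has every edge in an even number of triangles
        (exactly 2 for a manifold; voxel surfaces may have 4 where regions
        touch diagonally). Odd counts mean the surface does not close.
        """
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return [tuple(edge) for edge in uniq[counts % 2 != 0]]

    def is_closed(self) -> bool:
        return not self.boundary_edges()

    def signed_volume_mm3(self) -> float:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def oriented_outward(self) -> "SurfaceMesh":
        """Return a copy whose triangle winding gives positive signed volume."""
        if self.signed_volume_mm3() < 0:
            return SurfaceMesh(self.vertices.copy(), self.faces[:, ::-1].copy(), self.label)
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.label)

    def translated(self, offset) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices + np.asarray(offset, dtype=float), self.faces.copy(), self.label)


@dataclass
class LongAxis:
    """Muscle long axis through two world points; direction runs distal -> proximal."""

    proximal: np.ndarray
    distal: np.ndarray

    def __post_init__(self):
        self.proximal = np.asarray(self.proximal, dtype=float).reshape(3)
        self.distal = np.asarray(self.distal, dtype=float).reshape(3)
        if np.linalg.norm(self.proximal - self.distal) < 1e-12:
            raise ValueError("long-axis points must be distinct")

    @property
    def direction(self) -> np.ndarray:
        d = self.proximal - self.distal
        return d / np.linalg.norm(d)


def _taubin_smooth(vertices: np.ndarray, faces: np.ndarray, iterations: int,
                   lam: float = 0.33, mu: float = -0.34) -> np.ndarray:
    """Volume-conserving two-pass Laplacian smoothing (shrink + inflate)."""
    n = len(vertices)
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    i = np.concatenate([e[:, 0], e[:, 1]])
    j = np.concatenate([e[:, 1], e[:, 0]])
    deg = np.bincount(i, minlength=n).astype(float)
    v = vertices.copy()
    for _ in range(iterations):
        for factor in (lam, mu):
            nb = np.zeros_like(v)
            np.add.at(nb, i, v[j])
            v = v + factor * (nb / deg[:, None] - v)
    return v


def _voxel_boundary_surface(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed triangulated surface of the voxel boundary, in voxel-index
    coordinates (voxel ``i`` spans ``i - 0.5 .. i + 0.5``). The enclosed volume
    equals the voxel count exactly."""
    m = np.pad(mask, 1)
    quads = []  # (4, 3) corner coordinates in half-voxel integer units
    # in-plane corner offsets, CCW seen from the +axis side
    for axis in range(3):
        inside = m.astype(np.int8)
        diff = np.diff(inside, axis=axis)  # +1: exits at the far face of voxel i
        for sign in (1, -1):
            faces_idx = np.argwhere(diff == sign)
            if not len(faces_idx):
                continue
            # boundary plane sits between voxel i and i+1 along `axis`;
            # half-unit coordinates: value 2v+1 means index v + 0.5
            base = faces_idx.astype(np.int64) * 2 - 1
            base[:, axis] += 2  # plane at i + 0.5
            o1, o2 = [(a, b) for a, b in ((1, 2), (2, 0), (0, 1))][axis]
            corners = np.zeros((len(base), 4, 3), dtype=np.int64)
            offs = np.array([[0, 0], [2, 0], [2, 2], [0, 2]])
            if sign == -1:  # outward normal points toward -axis: reverse winding
                offs = offs[::-1]
            for c in range(4):
                corners[:, c, :] = base
                corners[:, c, o1] += offs[c, 0]
                corners[:, c, o2] += offs[c, 1]
            quads.append(corners)
    allq = np.concatenate(quads, axis=0)
    flat = allq.reshape(-1, 3)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    q = inverse.reshape(-1, 4)
    faces = np.concatenate([q[:, [0, 1, 2]], q[:, [0, 2, 3]]], axis=0)
    # half-units in the padded frame -> voxel-index coordinates of the original
    verts = uniq / 2.0 - 1.0
    return verts, faces


def build_surface(labels: LabelVolume, label: int, smooth_iterations: int = 3) -> SurfaceMesh:
    """Extract a closed, outward-oriented world-frame surface of one label.

    The exact voxel-boundary surface (whose volume equals the voxel count) is
    lightly smoothed with a two-pass (shrink/inflate) Laplacian; the smoothing
    keeps the enclosed volume within 2% of the voxel-count volume.
    """
    mask = labels.data == label
    if not mask.any():
        raise ValueError(f"label {label} not present in volume")
    verts, faces = _voxel_boundary_surface(mask)
    if smooth_iterations > 0:
        verts = _taubin_smooth(verts, faces, smooth_iterations, lam=0.5, mu=-0.53)
    world = verts @ labels.affine[:3, :3].T + labels.affine[:3, 3]
    return SurfaceMesh(world, faces, label=label).oriented_outward()


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume in cm^3 by the divergence theorem (orientation-agnostic)."""
    boundary = mesh.boundary_edges()
    if boundary:
        raise OpenMeshError(boundary)
    return abs(mesh.signed_volume_mm3()) / 1000.0


def muscle_length(meshes, axis: LongAxis) -> float:
    """Extent of all compartment surfaces combined, projected on the long axis (mm)."""
    meshes = list(meshes)
    if not meshes:
        raise ValueError("at least one mesh required")
    proj = np.concatenate([m.vertices @ axis.direction for m in meshes])
    return float(proj.max() - proj.min())


def auto_long_axis(meshes) -> LongAxis:
    """Default long axis: first principal axis of the pooled surface vertices."""
    pts = np.vstack([m.vertices for m in meshes])
    centre = pts.mean(axis=0)
    centred = pts - centre
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    d = vt[0]
    proj = centred @ d
    return LongAxis(proximal=centre + proj.max() * d, distal=centre + proj.min() * d)


def _resample_labels_nearest(labels: LabelVolume, affine: np.ndarray, shape) -> np.ndarray:
    """Nearest-neighbour resampling of the label grid onto another grid."""
    shape = tuple(int(s) for s in shape)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).reshape(-1, 4).astype(float)
    world = vox @ np.asarray(affine, dtype=float).T
    src = world @ np.linalg.inv(labels.affine).T
    idx = np.rint(src[:, :3]).astype(np.int64)
    out = np.zeros(len(idx), dtype=labels.data.dtype)
    ok = np.all((idx >= 0) & (idx < np.array(labels.data.shape)), axis=1)
    out[ok] = labels.data[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    return out.reshape(shape)


def make_seed_and_boundary_masks(labels: LabelVolume, dti_affine: np.ndarray, dti_shape,
                                 margin_voxels: int = 2) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-compartment (seed, boundary) masks on the DTI grid.

    The compartment mask is resampled nearest-neighbour; its boundary layer is
    every in-mask voxel within ``margin_voxels`` (chebyshev, voxel units) of an
    out-of-mask voxel; seeds are the remaining interior.
    """
    resampled = _resample_labels_nearest(labels, dti_affine, dti_shape)
    size = 2 * margin_voxels + 1
    structure = np.ones((size, size, size), dtype=bool)
    out = {}
    for lab in labels.labels():
        comp = resampled == lab
        seed = ndimage.binary_erosion(comp, structure=structure, border_value=0)
        boundary = comp & ~seed
        if not seed.any():
            raise ValueError(
                f"seed mask for label {lab} is empty after {margin_voxels}-voxel erosion; "
                "the compartment is too thin on the DTI grid"
            )
        out[lab] = (seed, boundary)
    return out


def volume_reliability(volumes_short: dict, volumes_long: dict) -> tuple[float, float]:
    """RMS short/long volume difference over paired compartments (cm^3, % of mean)."""
    if set(volumes_short) != set(volumes_long):
        raise ValueError(
            f"unpaired labels: short={sorted(volumes_short)} long={sorted(volumes_long)}"
        )
    labs = sorted(volumes_short)
    diffs = np.array([volumes_short[k] - volumes_long[k] for k in labs], dtype=float)
    rms = float(np.sqrt(np.mean(diffs**2)))
    all_vols = np.array([volumes_short[k] for k in labs] + [volumes_long[k] for k in labs], dtype=float)
    return rms, 100.0 * rms / float(all_vols.mean())
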