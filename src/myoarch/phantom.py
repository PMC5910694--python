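"""Synthetic pennate-muscle phantoms with analytically known architecture.

The phantom idealises each muscle compartment as a slab between two parallel
aponeurosis planes (normal along +x), with the muscle long axis along +z.
Fibre trajectories are either straight lines at a prescribed pennation angle
or congruent circular arcs of prescribed radius, so fascicle length, pennation
and curvature are known in closed form. Voxel boundaries are aligned with
integer multiples of the voxel size (the voxel-to-world affine places voxel
``i`` centre at ``(i + 0.5) * voxel_size``), so slab faces placed at voxel
multiples are voxelised exactly.

The voxelised compartment masks may be trimmed at both long-axis ends
(``cap_margin_mm``) relative to the surface mesh. This mimics restricting
tracking to the muscle belly, away from the ends where reconstruction is
unreliable, and guarantees that extrapolated fascicles attach on the
aponeurosis faces rather than on the end caps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dti import TensorVolume, design_matrix
from .geometry import LabelVolume, SurfaceMesh

__all__ = [
    "HEMISPHERE_16",
    "DEFAULT_EIGENVALUES",
    "CompartmentSpec",
    "PhantomSpec",
    "CompartmentTruth",
    "PhantomTruth",
    "PhantomResult",
    "generate_phantom",
    "synthesize_dwi",
    "four_slab_spec",
    "box_mesh",
]

# 16 electrostatically spread unit vectors on the upper hemisphere
# (minimum pairwise separation 37.4 deg; diffusion design matrix rank 6).
HEMISPHERE_16 = np.array([
    [-0.31236923, -0.94771306, 0.06531014],
    [0.99674793, 0.02838980, 0.07541607],
    [-0.37102778, 0.91828998, 0.13813722],
    [-0.79809088, -0.56014397, 0.22201281],
    [-0.83110259, 0.49000042, 0.26299825],
    [0.73632022, -0.56920630, 0.36583702],
    [0.70006724, 0.58404701, 0.41084662],
    [0.17724075, -0.86450328, 0.47034009],
    [0.12382668, 0.83466603, 0.53665591],
    [-0.79240866, -0.04864082, 0.60804817],
    [0.74701713, -0.00246329, 0.66480022],
    [-0.36943936, -0.61681384, 0.69502176],
    [-0.40569234, 0.53643947, 0.74003136],
    [0.27868636, -0.38288379, 0.88075758],
    [0.25628078, 0.32986595, 0.90857505],
    [-0.25987980, -0.04581439, 0.96455354],
])
HEMISPHERE_16 /= np.linalg.norm(HEMISPHERE_16, axis=1, keepdims=True)

# lambda1 >= lambda2 >= lambda3, giving FA ~ 0.237 and MD ~ 1.33e-3 mm^2/s:
# safely inside the tracking windows FA in [0.1, 0.5], MD in [1e-3, 2e-3].
DEFAULT_EIGENVALUES = (1.7e-3, 1.2e-3, 1.1e-3)

BACKGROUND_MD = 1.4e-3  # isotropic background tensor (FA = 0, outside FA window)


@dataclass
class CompartmentSpec:
    """A slab compartment between two parallel aponeurosis planes.

    The slab occupies ``x in [x0_mm, x0_mm + thickness_mm)`` with in-plane
    extents ``y_extent_mm`` and ``z_extent_mm`` (half-open intervals, so
    touching compartments never overlap). Fibres run in the x-z plane at
    ``pennation_deg`` to the long axis (+z) at mid-thickness; with a finite
    ``arc_radius_mm`` they follow congruent circular arcs of that radius.
    """

    label: int
    pennation_deg: float
    thickness_mm: float
    x0_mm: float = 0.0
    y_extent_mm: tuple[float, float] = (0.0, 40.0)
    z_extent_mm: tuple[float, float] = (0.0, 150.0)
    arc_radius_mm: float | None = None
    bipennate: bool = False
    cap_margin_mm: float = 0.0
    name: str = ""

    def __post_init__(self):
        if self.label <= 0:
            raise ValueError("label must be a positive integer")
        if not 0.0 <= self.pennation_deg < 90.0:
            raise ValueError("pennation_deg must be in [0, 90)")
        if self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be positive")
        if self.arc_radius_mm is not None:
            if self.arc_radius_mm <= self.thickness_mm:
                raise ValueError("arc_radius_mm must exceed thickness_mm")
            theta = math.radians(self.pennation_deg)
            # the arc must span the whole thickness without its tangent
            # turning parallel to the long axis inside the slab
            crossing = self.thickness_mm / 2.0
            if self.arc_radius_mm * (1.0 - math.cos(theta)) < crossing - 1e-9:
                min_r = crossing / (1.0 - math.cos(theta))
                raise ValueError(
                    f"arc_radius_mm={self.arc_radius_mm:g} too small to cross a "
                    f"{self.thickness_mm:g} mm slab at {self.pennation_deg:g} deg "
                    f"pennation (needs >= {min_r:.1f} mm or a larger pennation)"
                )
        if self.cap_margin_mm < 0:
            raise ValueError("cap_margin_mm must be non-negative")
        z0, z1 = self.z_extent_mm
        if z1 - z0 <= 2 * self.cap_margin_mm:
            raise ValueError("cap margins leave no mask between the z extents")

    # -- geometry ---------------------------------------------------------

    @property
    def x_mid(self) -> float:
        return self.x0_mm + self.thickness_mm / 2.0

    @property
    def _arc_centre_x(self) -> float:
        # centre line of the congruent arcs: tangent at mid-thickness makes
        # the prescribed pennation angle with +z
        return self.x_mid + self.arc_radius_mm * math.cos(math.radians(self.pennation_deg))

    def contains(self, points: np.ndarray, *, trimmed: bool = True) -> np.ndarray:
        """Membership test; ``trimmed`` applies the long-axis cap margins (mask
        geometry), otherwise the full mesh extents are used."""
        p = np.atleast_2d(points)
        z0, z1 = self.z_extent_mm
        if trimmed:
            z0, z1 = z0 + self.cap_margin_mm, z1 - self.cap_margin_mm
        y0, y1 = self.y_extent_mm
        return (
            (p[:, 0] >= self.x0_mm) & (p[:, 0] < self.x0_mm + self.thickness_mm)
            & (p[:, 1] >= y0) & (p[:, 1] < y1)
            & (p[:, 2] >= z0) & (p[:, 2] < z1)
        )

    def fibre_direction(self, points: np.ndarray) -> np.ndarray:
        """Unit tangent of the prescribed fibre trajectory at each point."""
        p = np.atleast_2d(points).astype(float)
        x = p[:, 0].copy()
        if self.bipennate:
            mirror = x >= self.x_mid
            x = np.where(mirror, 2 * self.x_mid - x, x)
        theta = math.radians(self.pennation_deg)
        if self.arc_radius_mm is None:
            d = np.tile([math.sin(theta), 0.0, math.cos(theta)], (len(p), 1))
        else:
            u = np.clip((x - self._arc_centre_x) / self.arc_radius_mm, -1.0, 1.0)
            d = np.stack([np.sqrt(1.0 - u**2), np.zeros_like(u), -u], axis=1)
        if self.bipennate:
            d[:, 0] = np.where(p[:, 0] >= self.x_mid, -d[:, 0], d[:, 0])
        return d

    # -- analytic truth ---------------------------------------------------

    def truth(self) -> "CompartmentTruth":
        theta = math.radians(self.pennation_deg)
        y0, y1 = self.y_extent_mm
        z0, z1 = self.z_extent_mm
        volume_cm3 = self.thickness_mm * (y1 - y0) * (z1 - z0) / 1000.0
        crossing = self.thickness_mm / (2.0 if self.bipennate else 1.0)
        if self.arc_radius_mm is None:
            curvature = 0.0
            if self.pennation_deg == 0.0:
                length = z1 - z0  # parallel-fibred: fibres run the z extent
                pennation = 0.0
            else:
                length = crossing / math.sin(theta)
                pennation = self.pennation_deg
        else:
            r = self.arc_radius_mm
            curvature = 1000.0 / r
            # tangent angle from +z at entry/exit faces of the crossing
            phi0 = math.acos(min(1.0, math.cos(theta) + crossing / (2 * r)))
            phi1 = math.acos(max(-1.0, math.cos(theta) - crossing / (2 * r)))
            length = r * (phi1 - phi0)
            chord = np.array([crossing, 0.0, r * (math.sin(phi1) - math.sin(phi0))])
            pennation = math.degrees(math.acos(abs(chord[2]) / np.linalg.norm(chord)))
        pcsa_cm2 = volume_cm3 / (length / 10.0)
        return CompartmentTruth(
            label=self.label, name=self.name, fascicle_length_mm=length,
            pennation_deg=pennation, curvature_per_m=curvature,
            volume_cm3=volume_cm3, pcsa_cm2=pcsa_cm2,
        )


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int]
    compartments: list[CompartmentSpec]
    voxel_size: tuple[float, float, float] = (1.875, 1.875, 5.0)
    eigenvalues: tuple[float, float, float] = DEFAULT_EIGENVALUES
    s0: float = 1000.0
    noise_sigma: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        l1, l2, l3 = self.eigenvalues
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError("eigenvalues must satisfy lambda1 >= lambda2 >= lambda3 > 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not self.compartments:
            raise ValueError("at least one compartment required")
        labels = [c.label for c in self.compartments]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate compartment labels: {labels}")

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0], a[1, 1], a[2, 2] = self.voxel_size
        a[:3, 3] = np.asarray(self.voxel_size) / 2.0  # voxel boundaries on multiples
        return a


@dataclass
class CompartmentTruth:
    label: int
    name: str
    fascicle_length_mm: float
    pennation_deg: float
    curvature_per_m: float
    volume_cm3: float
    pcsa_cm2: float


@dataclass
class PhantomTruth:
    compartments: dict[int, CompartmentTruth]

    def __getitem__(self, label: int) -> CompartmentTruth:
        return self.compartments[label]


@dataclass
class PhantomResult:
    tensors: TensorVolume
    labels: LabelVolume
    meshes: dict[int, SurfaceMesh]
    truth: PhantomTruth
    spec: PhantomSpec


_BOX_FACES = np.array([
    [0, 2, 1], [0, 3, 2],  # x = x0
    [4, 5, 6], [4, 6, 7],  # x = x1
    [0, 1, 5], [0, 5, 4],  # y = y0
    [3, 7, 6], [3, 6, 2],  # y = y1
    [0, 4, 7], [0, 7, 3],  # z = z0
    [1, 2, 6], [1, 6, 5],  # z = z1
])


def box_mesh(x_bounds, y_bounds, z_bounds, label: int = 0) -> SurfaceMesh:
    """Closed, outward-oriented axis-aligned box (8 vertices, 12 triangles)."""
    x0, x1 = x_bounds
    y0, y1 = y_bounds
    z0, z1 = z_bounds
    verts = np.array([
        [x0, y0, z0], [x0, y0, z1], [x0, y1, z1], [x0, y1, z0],
        [x1, y0, z0], [x1, y0, z1], [x1, y1, z1], [x1, y1, z0],
    ], dtype=float)
    return SurfaceMesh(verts, _BOX_FACES.copy(), label=label).oriented_outward()


def _voxel_centres(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.grid_shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    return idx * np.asarray(spec.voxel_size) + np.asarray(spec.voxel_size) / 2.0


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build tensors, labels, surface meshes and analytic truth for a phantom.

    Every in-mask voxel's primary eigenvector is the unit tangent of the
    prescribed fibre trajectory at the voxel centre. Voxels cut by a
    compartment face are assigned by the majority of a 2 x 2 x 2 sub-sample
    (at least half of the sub-points inside; ties between compartments cannot
    occur because compartment geometries are disjoint half-open boxes).
    """
    centres = _voxel_centres(spec)
    n_vox = len(centres)
    offsets = np.array(np.meshgrid(*([[-0.25, 0.25]] * 3), indexing="ij")).reshape(3, -1).T
    sub = centres[:, None, :] + offsets[None, :, :] * np.asarray(spec.voxel_size)

    counts = np.zeros((n_vox, len(spec.compartments)), dtype=np.int8)
    flat_sub = sub.reshape(-1, 3)
    for ci, comp in enumerate(spec.compartments):
        counts[:, ci] = comp.contains(flat_sub).reshape(n_vox, 8).sum(axis=1)

    multi = (counts > 0).sum(axis=1) > 1
    if multi.any():
        bad = np.where(multi)[0][0]
        labs = [spec.compartments[ci].label for ci in np.where(counts[bad] > 0)[0]]
        raise ValueError(f"compartments with labels {labs} overlap in voxel space")

    best = counts.argmax(axis=1)
    best_count = counts[np.arange(n_vox), best]
    labels_flat = np.zeros(n_vox, dtype=np.int16)
    in_mask = best_count >= 4  # geometric majority (>= half the sub-points)
    labels_flat[in_mask] = np.array([c.label for c in spec.compartments], dtype=np.int16)[best[in_mask]]

    l1, l2, l3 = spec.eigenvalues
    tensors_flat = np.empty((n_vox, 3, 3), dtype=float)
    tensors_flat[:] = BACKGROUND_MD * np.eye(3)
    e2 = np.array([0.0, 1.0, 0.0])
    for ci, comp in enumerate(spec.compartments):
        sel = in_mask & (best == ci)
        if not sel.any():
            continue
        d = comp.fibre_direction(centres[sel])
        e3 = np.cross(d, e2)
        e3 /= np.linalg.norm(e3, axis=1, keepdims=True)
        tensors_flat[sel] = (
            l1 * d[:, :, None] * d[:, None, :]
            + l2 * e2[:, None] * e2[None, :]
            + l3 * e3[:, :, None] * e3[:, None, :]
        )

    shape = tuple(spec.grid_shape)
    labels = LabelVolume(labels_flat.reshape(shape), spec.affine)
    tensors = TensorVolume.from_full(
        tensors_flat.reshape(shape + (3, 3)), spec.affine, labels_flat.reshape(shape) > 0
    )
    meshes = {
        c.label: box_mesh((c.x0_mm, c.x0_mm + c.thickness_mm), c.y_extent_mm, c.z_extent_mm,
                          label=c.label)
        for c in spec.compartments
    }
    truth = PhantomTruth({c.label: c.truth() for c in spec.compartments})
    return PhantomResult(tensors=tensors, labels=labels, meshes=meshes, truth=truth, spec=spec)


def synthesize_dwi(tensors: TensorVolume, b_value: float, directions: np.ndarray,
                   s0: float = 1000.0, noise_sigma: float = 0.0,
                   rng_seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one b0 plus one diffusion-weighted volume per direction.

    Noiseless signal is ``S_k = s0 * exp(-b g^T D g)``. With ``noise_sigma > 0``
    each measurement (b0 included) gets independent Rician noise, i.e. the
    magnitude of the signal perturbed by complex Gaussian noise.
    """
    directions = np.asarray(directions, dtype=float)
    if directions.ndim != 2 or directions.shape[0] < 6:
        raise ValueError("at least 6 gradient directions are required")
    if b_value <= 0:
        raise ValueError("b_value must be positive")
    a = design_matrix(b_value, directions)  # validates unit norm
    # exponent b g^T D g expressed through the 6 stored components
    exponent = np.tensordot(tensors.lower, a, axes=([3], [1]))
    dwi = s0 * np.exp(-exponent)
    b0 = np.full(tensors.shape, float(s0))
    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        for vol in (b0, dwi):
            real = vol + rng.normal(0.0, noise_sigma, vol.shape)
            imag = rng.normal(0.0, noise_sigma, vol.shape)
            vol[:] = np.hypot(real, imag)
    return b0, dwi


def four_slab_spec(arc_radius_mm: float | None = None,
                   noise_sigma: float = 0.0, rng_seed: int = 0) -> PhantomSpec:
    """Four-compartment preset mirroring the MA/LA/MP/LP layout as parallel slabs.

    Anterior compartments get smaller pennation angles than posterior ones.
    With a finite ``arc_radius_mm`` all compartments use arc fibres and larger
    pennations (an arc of modest radius cannot cross the slab at a shallow
    angle without turning parallel to the long axis).
    """
    voxel = (1.875, 1.875, 5.0)
    thickness = 22.5  # 12 voxels
    y_extent = (3.75, 48.75)  # 24 voxels
    z_extent = (10.0, 170.0)  # 32 voxels
    cap = 30.0  # 6 voxels trimmed from each z end of the mask
    if arc_radius_mm is None:
        pennations = {"MA": 28.0, "LA": 30.0, "MP": 38.0, "LP": 35.0}
    else:
        pennations = {"MA": 40.0, "LA": 42.0, "MP": 46.0, "LP": 44.0}
    comps = []
    for i, (name, penn) in enumerate(pennations.items()):
        comps.append(CompartmentSpec(
            label=i + 1, name=name, pennation_deg=penn, thickness_mm=thickness,
            x0_mm=3.75 + i * thickness, y_extent_mm=y_extent, z_extent_mm=z_extent,
            arc_radius_mm=arc_radius_mm, cap_margin_mm=cap,
        ))
    return PhantomSpec(grid_shape=(52, 28, 36), compartments=comps, voxel_size=voxel,
                       noise_sigma=noise_sigma, rng_seed=rng_seed)
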