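"""Diffusion-tensor fitting and derived maps (eigen-decomposition, FA, MD, RGB).

Tensors are stored as the 6 unique components in lower-triangular row order
(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz), in mm^2/s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "TensorVolume",
    "EigenMaps",
    "design_matrix",
    "fit_tensor",
    "eigen_maps",
    "primary_eigenvector_rgb",
    "smooth_tensor_components",
]

# index pairs of the 6 stored components within the full symmetric 3x3 tensor
_LT = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensor with a voxel-to-world affine."""

    lower: np.ndarray  # (X, Y, Z, 6): Dxx, Dxy, Dyy, Dxz, Dyz, Dzz
    affine: np.ndarray  # 4x4 (mm)
    mask: np.ndarray  # (X, Y, Z) bool

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.lower.ndim != 4 or self.lower.shape[-1] != 6:
            raise ValueError("tensor volume must have shape (X, Y, Z, 6)")
        if self.mask.shape != self.lower.shape[:3]:
            raise ValueError("mask shape does not match tensor grid")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.lower.shape[:3]

    def full(self) -> np.ndarray:
        """Expand to full symmetric (X, Y, Z, 3, 3) tensors."""
        out = np.empty(self.shape + (3, 3), dtype=float)
        for comp, (i, j) in enumerate(_LT):
            out[..., i, j] = self.lower[..., comp]
            out[..., j, i] = self.lower[..., comp]
        return out

    @classmethod
    def from_full(cls, tensors: np.ndarray, affine: np.ndarray, mask: np.ndarray) -> "TensorVolume":
        tensors = np.asarray(tensors, dtype=float)
        lower = np.stack([tensors[..., i, j] for (i, j) in _LT], axis=-1)
        return cls(lower, affine, mask)


@dataclass
class EigenMaps:
    """Sorted eigen-decomposition of a tensor volume plus FA and MD."""

    evals: np.ndarray  # (X, Y, Z, 3), lambda1 >= lambda2 >= lambda3
    evecs: np.ndarray  # (X, Y, Z, 3, 3), evecs[..., i, :] is the i-th eigenvector
    fa: np.ndarray
    md: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    negative_eigenvalue_mask: np.ndarray | None = None

    @property
    def e1(self) -> np.ndarray:
        return self.evecs[..., 0, :]


def design_matrix(b_value: float, directions: np.ndarray) -> np.ndarray:
    """Rows b * (gx^2, 2 gx gy, gy^2, 2 gx gz, 2 gy gz, gz^2) matching the storage order."""
    g = np.asarray(directions, dtype=float)
    if g.ndim != 2 or g.shape[1] != 3:
        raise ValueError("directions must be (N, 3)")
    norms = np.linalg.norm(g, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("gradient directions must be unit vectors")
    gx, gy, gz = g.T
    return b_value * np.column_stack([gx**2, 2 * gx * gy, gy**2, 2 * gx * gz, 2 * gy * gz, gz**2])


def fit_tensor(dwi: np.ndarray, b_value: float, directions: np.ndarray,
               b0: np.ndarray, affine: np.ndarray, mask: np.ndarray | None = None) -> TensorVolume:
    """Log-linear least-squares tensor fit.

    Solves log(S_k/S0) = -b g_k^T D g_k per voxel. Voxels with non-positive
    signal (in any volume) are removed from the mask.
    """
    dwi = np.asarray(dwi, dtype=float)
    b0 = np.asarray(b0, dtype=float)
    directions = np.asarray(directions, dtype=float)
    if directions.shape[0] < 6:
        raise ValueError("at least 6 gradient directions are required")
    if dwi.ndim != 4 or dwi.shape[-1] != directions.shape[0]:
        raise ValueError("dwi must be (X, Y, Z, n_directions)")
    a = design_matrix(b_value, directions)
    if np.linalg.matrix_rank(a) < 6:
        raise ValueError("gradient scheme is rank-deficient (coplanar directions?)")
    if mask is None:
        mask = np.ones(dwi.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool).copy()
    positive = (b0 > 0) & np.all(dwi > 0, axis=-1)
    n_dropped = int((mask & ~positive).sum())
    if n_dropped:
        logger.info("fit_tensor: dropping %d voxels with non-positive signal", n_dropped)
    mask &= positive

    lower = np.zeros(dwi.shape[:3] + (6,), dtype=float)
    if mask.any():
        y = -np.log(dwi[mask] / b0[mask][:, None])  # (V, N)
        pinv = np.linalg.pinv(a)  # (6, N)
        lower[mask] = y @ pinv.T
    return TensorVolume(lower, affine, mask)


def eigen_maps(tensors: TensorVolume) -> EigenMaps:
    """Sorted eigenvalues/eigenvectors, FA and MD per voxel.

    Non-finite tensors are dropped from the mask (and counted in the log).
    Negative eigenvalues are clamped to zero for the FA computation only and
    the affected voxels flagged.
    """
    full = tensors.full()
    mask = tensors.mask.copy()
    finite = np.all(np.isfinite(full), axis=(-2, -1))
    n_bad = int((mask & ~finite).sum())
    if n_bad:
        logger.info("eigen_maps: dropping %d voxels with non-finite tensors", n_bad)
        mask &= finite
    full = np.where(finite[..., None, None], full, 0.0)

    w, v = np.linalg.eigh(full)  # ascending; v[..., :, i] is i-th eigenvector
    order = slice(None, None, -1)
    evals = w[..., order]
    evecs = np.swapaxes(v, -2, -1)[..., order, :]

    md = evals.mean(axis=-1)
    negative = mask & np.any(evals < 0, axis=-1)
    clamped = np.clip(evals, 0.0, None)
    num = ((clamped[..., 0] - clamped[..., 1]) ** 2
           + (clamped[..., 1] - clamped[..., 2]) ** 2
           + (clamped[..., 2] - clamped[..., 0]) ** 2)
    den = (clamped**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return EigenMaps(evals=evals, evecs=evecs, fa=fa, md=md, mask=mask,
                     affine=tensors.affine, negative_eigenvalue_mask=negative)


def primary_eigenvector_rgb(maps: EigenMaps) -> np.ndarray:
    """Direction-encoded colour volume: RGB = |e1| * FA (sign-invariant)."""
    return np.abs(maps.e1) * maps.fa[..., None]


def smooth_tensor_components(tensors: TensorVolume, sigma_mm: float) -> TensorVolume:
    """Optional Gaussian smoothing of the 6 tensor components (off by default upstream)."""
    if sigma_mm <= 0:
        return tensors
    voxel = np.sqrt((tensors.affine[:3, :3] ** 2).sum(axis=0))
    sigma_vox = sigma_mm / voxel
    lower = np.stack(
        [ndimage.gaussian_filter(tensors.lower[..., c], sigma=sigma_vox) for c in range(6)],
        axis=-1,
    )
    return TensorVolume(lower, tensors.affine, tensors.mask)
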